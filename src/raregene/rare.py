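"""Rare-gene identification by permutation-derived thresholds.

A rare gene is abundantly expressed (high average non-zero log expression)
in a small fraction of cells. Thresholds for "abundantly" and "small" come
from a permutation null: the combined PCG + lncRNA matrix is scrambled
``n_perm`` times, per-gene average non-zero expression and cell proportion
are recomputed on each scramble and pooled, and the thresholds are the 99th
percentile of the pooled expression null and the 1st percentile of the
pooled proportion null. A gene passes when its average non-zero expression
is strictly above the expression threshold, its cell proportion strictly
below the proportion threshold, it is detected in at least ``min_cells``
cells, and no single sample shows it in more than ``max_sample_prop`` of
that sample's cells.

The default scramble permutes all entries over the whole genes x cells grid
(one global permutation per iteration), giving a common null for both
statistics; a within-cell mode that permutes each column separately is
available for sensitivity analysis.

A simpler quartile screen is also provided: flag genes whose average
non-zero expression exceeds the third quartile of the PCG values while
their cell proportion stays below 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import ConfigurationError, DataError

__all__ = [
    "gene_stats",
    "NullDistributions",
    "permutation_null",
    "identify_rare_genes",
    "quartile_screen",
]

FAIL_LOW_EXPR = "low_expr"
FAIL_HIGH_PROPORTION = "high_proportion"
FAIL_TOO_FEW_CELLS = "too_few_cells"
FAIL_ABUNDANT_IN_SAMPLE = "abundant_in_sample"


def gene_stats(
    log_m: pd.DataFrame,
    sample_ids: pd.Series,
    biotype: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene detection statistics.

    Columns: ``avg_nonzero`` (mean log expression over detected cells, NaN
    when the gene is detected nowhere — never silently 0),
    ``n_detected_cells``, ``cell_proportion``, one ``prop_<sample>`` column
    per sample, ``max_sample_proportion``, and ``biotype`` when given.
    """
    if log_m.empty:
        raise DataError("expression matrix is empty")
    missing = log_m.columns.difference(sample_ids.index)
    if len(missing):
        raise DataError(f"no sample id for cell {missing[0]!r}")
    values = log_m.to_numpy(dtype=float)
    detected = values > 0
    n_det = detected.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        avg_nonzero = np.where(n_det > 0, values.sum(axis=1) / np.maximum(n_det, 1), np.nan)
    out = pd.DataFrame(
        {
            "avg_nonzero": avg_nonzero,
            "n_detected_cells": n_det,
            "cell_proportion": n_det / log_m.shape[1],
        },
        index=log_m.index,
    )
    samples = sample_ids.loc[log_m.columns]
    prop_cols = []
    for sample in dict.fromkeys(samples):
        in_sample = (samples == sample).to_numpy()
        col = f"prop_{sample}"
        out[col] = detected[:, in_sample].sum(axis=1) / in_sample.sum()
        prop_cols.append(col)
    out["max_sample_proportion"] = out[prop_cols].max(axis=1)
    if biotype is not None:
        out.insert(0, "biotype", biotype.loc[log_m.index])
    return out


@dataclass
class NullDistributions:
    """Pooled permutation nulls and the thresholds derived from them."""

    n_perm: int
    seed: int
    mode: str
    expr_null: np.ndarray
    prop_null: np.ndarray
    expr_threshold: float
    prop_threshold: float


def permutation_null(
    log_m: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    mode: str = "global",
    expr_percentile: float = 99.0,
    prop_percentile: float = 1.0,
) -> NullDistributions:
    """Scramble the matrix ``n_perm`` times and pool per-gene statistics.

    ``mode="global"`` permutes all entries over the genes x cells grid;
    ``mode="within-cell"`` permutes each cell's column separately. Genes
    with zero detected cells in a scramble contribute no expression-null
    value (their average is undefined). Percentiles use linear
    interpolation between order statistics.
    """
    if n_perm < 1:
        raise ConfigurationError(f"n_perm must be >= 1, got {n_perm}")
    if mode not in ("global", "within-cell"):
        raise ConfigurationError(f"unknown shuffle mode {mode!r}")
    values = log_m.to_numpy(dtype=float)
    n_genes, n_cells = values.shape
    flat = values.ravel()
    rng = np.random.default_rng(seed)
    expr_parts, prop_parts = [], []
    for _ in range(n_perm):
        if mode == "global":
            perm = rng.permutation(flat).reshape(n_genes, n_cells)
        else:
            perm = rng.permuted(values, axis=0)
        n_det = np.count_nonzero(perm > 0, axis=1)
        sums = perm.sum(axis=1)
        ok = n_det > 0
        expr_parts.append(sums[ok] / n_det[ok])
        prop_parts.append(n_det / n_cells)
    expr_null = np.concatenate(expr_parts)
    prop_null = np.concatenate(prop_parts)
    return NullDistributions(
        n_perm=n_perm,
        seed=seed,
        mode=mode,
        expr_null=expr_null,
        prop_null=prop_null,
        expr_threshold=float(np.percentile(expr_null, expr_percentile)),
        prop_threshold=float(np.percentile(prop_null, prop_percentile)),
    )


def identify_rare_genes(
    stats: pd.DataFrame,
    nulls: NullDistributions,
    min_cells: int = 10,
    max_sample_prop: float = 0.2,
) -> pd.DataFrame:
    """Apply the four rare-gene criteria and record every failure reason.

    A gene passes iff its average non-zero expression is strictly above the
    expression threshold, its cell proportion strictly below the proportion
    threshold, it is detected in at least ``min_cells`` cells, and its
    maximal per-sample proportion is at most ``max_sample_prop``.
    """
    out = stats.copy()
    avg = out["avg_nonzero"]
    reasons = []
    for gene in out.index:
        r = []
        a = avg.loc[gene]
        if not (np.isfinite(a) and a > nulls.expr_threshold):
            r.append(FAIL_LOW_EXPR)
        if not (out.at[gene, "cell_proportion"] < nulls.prop_threshold):
            r.append(FAIL_HIGH_PROPORTION)
        if out.at[gene, "n_detected_cells"] < min_cells:
            r.append(FAIL_TOO_FEW_CELLS)
        if out.at[gene, "max_sample_proportion"] > max_sample_prop:
            r.append(FAIL_ABUNDANT_IN_SAMPLE)
        reasons.append(r)
    out["fail_reasons"] = [";".join(r) for r in reasons]
    out["passed"] = [not r for r in reasons]
    return out


def quartile_screen(
    stats: pd.DataFrame,
    max_prop: float = 0.2,
    quantile: float = 0.75,
) -> tuple[pd.DataFrame, dict]:
    """Quartile screening heuristic across biotypes.

    Flags any gene whose average non-zero expression is strictly above the
    ``quantile`` (default third quartile, linear-interpolation convention)
    of the PCG averages while its cell proportion is strictly below
    ``max_prop``. The summary reports the fraction of flagged genes among
    all genes above the quartile bar.
    """
    if "biotype" not in stats.columns:
        raise DataError("stats table lacks a 'biotype' column")
    pcg_avg = stats.loc[stats["biotype"] == "PCG", "avg_nonzero"].dropna()
    if pcg_avg.empty:
        raise DataError("no PCGs with defined average non-zero expression")
    q3 = float(np.quantile(pcg_avg.to_numpy(), quantile))
    out = stats.copy()
    above = out["avg_nonzero"] > q3
    out["flagged"] = above & (out["cell_proportion"] < max_prop)
    n_above = int(above.sum())
    summary = {
        "q3": q3,
        "n_above_quartile": n_above,
        "n_flagged": int(out["flagged"].sum()),
        "rare_fraction_of_high": (float(out["flagged"].sum() / n_above) if n_above else np.nan),
    }
    return out, summary
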