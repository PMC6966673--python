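"""Expression-inferred copy-number profiles and malignancy calling.

A relative copy-number proxy per gene is the moving average of log
expression over its genomically flanking genes (half the window on each
side, the focal gene excluded, truncated at the ends of the sorted gene
list). Each cell's profile is then centered to mean zero. Cells are called
malignant by hierarchical clustering together with a normal reference
profile: cells clustering with the reference are non-malignant.

The flanking window runs over the single global genomic sort by default,
mirroring a one-pass sort of all genes; a per-chromosome mode that restarts
the window at chromosome boundaries is available.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ._errors import ConfigurationError, DataError

__all__ = ["order_genes", "infer_cnv", "build_reference", "call_malignant"]


def order_genes(ann: pd.DataFrame, chrom_order: list[str] | None = None) -> list[str]:
    """Gene ids sorted by (chromosome, start), stably.

    Chromosomes follow ``chrom_order`` when given, otherwise their first
    appearance in the annotation. Ties on (chromosome, start) preserve the
    input order.
    """
    if ann.empty:
        return []
    for col in ("chrom", "start"):
        if col not in ann.columns:
            raise DataError(f"annotation lacks a {col!r} column")
        bad = ann.index[ann[col].isna()]
        if len(bad):
            raise DataError(f"gene {bad[0]!r} has no {col!r} coordinate")
    if chrom_order is None:
        chrom_order = list(dict.fromkeys(ann["chrom"]))
    unknown = set(ann["chrom"]) - set(chrom_order)
    if unknown:
        raise DataError(f"chromosome {sorted(unknown)[0]!r} missing from chrom_order")
    rank = {c: i for i, c in enumerate(chrom_order)}
    key = pd.DataFrame(
        {"c": ann["chrom"].map(rank), "s": ann["start"]}, index=ann.index
    )
    return key.sort_values(["c", "s"], kind="mergesort").index.tolist()


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Moving average over ``window`` flanking entries (half per side),
    excluding the focal entry, truncated at array bounds.

    ``values`` is (genes x cells); smoothing acts along axis 0.
    """
    n = values.shape[0]
    half = window // 2
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    csum = np.vstack([np.zeros((1, values.shape[1])), np.cumsum(values, axis=0)])
    window_sum = csum[hi + 1] - csum[lo]
    count = (hi - lo + 1)[:, None] - 1  # focal gene excluded
    return (window_sum - values) / count


def infer_cnv(
    log_m: pd.DataFrame,
    order: list[str],
    window: int = 100,
    per_chromosome: bool = False,
    ann: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-cell centered CNV profiles (genes x cells, ``order`` rows).

    Each gene's value is the mean log expression of its ``window`` flanking
    genes (window/2 per side, focal gene excluded, shorter at the edges);
    each cell's vector is then centered by subtracting its own mean.
    """
    if window < 2 or window % 2:
        raise ConfigurationError(f"window must be an even integer >= 2, got {window}")
    if window >= len(order):
        raise ConfigurationError(
            f"window ({window}) must be smaller than the number of ordered genes ({len(order)})"
        )
    missing = [g for g in order if g not in log_m.index]
    if missing:
        raise DataError(f"gene {missing[0]!r} in the ordering is absent from the matrix")
    values = log_m.loc[order].to_numpy(dtype=float)
    if per_chromosome:
        if ann is None:
            raise ConfigurationError("per_chromosome smoothing requires the annotation")
        chroms = ann.loc[order, "chrom"].to_numpy()
        smoothed = np.empty_like(values)
        for c in dict.fromkeys(chroms):
            block = chroms == c
            if block.sum() <= window:
                raise ConfigurationError(
                    f"window ({window}) must be smaller than chromosome {c!r} ({block.sum()} genes)"
                )
            smoothed[block] = _smooth(values[block], window)
    else:
        smoothed = _smooth(values, window)
    centered = smoothed - smoothed.mean(axis=0, keepdims=True)
    return pd.DataFrame(centered, index=pd.Index(order, name="gene_id"), columns=log_m.columns)


def build_reference(
    normal_log_m: pd.DataFrame,
    order: list[str],
    window: int = 100,
    per_chromosome: bool = False,
    ann: pd.DataFrame | None = None,
) -> pd.Series:
    """Reference CNV profile from normal samples.

    Normal expression is averaged per gene across samples first; the single
    averaged vector is then smoothed and centered exactly as a cell profile.
    """
    if normal_log_m.shape[1] == 0:
        raise DataError("no normal samples supplied")
    mean_profile = normal_log_m.mean(axis=1).to_frame("reference")
    prof = infer_cnv(mean_profile, order, window, per_chromosome=per_chromosome, ann=ann)
    return prof["reference"]


def _correlation_distances(x: np.ndarray) -> np.ndarray:
    """Pairwise (1 - Pearson correlation) with constant-row handling:
    two rows that are both constant are at distance 0 from each other and
    at the maximal distance 2 from any non-constant row."""
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    flat = norms < 1e-300
    safe = np.where(flat, 1.0, norms)
    corr = (centered @ centered.T) / np.outer(safe, safe)
    dist = 1.0 - corr
    if flat.any():
        dist[flat, :] = 2.0
        dist[:, flat] = 2.0
        dist[np.ix_(flat, flat)] = 0.0
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum((dist + dist.T) / 2.0, 0.0)
    return dist


def call_malignant(
    profiles: pd.DataFrame,
    reference: pd.Series,
    linkage_method: str = "average",
    k: int = 2,
    max_reference_fraction: float = 0.9,
) -> pd.Series:
    """Malignant / non-malignant flags per cell.

    Cells and the reference profile are clustered agglomeratively
    (1 - Pearson correlation distance, ``linkage_method`` linkage, cut into
    ``k`` clusters); every cell sharing a cluster with the reference is
    flagged non-malignant, all others malignant.

    When the cut fails to isolate a reference-containing cluster genuinely
    smaller than the whole set — the reference cluster swallows more than
    ``max_reference_fraction`` of the cells, which with noise is "all of
    them modulo stray outliers" — the separation is uninformative and all
    cells are flagged malignant with a warning. The one exception: cells
    numerically identical to the reference are always non-malignant.
    """
    if not profiles.index.equals(reference.index):
        raise DataError("profiles and reference are not on the same gene order")
    n_cells = profiles.shape[1]
    if n_cells + 1 < k + 1:
        raise ConfigurationError(f"need at least {k} cells to cut into k={k} clusters")
    x = np.vstack([profiles.to_numpy(dtype=float).T, reference.to_numpy(dtype=float)])
    dist = _correlation_distances(x)
    if np.allclose(dist[-1, :-1], 0.0, atol=1e-12):
        return pd.Series(False, index=profiles.columns, name="malignant")
    z = linkage(squareform(dist, checks=False), method=linkage_method)
    labels = fcluster(z, t=k, criterion="maxclust")
    ref_cluster = labels[-1]
    non_malignant = labels[:-1] == ref_cluster
    if non_malignant.mean() > max_reference_fraction:
        warnings.warn(
            "clustering failed to isolate a reference cluster smaller than "
            "the whole set; flagging all cells malignant",
            stacklevel=2,
        )
        non_malignant[:] = False
    return pd.Series(~non_malignant, index=profiles.columns, name="malignant")
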