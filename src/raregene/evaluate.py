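"""Parameter-recovery evaluation against synthetic ground truth.

Each helper generates a dataset from a :class:`SyntheticConfig`, runs one
pipeline stage, and scores the result against the planted truth. These are
the building blocks for recovery studies and for the reproduction script.
"""

from __future__ import annotations

import numpy as np

from . import cnv, noise, rare
from .preprocess import ExpressionMatrix
from .synthetic import SyntheticConfig, generate_dataset, generate_normal_reference

__all__ = [
    "rare_gene_recovery",
    "noise_classifier_performance",
    "noise_classifier_null_control",
    "malignancy_accuracy",
]


def rare_gene_recovery(cfg: SyntheticConfig, n_perm: int = 1000) -> dict:
    """Sensitivity and precision of `discover` on planted rare genes.

    Runs gene statistics, the permutation null and the four-filter call on
    the full synthetic matrix (QC is moot: generated cells all pass).
    """
    ds = generate_dataset(cfg)
    log = ExpressionMatrix(ds.matrix).log2
    stats = rare.gene_stats(log, ds.cells["sample_id"], biotype=ds.annotation["biotype"])
    nulls = rare.permutation_null(log, n_perm=n_perm, seed=cfg.seed)
    calls = rare.identify_rare_genes(stats, nulls)
    called = set(calls.index[calls["passed"]])
    truth = ds.truth.rare_gene_ids
    tp = len(called & truth)
    return {
        "sensitivity": tp / len(truth) if truth else np.nan,
        "precision": tp / len(called) if called else np.nan,
        "n_called": len(called),
        "expr_threshold": nulls.expr_threshold,
        "prop_threshold": nulls.prop_threshold,
    }


def noise_classifier_performance(cfg: SyntheticConfig) -> dict:
    """Mean cross-validated AUC over cells and the fraction of planted
    noise entries labeled noise, for one synthetic dataset."""
    ds = generate_dataset(cfg)
    m = ExpressionMatrix(ds.matrix)
    lnc = ds.annotation.index[ds.annotation["biotype"] == "lncRNA"]
    res = noise.denoise(m.log2.loc[lnc], ds.coverage, seed=cfg.seed)
    mask = ds.truth.noise_entry_mask.loc[res.denoised.index, res.retained_cells]
    noisy = res.calls[res.calls["label"] == "noise"]
    called = set(zip(noisy["gene_id"], noisy["cell_id"]))
    genes, cells = np.nonzero(mask.to_numpy())
    truth_pairs = list(zip(mask.index[genes], mask.columns[cells]))
    hit = sum(p in called for p in truth_pairs)
    return {
        "mean_auc": float(res.summary["mean_auc"].dropna().mean()),
        "noise_recall": hit / len(truth_pairs) if truth_pairs else np.nan,
        "n_cells_retained": len(res.retained_cells),
    }


def noise_classifier_null_control(seed: int, n_points: int = 40, k: int = 5) -> float:
    """Mean CV AUC when positive and negative features share one
    distribution — the no-information control, expected near 0.5."""
    rng = np.random.default_rng(seed)

    def draw():
        return np.column_stack([rng.uniform(0, 1, n_points), rng.beta(2, 2, n_points)])

    return float(np.mean(noise.cross_validate_cell(draw(), draw(), k=k, seed=seed)))


def malignancy_accuracy(cfg: SyntheticConfig, window: int = 100) -> float:
    """Accuracy of CNV-based malignant/non-malignant calls vs truth."""
    import warnings

    ds = generate_dataset(cfg)
    m = ExpressionMatrix(ds.matrix)
    order = cnv.order_genes(ds.annotation)
    profiles = cnv.infer_cnv(m.log2, order, window)
    normals = ExpressionMatrix(generate_normal_reference(cfg))
    reference = cnv.build_reference(normals.log2.loc[order], order, window)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # no-signal configs fall back loudly
        calls = cnv.call_malignant(profiles, reference)
    truth = calls.index.isin(ds.truth.malignant_cell_ids)
    return float((calls.to_numpy() == truth).mean())
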