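"""Per-cell lncRNA noise filtering by a kernel-density likelihood ratio.

Low-level lncRNA signal in single cells can stem from genomic DNA
contamination or incompletely processed transcripts rather than genuine
expression. For each cell, a classifier is trained on two features of each
detected lncRNA — its relative abundance (empirical-CDF rank among the
lncRNAs detected in that cell) and its exon coverage — using as labels two
population-level training sets: lncRNAs detected in more than
``pos_fraction`` of QC-passed cells (positive, genuinely expressed) and
lncRNAs detected in no more than ``neg_max_cells`` cells (negative, noise).

Bivariate Gaussian KDEs (Scott bandwidth) are fit to each set, evaluated on
a regular lattice over the unit square and queried by bilinear
interpolation; the likelihood ratio (pos + eps) / (neg + eps) is
thresholded at the cutoff maximizing balanced accuracy on the training
lncRNAs. A lncRNA with ratio strictly below the cutoff is "noise", others
"expressed". Classifier quality per cell is the mean ROC AUC over
stratified k-fold cross-validation; cells at or below ``min_auc`` are
dropped from downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.stats import gaussian_kde, rankdata
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from ._errors import ClassifierNotTrainableError, ConfigurationError, DataError

__all__ = [
    "TrainingSets",
    "CellClassifier",
    "build_training_sets",
    "relative_abundance",
    "exon_coverage_feature",
    "fit_cell_classifier",
    "select_cutoff",
    "cross_validate_cell",
    "gate_cells",
    "apply_classifier",
    "denoise",
]


@dataclass
class TrainingSets:
    positive_ids: list[str]
    negative_ids: list[str]


@dataclass
class CellClassifier:
    """Fitted per-cell KDE likelihood-ratio classifier."""

    cell_id: str
    grid_x: np.ndarray
    grid_y: np.ndarray
    pos_density: np.ndarray
    neg_density: np.ndarray
    epsilon: float = 1e-10
    cutoff: float = np.nan
    fold_aucs: list[float] = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs)) if self.fold_aucs else np.nan

    def likelihood_ratio(self, points: np.ndarray) -> np.ndarray:
        """(pos + eps) / (neg + eps) at query points (n x 2), densities
        obtained by bilinear interpolation on the lattice."""
        points = np.atleast_2d(points)
        pos = RegularGridInterpolator((self.grid_x, self.grid_y), self.pos_density)(points)
        neg = RegularGridInterpolator((self.grid_x, self.grid_y), self.neg_density)(points)
        return (pos + self.epsilon) / (neg + self.epsilon)


def build_training_sets(
    lnc_log_m: pd.DataFrame,
    pos_fraction: float = 0.8,
    neg_max_cells: int = 2,
) -> TrainingSets:
    """Population-level positive/negative lncRNA sets.

    Positive: detected in strictly more than ``pos_fraction`` of cells.
    Negative: detected in at least one and at most ``neg_max_cells`` cells.
    """
    n_cells = lnc_log_m.shape[1]
    if n_cells < 1:
        raise DataError("need at least one cell to build training sets")
    detected = (lnc_log_m > 0).sum(axis=1)
    pos = detected.index[(detected / n_cells) > pos_fraction].tolist()
    neg = detected.index[(detected >= 1) & (detected <= neg_max_cells)].tolist()
    if not pos or not neg:
        raise ClassifierNotTrainableError(
            f"training sets not usable: {len(pos)} positive, {len(neg)} negative lncRNAs"
        )
    return TrainingSets(positive_ids=pos, negative_ids=neg)


def relative_abundance(cell_expr: pd.Series) -> pd.Series:
    """Empirical-CDF rank in (0, 1] of each detected lncRNA's expression
    among the lncRNAs detected in one cell; ties share the maximal rank."""
    if len(cell_expr) == 0:
        return pd.Series(dtype=float)
    if (cell_expr <= 0).any():
        raise DataError("relative_abundance expects only detected (positive) values")
    ranks = rankdata(cell_expr.to_numpy(), method="max")
    return pd.Series(ranks / len(cell_expr), index=cell_expr.index)


def exon_coverage_feature(
    cov_m: pd.DataFrame, cell_id: str, gene_ids: list[str]
) -> pd.Series:
    """Exon-coverage values for given genes in one cell, checked to [0, 1]."""
    if cell_id not in cov_m.columns:
        raise DataError(f"coverage matrix has no column for cell {cell_id!r}")
    missing = [g for g in gene_ids if g not in cov_m.index]
    if missing:
        raise DataError(f"coverage missing for gene {missing[0]!r}, cell {cell_id!r}")
    vals = cov_m.loc[gene_ids, cell_id]
    if vals.isna().any():
        g = vals.index[vals.isna()][0]
        raise DataError(f"coverage missing for gene {g!r}, cell {cell_id!r}")
    if ((vals < 0) | (vals > 1)).any():
        g = vals.index[(vals < 0) | (vals > 1)][0]
        raise DataError(f"coverage outside [0, 1] for gene {g!r}, cell {cell_id!r}")
    return vals


def _kde_on_grid(points: np.ndarray, gx: np.ndarray, gy: np.ndarray) -> np.ndarray:
    """Gaussian KDE (Scott bandwidth) of (n x 2) points evaluated on the
    lattice; raises ClassifierNotTrainableError on degenerate inputs."""
    if points.shape[0] < 3:
        raise ClassifierNotTrainableError(
            f"too few points ({points.shape[0]}) for a bivariate KDE"
        )
    try:
        kde = gaussian_kde(points.T)
        mesh = np.meshgrid(gx, gy, indexing="ij")
        dens = kde(np.vstack([m.ravel() for m in mesh])).reshape(len(gx), len(gy))
    except np.linalg.LinAlgError as exc:
        raise ClassifierNotTrainableError(f"degenerate KDE: {exc}") from exc
    return dens


def fit_cell_classifier(
    cell_id: str,
    pos_points: np.ndarray,
    neg_points: np.ndarray,
    grid_resolution: int = 100,
    epsilon: float = 1e-10,
    min_train: int = 5,
) -> CellClassifier:
    """Fit the two KDEs for one cell on (abundance, coverage) points."""
    pos_points = np.atleast_2d(np.asarray(pos_points, dtype=float))
    neg_points = np.atleast_2d(np.asarray(neg_points, dtype=float))
    if len(pos_points) < min_train or len(neg_points) < min_train:
        raise ClassifierNotTrainableError(
            f"cell {cell_id!r}: {len(pos_points)} positive / {len(neg_points)} "
            f"negative training lncRNAs detected (need >= {min_train} each)"
        )
    gx = np.linspace(0.0, 1.0, grid_resolution)
    gy = np.linspace(0.0, 1.0, grid_resolution)
    return CellClassifier(
        cell_id=cell_id,
        grid_x=gx,
        grid_y=gy,
        pos_density=_kde_on_grid(pos_points, gx, gy),
        neg_density=_kde_on_grid(neg_points, gx, gy),
        epsilon=epsilon,
    )


def select_cutoff(ratios: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Likelihood-ratio cutoff maximizing balanced accuracy.

    Candidates are the sorted unique observed ratios; the prediction rule is
    "expressed iff ratio >= cutoff". Ties on balanced accuracy are broken by
    the smallest cutoff. Returns (cutoff, balanced accuracy).
    """
    ratios = np.asarray(ratios, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise DataError("cutoff selection needs both positive and negative labels")
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    best_cut, best_ba = np.nan, -1.0
    for cut in np.unique(ratios):
        pred = ratios >= cut
        sens = (pred & labels).sum() / n_pos
        spec = (~pred & ~labels).sum() / n_neg
        ba = (sens + spec) / 2.0
        if ba > best_ba:
            best_cut, best_ba = float(cut), float(ba)
    return best_cut, best_ba


def cross_validate_cell(
    pos_points: np.ndarray,
    neg_points: np.ndarray,
    k: int = 5,
    seed: int = 0,
    grid_resolution: int = 100,
    epsilon: float = 1e-10,
) -> list[float]:
    """Stratified k-fold ROC AUCs of the likelihood ratio for one cell.

    Raises :class:`ClassifierNotTrainableError` when either class has fewer
    members than folds or a fold degenerates.
    """
    pos_points = np.atleast_2d(np.asarray(pos_points, dtype=float))
    neg_points = np.atleast_2d(np.asarray(neg_points, dtype=float))
    if len(pos_points) < k or len(neg_points) < k:
        raise ClassifierNotTrainableError(
            f"classes of size {len(pos_points)}/{len(neg_points)} cannot be "
            f"split into {k} stratified folds"
        )
    x = np.vstack([pos_points, neg_points])
    y = np.concatenate([np.ones(len(pos_points), dtype=bool), np.zeros(len(neg_points), dtype=bool)])
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    aucs = []
    for train, test in splitter.split(x, y):
        clf = fit_cell_classifier(
            "cv", x[train][y[train]], x[train][~y[train]],
            grid_resolution=grid_resolution, epsilon=epsilon, min_train=3,
        )
        scores = clf.likelihood_ratio(x[test])
        aucs.append(float(roc_auc_score(y[test], scores)))
    return aucs


def gate_cells(classifiers: dict[str, CellClassifier], min_auc: float = 0.8) -> list[str]:
    """Cells whose mean cross-validated AUC is strictly above ``min_auc``."""
    return [
        cid for cid, clf in classifiers.items()
        if np.isfinite(clf.mean_auc) and clf.mean_auc > min_auc
    ]


def apply_classifier(
    clf: CellClassifier, points: np.ndarray, gene_ids: list[str]
) -> pd.DataFrame:
    """Label every detected lncRNA of one cell.

    A lncRNA whose likelihood ratio is strictly below the cell's cutoff is
    "noise"; a ratio at or above the cutoff is "expressed".
    """
    if not np.isfinite(clf.cutoff):
        raise ClassifierNotTrainableError(f"cell {clf.cell_id!r} has no fitted cutoff")
    ratios = clf.likelihood_ratio(points)
    labels = np.where(ratios < clf.cutoff, "noise", "expressed")
    points = np.atleast_2d(points)
    return pd.DataFrame(
        {
            "cell_id": clf.cell_id,
            "gene_id": gene_ids,
            "abundance": points[:, 0],
            "coverage": points[:, 1],
            "likelihood_ratio": ratios,
            "label": labels,
        }
    )


@dataclass
class DenoiseResult:
    denoised: pd.DataFrame          # lncRNA log matrix with noise entries zeroed
    calls: pd.DataFrame             # one row per (cell, detected lncRNA)
    summary: pd.DataFrame           # per-cell classifier summary
    retained_cells: list[str]
    classifiers: dict[str, CellClassifier]


def _cell_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))


def denoise(
    lnc_log_m: pd.DataFrame,
    cov_m: pd.DataFrame,
    pos_fraction: float = 0.8,
    neg_max_cells: int = 2,
    cv_folds: int = 5,
    min_auc: float = 0.8,
    seed: int = 0,
    grid_resolution: int = 100,
    epsilon: float = 1e-10,
    min_train: int = 5,
) -> DenoiseResult:
    """Full noise-filtering pass over a lncRNA log matrix.

    Training-set membership is defined once on the full cell population,
    then intersected with the lncRNAs detected in each focal cell for
    fitting. Cells with untrainable classifiers or with mean CV AUC at or
    below ``min_auc`` are dropped (recorded in the summary); noise entries
    of retained cells are zeroed in the returned matrix.
    """
    if cv_folds < 2:
        raise ConfigurationError("cv_folds must be >= 2")
    sets = build_training_sets(lnc_log_m, pos_fraction, neg_max_cells)
    pos_ids = pd.Index(sets.positive_ids)
    neg_ids = pd.Index(sets.negative_ids)

    denoised = lnc_log_m.copy()
    calls_parts: list[pd.DataFrame] = []
    rows = []
    classifiers: dict[str, CellClassifier] = {}
    for i, cell in enumerate(lnc_log_m.columns):
        expr = lnc_log_m[cell]
        detected = expr.index[expr > 0]
        abundance = relative_abundance(expr[detected])
        coverage = exon_coverage_feature(cov_m, cell, detected.tolist())
        feats = pd.DataFrame({"abundance": abundance, "coverage": coverage})
        pos_in_cell = detected.intersection(pos_ids)
        neg_in_cell = detected.intersection(neg_ids)
        pos_pts = feats.loc[pos_in_cell].to_numpy()
        neg_pts = feats.loc[neg_in_cell].to_numpy()
        row = {
            "cell_id": cell,
            "n_pos": len(pos_in_cell),
            "n_neg": len(neg_in_cell),
            "mean_auc": np.nan,
            "cutoff": np.nan,
            "retained": False,
            "reason": "",
        }
        try:
            aucs = cross_validate_cell(
                pos_pts, neg_pts, k=cv_folds, seed=_cell_seed(seed, i),
                grid_resolution=grid_resolution, epsilon=epsilon,
            )
            clf = fit_cell_classifier(
                cell, pos_pts, neg_pts,
                grid_resolution=grid_resolution, epsilon=epsilon, min_train=min_train,
            )
        except ClassifierNotTrainableError as exc:
            row["reason"] = f"untrainable: {exc}"
            rows.append(row)
            continue
        clf.fold_aucs = aucs
        train_ratios = clf.likelihood_ratio(np.vstack([pos_pts, neg_pts]))
        train_labels = np.concatenate(
            [np.ones(len(pos_pts), dtype=bool), np.zeros(len(neg_pts), dtype=bool)]
        )
        clf.cutoff, _ = select_cutoff(train_ratios, train_labels)
        classifiers[cell] = clf
        row["mean_auc"] = clf.mean_auc
        row["cutoff"] = clf.cutoff
        if clf.mean_auc > min_auc:
            row["retained"] = True
        else:
            row["reason"] = f"mean CV AUC {clf.mean_auc:.3f} <= {min_auc}"
        rows.append(row)
        if not row["retained"]:
            continue
        cell_calls = apply_classifier(clf, feats.to_numpy(), detected.tolist())
        calls_parts.append(cell_calls)
        noisy = cell_calls.loc[cell_calls["label"] == "noise", "gene_id"]
        denoised.loc[noisy, cell] = 0.0

    summary = pd.DataFrame(rows).set_index("cell_id")
    retained = summary.index[summary["retained"]].tolist()
    if not retained:
        warnings_msg = "no cell passed the AUC gate; denoised matrix is empty"
        import warnings

        warnings.warn(warnings_msg, stacklevel=2)
    calls = (
        pd.concat(calls_parts, ignore_index=True)
        if calls_parts
        else pd.DataFrame(
            columns=["cell_id", "gene_id", "abundance", "coverage", "likelihood_ratio", "label"]
        )
    )
    return DenoiseResult(
        denoised=denoised[retained] if retained else denoised.iloc[:, :0],
        calls=calls,
        summary=summary,
        retained_cells=retained,
        classifiers=classifiers,
    )
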