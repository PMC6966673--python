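"""Per-cell gene-set scores: stemness, cell cycle, invasive potential.

All scores are plain averages of log2(TPM+1) over a gene set. The stemness
score subtracts the per-cell average over all genes, so it is invariant to
adding a constant to the whole matrix; its significance can be judged
against a null of equally sized random marker sets. Cells are grouped on
their invasion-score vectors by Ward clustering of standardized scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from ._errors import ConfigurationError, DataError

__all__ = [
    "GeneSet",
    "filter_gene_set",
    "set_score",
    "stemness_score",
    "random_marker_null",
    "invasion_scores",
    "cluster_cells",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    gene_ids: tuple[str, ...]
    role: str = ""  # stemness | g1s | g2m | invasion

    def __post_init__(self):
        if not self.gene_ids:
            raise DataError(f"gene set {self.name!r} is empty")


def filter_gene_set(log_m: pd.DataFrame, s: GeneSet) -> GeneSet:
    """Restrict a set to unique genes present in the matrix and expressed
    in at least one cell; genes with no expression anywhere are dropped."""
    seen = dict.fromkeys(s.gene_ids)
    present = [g for g in seen if g in log_m.index]
    expressed = [g for g in present if (log_m.loc[g] > 0).any()]
    if not expressed:
        raise DataError(f"gene set {s.name!r} has no expressed member in the matrix")
    return GeneSet(name=s.name, gene_ids=tuple(expressed), role=s.role)


def set_score(log_m: pd.DataFrame, s: GeneSet) -> pd.Series:
    """Mean log expression of the set's genes, per cell."""
    s = filter_gene_set(log_m, s)
    return log_m.loc[list(s.gene_ids)].mean(axis=0).rename(s.name)


def stemness_score(log_m: pd.DataFrame, markers: GeneSet) -> pd.Series:
    """Marker average minus the average over all genes, per cell."""
    marker_mean = set_score(log_m, markers)
    return (marker_mean - log_m.mean(axis=0)).rename(f"{markers.name}_stemness")


def random_marker_null(
    log_m: pd.DataFrame,
    set_size: int,
    n_sets: int = 1000,
    seed: int = 0,
    true_scores: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.Series | None]:
    """Stemness-score null from random marker sets of a given size.

    Sets are drawn without replacement from the genes expressed in at least
    one cell. Returns the (n_sets x cells) null score table and, when
    ``true_scores`` is given, the per-cell empirical percentile of the true
    score within its null.
    """
    eligible = log_m.index[(log_m > 0).any(axis=1)]
    if set_size > len(eligible):
        raise ConfigurationError(
            f"set_size {set_size} exceeds the {len(eligible)} expressed genes"
        )
    rng = np.random.default_rng(seed)
    global_mean = log_m.mean(axis=0)
    rows = []
    for i in range(n_sets):
        chosen = rng.choice(len(eligible), size=set_size, replace=False)
        rows.append(log_m.loc[eligible[chosen]].mean(axis=0) - global_mean)
    null = pd.DataFrame(rows, index=pd.RangeIndex(n_sets, name="null_set"))
    percentile = None
    if true_scores is not None:
        percentile = pd.Series(
            (null.le(true_scores, axis=1).sum(axis=0) / n_sets) * 100.0,
            name="stemness_percentile",
        )
    return null, percentile


def invasion_scores(log_m: pd.DataFrame, sets: list[GeneSet]) -> pd.DataFrame:
    """One score column per invasion gene set (cells x sets)."""
    if not sets:
        raise DataError("no invasion gene sets supplied")
    return pd.concat([set_score(log_m, s) for s in sets], axis=1)


def cluster_cells(scores: pd.DataFrame, k: int = 4) -> pd.Series:
    """Group cells on their score vectors.

    Score columns are standardized (zero-variance columns become zeros),
    then cells are clustered with Ward linkage on Euclidean distance and
    the tree is cut into ``k`` groups. Identical cells always share a
    label.
    """
    if scores.shape[0] < k:
        raise ConfigurationError(f"need at least k={k} cells, got {scores.shape[0]}")
    x = scores.to_numpy(dtype=float)
    sd = x.std(axis=0)
    centered = x - x.mean(axis=0)
    z = np.where(sd > 0, centered / np.where(sd > 0, sd, 1.0), 0.0)
    tree = linkage(z, method="ward")
    labels = fcluster(tree, t=k, criterion="maxclust")
    return pd.Series(labels, index=scores.index, name="cluster")
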