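"""Synthetic single-cell expression data with planted rare genes.

The generator emulates the statistical regimes every downstream stage
assumes, with ground-truth labels for parameter-recovery testing:

* log-normal baseline expression with a logistic dropout law, so that both
  detection proportions and non-zero expression averages are meaningful;
* a minority of "rare" genes whose non-zero expression is high but confined
  to a small, exactly known subset of (malignant) cells;
* lncRNAs split into genuinely expressed genes and sporadic low-abundance
  noise whose exon coverage is stochastically low;
* an additive log2 shift over a contiguous window of genomically adjacent
  genes in malignant cells, mimicking a copy-number amplification;
* a stem-like subpopulation overexpressing a designated marker set together
  with cell-cycle and invasion signature sets.

All randomness flows from a single integer seed through named sub-streams,
so e.g. gene-level draws are unchanged when only cell-level settings move.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

from ._errors import ConfigurationError

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticDataset",
    "generate_annotation",
    "generate_dataset",
    "generate_normal_reference",
]

# Sub-stream names, in a fixed order; each gets its own child SeedSequence.
_STREAMS = (
    "annotation",
    "gene_means",
    "baseline",
    "dropout",
    "rare",
    "noise",
    "coverage",
    "subpop",
    "reads",
    "normals",
)

_CYCLE_SET_SIZE = 30
_INVASION_SET_SIZE = 30
_N_INVASION_SETS = 4


@dataclass(frozen=True)
class SyntheticConfig:
    """Settings for one synthetic dataset.

    Expression parameters are on the log2(TPM+1) scale. The defaults
    describe a 300-cell, 2800-gene experiment pooled from four samples with
    20 planted rare genes present in 5% of cells, whose non-zero mean sits
    two baseline standard deviations above the baseline mean.
    """

    n_cells: int = 300
    n_samples: int = 4
    n_pcg: int = 2000
    n_lnc: int = 800
    n_chromosomes: int = 10
    base_log_mean: float = 1.5
    base_log_sd: float = 0.75
    dropout_midpoint: float = 1.0
    dropout_steepness: float = 2.0
    n_rare_genes: int = 20
    rare_cell_fraction: float = 0.05
    rare_log_mean: float = 3.0
    n_noise_lnc: int = 400
    noise_coverage_beta: tuple[float, float] = (2.0, 8.0)
    true_coverage_beta: tuple[float, float] = (8.0, 2.0)
    n_malignant: int = 240
    cnv_region_length: int = 300
    cnv_log2_shift: float = 1.0
    n_stemlike: int = 30
    stem_marker_count: int = 51
    stem_log2_shift: float = 1.5
    seed: int = 0

    @property
    def n_genes(self) -> int:
        return self.n_pcg + self.n_lnc

    def validate(self) -> None:
        """Raise :class:`ConfigurationError` naming the offending field."""
        positive = (
            "n_cells", "n_samples", "n_pcg", "n_lnc", "n_chromosomes",
            "n_malignant", "cnv_region_length", "stem_marker_count",
        )
        for name in positive:
            if int(getattr(self, name)) <= 0:
                raise ConfigurationError(f"{name} must be a positive count, got {getattr(self, name)}")
        for name in ("n_rare_genes", "n_noise_lnc", "n_stemlike"):
            if int(getattr(self, name)) < 0:
                raise ConfigurationError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.dropout_steepness <= 0:
            raise ConfigurationError("dropout_steepness must be > 0")
        if not (0.0 < self.rare_cell_fraction < 0.2):
            raise ConfigurationError(
                "rare_cell_fraction must lie in (0, 0.2); planted genes would "
                f"violate the rare definition at {self.rare_cell_fraction}"
            )
        if self.n_rare_genes > 0 and self.rare_cell_fraction * self.n_cells < 10:
            raise ConfigurationError(
                "rare_cell_fraction * n_cells must be >= 10 so planted genes "
                "survive the minimum-cell filter"
            )
        if self.n_rare_genes >= self.n_genes:
            raise ConfigurationError("n_rare_genes must be < n_pcg + n_lnc")
        if self.n_noise_lnc > self.n_lnc:
            raise ConfigurationError("n_noise_lnc must be <= n_lnc")
        if self.n_malignant > self.n_cells:
            raise ConfigurationError("n_malignant must be <= n_cells")
        if self.n_stemlike > self.n_malignant:
            raise ConfigurationError("n_stemlike must be <= n_malignant")
        if self.cnv_region_length >= self.n_genes:
            raise ConfigurationError("cnv_region_length must be < total gene count")
        for name in ("noise_coverage_beta", "true_coverage_beta"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ConfigurationError(f"{name} shape parameters must be > 0")
        if (
            self.n_rare_genes > 0
            and round(self.rare_cell_fraction * self.n_cells) > self.n_malignant
        ):
            raise ConfigurationError(
                "rare_cell_fraction * n_cells exceeds n_malignant; rare genes "
                "are planted in malignant cells"
            )

    def streams(self) -> dict[str, np.random.Generator]:
        """Named, independent random generators derived from ``seed``."""
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


@dataclass
class GroundTruth:
    """Planted structure of a synthetic dataset."""

    rare_gene_ids: set[str]
    noise_lnc_ids: set[str]
    malignant_cell_ids: set[str]
    stemlike_cell_ids: set[str]
    noise_entry_mask: pd.DataFrame  # genes x cells, bool; True only on lncRNA rows
    cnv_region_gene_ids: list[str] = field(default_factory=list)


@dataclass
class SyntheticDataset:
    """One generated experiment: matrix (TPM), annotation, cell metadata,
    per-entry exon coverage, ground truth and the emitted gene sets."""

    matrix: pd.DataFrame          # genes x cells, TPM
    annotation: pd.DataFrame      # gene_id index; biotype/chrom/start/strand/n_exons
    cells: pd.DataFrame           # cell_id index; sample_id, aligned_reads
    coverage: pd.DataFrame        # genes x cells in [0, 1]
    truth: GroundTruth
    gene_sets: dict[str, list[str]]

    def __iter__(self) -> Iterator:
        return iter((self.matrix, self.annotation, self.cells, self.coverage, self.truth))


def generate_annotation(cfg: SyntheticConfig) -> pd.DataFrame:
    """Gene annotation table in genomic order.

    PCGs and lncRNAs are interleaved at random along ``n_chromosomes``
    chromosomes, with strictly increasing start coordinates within each
    chromosome. Exon counts are Poisson-distributed (PCGs richer in exons
    than lncRNAs), floored at one.
    """
    cfg.validate()
    rng = cfg.streams()["annotation"]
    n = cfg.n_genes
    ids = np.array(
        [f"PCG{i + 1:05d}" for i in range(cfg.n_pcg)]
        + [f"LNC{i + 1:05d}" for i in range(cfg.n_lnc)]
    )
    biotype = np.array(["PCG"] * cfg.n_pcg + ["lncRNA"] * cfg.n_lnc)
    genome_order = rng.permutation(n)
    ids, biotype = ids[genome_order], biotype[genome_order]

    # near-even chromosome sizes
    sizes = np.full(cfg.n_chromosomes, n // cfg.n_chromosomes)
    sizes[: n % cfg.n_chromosomes] += 1
    chroms = np.repeat([f"chr{i + 1}" for i in range(cfg.n_chromosomes)], sizes)
    starts = np.empty(n, dtype=np.int64)
    pos = 0
    for size in sizes:
        gaps = rng.integers(1_000, 100_000, size=size)
        starts[pos: pos + size] = np.cumsum(gaps)
        pos += size
    exons = np.where(
        biotype == "PCG",
        rng.poisson(8, size=n) + 1,
        rng.poisson(2, size=n) + 1,
    )
    strand = rng.choice(["+", "-"], size=n)
    ann = pd.DataFrame(
        {
            "biotype": biotype,
            "chrom": chroms,
            "start": starts,
            "strand": strand,
            "n_exons": exons,
        },
        index=pd.Index(ids, name="gene_id"),
    )
    return ann


def _log_to_tpm(log_values: np.ndarray) -> np.ndarray:
    """Invert log2(TPM + 1); exact zeros map back to exact zeros."""
    return np.exp2(log_values) - 1.0


@dataclass
class _Cast:
    """Planted structure selected from the named streams; shared between the
    cell-matrix and normal-reference generators so both agree on which genes
    are rare/noise."""

    malignant_idx: np.ndarray
    stem_idx: np.ndarray
    cnv_idx: np.ndarray
    noise_idx: np.ndarray
    rare_idx: np.ndarray
    stem_set: np.ndarray
    g1s_set: np.ndarray
    g2m_set: np.ndarray
    invasion_sets: list[np.ndarray]


def _check_gene_budget(cfg: SyntheticConfig) -> None:
    n_reserved = (
        cfg.n_rare_genes + cfg.stem_marker_count
        + 2 * _CYCLE_SET_SIZE + _N_INVASION_SETS * _INVASION_SET_SIZE
    )
    if n_reserved > cfg.n_pcg + cfg.n_lnc - cfg.n_noise_lnc:
        raise ConfigurationError(
            "not enough genes to host rare genes plus signature sets; "
            "increase n_pcg/n_lnc or shrink the planted structure"
        )


def _select_cast(cfg: SyntheticConfig, ann: pd.DataFrame, streams) -> _Cast:
    n_genes, n_cells = cfg.n_genes, cfg.n_cells
    rng_sub = streams["subpop"]
    malignant_idx = np.sort(rng_sub.choice(n_cells, size=cfg.n_malignant, replace=False))
    stem_idx = np.sort(rng_sub.choice(malignant_idx, size=cfg.n_stemlike, replace=False))
    cnv_start = int(rng_sub.integers(0, n_genes - cfg.cnv_region_length + 1))
    cnv_idx = np.arange(cnv_start, cnv_start + cfg.cnv_region_length)

    rng_noise = streams["noise"]
    lnc_pos = np.flatnonzero(ann["biotype"].to_numpy() == "lncRNA")
    pcg_pos = np.flatnonzero(ann["biotype"].to_numpy() == "PCG")
    noise_idx = np.sort(rng_noise.choice(lnc_pos, size=cfg.n_noise_lnc, replace=False))

    rng_rare = streams["rare"]
    n_rare_lnc = min(cfg.n_rare_genes // 2, cfg.n_lnc - cfg.n_noise_lnc)
    n_rare_pcg = cfg.n_rare_genes - n_rare_lnc
    free_lnc = np.setdiff1d(lnc_pos, noise_idx)
    rare_idx = np.sort(
        np.concatenate(
            [
                rng_rare.choice(pcg_pos, size=n_rare_pcg, replace=False),
                rng_rare.choice(free_lnc, size=n_rare_lnc, replace=False),
            ]
        ).astype(int)
    )

    # signature sets drawn from PCGs not used for rare genes
    free_pcg = np.setdiff1d(pcg_pos, rare_idx)
    rng_sub.shuffle(free_pcg)
    cursor = 0

    def _take(k: int) -> np.ndarray:
        nonlocal cursor
        out = free_pcg[cursor: cursor + k]
        cursor += k
        return np.sort(out)

    return _Cast(
        malignant_idx=malignant_idx,
        stem_idx=stem_idx,
        cnv_idx=cnv_idx,
        noise_idx=noise_idx,
        rare_idx=rare_idx,
        stem_set=_take(cfg.stem_marker_count),
        g1s_set=_take(_CYCLE_SET_SIZE),
        g2m_set=_take(_CYCLE_SET_SIZE),
        invasion_sets=[_take(_INVASION_SET_SIZE) for _ in range(_N_INVASION_SETS)],
    )


def generate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate one complete synthetic experiment.

    Every planted rare gene is non-zero in exactly
    ``round(rare_cell_fraction * n_cells)`` malignant cells (an exact count,
    not a Bernoulli draw, so recovery tests have crisp truth) and zero
    elsewhere. Noise lncRNAs carry only sporadic low entries, flagged in the
    ground-truth mask, whose exon coverage is drawn from the noise Beta law.
    """
    cfg.validate()
    _check_gene_budget(cfg)
    streams = cfg.streams()
    ann = generate_annotation(cfg)
    gene_ids = ann.index.to_numpy()
    n_genes, n_cells = cfg.n_genes, cfg.n_cells

    cell_ids = np.array([f"CELL{i + 1:04d}" for i in range(n_cells)])
    sample_ids = np.array(
        [f"S{(i % cfg.n_samples) + 1}" for i in range(n_cells)]
    )
    aligned_reads = streams["reads"].integers(250_000, 2_000_001, size=n_cells)

    # --- per-gene means, shared with the normal-reference generator
    mu = streams["gene_means"].normal(cfg.base_log_mean, cfg.base_log_sd, size=n_genes)

    cast = _select_cast(cfg, ann, streams)
    malignant_idx, stem_idx, cnv_idx = cast.malignant_idx, cast.stem_idx, cast.cnv_idx
    noise_idx, rare_idx = cast.noise_idx, cast.rare_idx
    stem_set, g1s_set, g2m_set = cast.stem_set, cast.g1s_set, cast.g2m_set
    invasion_sets = cast.invasion_sets
    rng_noise = streams["noise"]
    rng_rare = streams["rare"]

    # --- latent log2 expression
    latent = streams["baseline"].normal(mu[:, None], cfg.base_log_sd, size=(n_genes, n_cells))
    if cfg.cnv_log2_shift != 0.0:
        latent[np.ix_(cnv_idx, malignant_idx)] += cfg.cnv_log2_shift
    if cfg.stem_log2_shift != 0.0 and len(stem_idx):
        boosted = np.concatenate([stem_set, g1s_set, g2m_set, *invasion_sets])
        latent[np.ix_(boosted, stem_idx)] += cfg.stem_log2_shift
    np.maximum(latent, 0.0, out=latent)

    # logistic dropout on detection probability
    p_detect = 1.0 / (1.0 + np.exp(-cfg.dropout_steepness * (latent - cfg.dropout_midpoint)))
    latent *= streams["dropout"].random(size=latent.shape) < p_detect

    # --- plant rare genes: exact cell counts, confined to malignant cells
    k_rare = int(round(cfg.rare_cell_fraction * n_cells))
    for gi in rare_idx:
        latent[gi, :] = 0.0
        cells_gi = rng_rare.choice(malignant_idx, size=k_rare, replace=False)
        vals = rng_rare.normal(cfg.rare_log_mean, 0.3, size=k_rare)
        latent[gi, cells_gi] = np.maximum(vals, 0.1)

    # --- noise lncRNAs: 1-2 sporadic low entries each
    noise_mask = np.zeros((n_genes, n_cells), dtype=bool)
    for gi in noise_idx:
        latent[gi, :] = 0.0
        k = int(rng_noise.integers(1, 3))
        cells_gi = rng_noise.choice(n_cells, size=k, replace=False)
        latent[gi, cells_gi] = np.abs(rng_noise.normal(0.6, 0.2, size=k)) + 0.05
        noise_mask[gi, cells_gi] = True

    # --- exon coverage: genuine vs noise Beta laws
    a_t, b_t = cfg.true_coverage_beta
    a_n, b_n = cfg.noise_coverage_beta
    coverage = streams["coverage"].beta(a_t, b_t, size=(n_genes, n_cells))
    coverage[noise_mask] = streams["coverage"].beta(a_n, b_n, size=int(noise_mask.sum()))

    matrix = pd.DataFrame(_log_to_tpm(latent), index=ann.index, columns=cell_ids)
    cells = pd.DataFrame(
        {"sample_id": sample_ids, "aligned_reads": aligned_reads},
        index=pd.Index(cell_ids, name="cell_id"),
    )
    truth = GroundTruth(
        rare_gene_ids=set(gene_ids[rare_idx]),
        noise_lnc_ids=set(gene_ids[noise_idx]),
        malignant_cell_ids=set(cell_ids[malignant_idx]),
        stemlike_cell_ids=set(cell_ids[stem_idx]),
        noise_entry_mask=pd.DataFrame(noise_mask, index=ann.index, columns=cell_ids),
        cnv_region_gene_ids=list(gene_ids[cnv_idx]),
    )
    gene_sets = {
        "stemness": list(gene_ids[stem_set]),
        "g1s": list(gene_ids[g1s_set]),
        "g2m": list(gene_ids[g2m_set]),
    }
    for j, s in enumerate(invasion_sets, start=1):
        gene_sets[f"invasion{j}"] = list(gene_ids[s])
    return SyntheticDataset(matrix, ann, cells, pd.DataFrame(coverage, index=ann.index, columns=cell_ids), truth, gene_sets)


def generate_normal_reference(
    cfg: SyntheticConfig, n_reference: int = 5, tissue_log_sd: float = 0.25
) -> pd.DataFrame:
    """Bulk-like normal samples (genes x samples, TPM) for CNV referencing.

    Shares the per-gene mean stream with :func:`generate_dataset`, so the
    reference tracks the same baseline expression landscape without CNV,
    dropout or planted subpopulations — plus a per-gene offset of standard
    deviation ``tissue_log_sd`` emulating the expression difference between
    the tumor and the normal reference tissue. Tumor-specific rare genes and
    artifact (noise) lncRNAs are absent from the normal tissue.
    """
    cfg.validate()
    _check_gene_budget(cfg)
    if n_reference < 1:
        raise ConfigurationError("n_reference must be >= 1")
    streams = cfg.streams()
    ann = generate_annotation(cfg)
    mu = streams["gene_means"].normal(cfg.base_log_mean, cfg.base_log_sd, size=cfg.n_genes)
    cast = _select_cast(cfg, ann, streams)
    rng = streams["normals"]
    tissue = mu + rng.normal(0.0, tissue_log_sd, size=cfg.n_genes)
    log_vals = rng.normal(tissue[:, None], 0.2, size=(cfg.n_genes, n_reference))
    np.maximum(log_vals, 0.0, out=log_vals)
    log_vals[cast.rare_idx, :] = 0.0
    log_vals[cast.noise_idx, :] = 0.0
    cols = [f"NORM{i + 1}" for i in range(n_reference)]
    return pd.DataFrame(_log_to_tpm(log_vals), index=ann.index, columns=cols)


def config_with(cfg: SyntheticConfig, **overrides) -> SyntheticConfig:
    """Convenience: a modified copy that is re-validated on use."""
    return replace(cfg, **overrides)
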