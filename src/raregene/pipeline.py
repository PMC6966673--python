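"""End-to-end orchestration: QC -> malignancy -> denoising -> discovery -> scores.

Each stage writes its outputs into the run directory and never mutates an
upstream artifact; a run manifest records the configuration hash, seed and
per-stage cell/gene counts. Stages whose inputs are absent (no normal
samples, no coverage matrix) are skipped with a loud warning and downstream
stages run on the unreduced data.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, cnv, io, noise, rare, scores
from ._errors import ConfigurationError, DataError
from .preprocess import ExpressionMatrix, filter_low_pcgs, qc_filter_cells

logger = logging.getLogger("raregene")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All inputs and thresholds for one pipeline run."""

    matrix: str = ""
    annotation: str = ""
    cells: str = ""
    normals: str = ""            # optional: genes x samples TPM for CNV reference
    coverage: str = ""           # optional: genes x cells exon coverage in [0, 1]
    gene_sets: dict[str, str] = field(default_factory=dict)  # role -> path
    outdir: str = "raregene_run"
    matrix_format: str = "dense"  # dense | mtx

    min_reads: int = 200_000
    min_genes: int = 3000
    pcg_min_cells: int = 2
    pcg_expr_threshold: float = 1.0
    cnv_window: int = 100
    cnv_k: int = 2
    pos_fraction: float = 0.8
    neg_max_cells: int = 2
    cv_folds: int = 5
    min_auc: float = 0.8
    n_perm: int = 1000
    shuffle_mode: str = "global"
    rare_min_cells: int = 10
    max_sample_prop: float = 0.2
    quartile: float = 0.75
    max_prop: float = 0.2
    score_k: int = 4
    seed: int = 0

    def validate(self) -> None:
        if not self.matrix:
            raise ConfigurationError("no expression matrix configured")
        for name in ("min_reads", "min_genes", "pcg_min_cells", "cv_folds",
                     "n_perm", "rare_min_cells", "cnv_window", "cnv_k", "score_k"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        for name, lo, hi in (
            ("pos_fraction", 0.0, 1.0),
            ("min_auc", 0.0, 1.0),
            ("max_sample_prop", 0.0, 1.0),
            ("quartile", 0.0, 1.0),
            ("max_prop", 0.0, 1.0),
        ):
            if not (lo <= getattr(self, name) <= hi):
                raise ConfigurationError(f"{name} must lie in [{lo}, {hi}]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    def digest(self) -> str:
        canon = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _load_matrix(cfg: RunConfig) -> ExpressionMatrix:
    if cfg.matrix_format == "dense":
        tpm = io.read_matrix_tsv(cfg.matrix)
    elif cfg.matrix_format == "mtx":
        tpm = io.read_matrix_mtx(cfg.matrix)
    else:
        raise ConfigurationError(f"unknown matrix_format {cfg.matrix_format!r}")
    return ExpressionMatrix(tpm)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns the run manifest (also written to disk)."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "raregene",
        "version": __version__,
        "config_hash": cfg.digest(),
        "seed": cfg.seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }
    cfg.to_yaml(outdir / "config.yaml")

    # --- preprocess -------------------------------------------------------
    m = _load_matrix(cfg)
    ann = io.read_annotation(cfg.annotation)
    cells = io.read_cells(cfg.cells)
    retained_cells, cell_table = qc_filter_cells(m, cells, cfg.min_reads, cfg.min_genes)
    if not retained_cells:
        raise DataError("preprocess: no cell passed QC; check min_reads/min_genes")
    m_qc = m.subset(cells=retained_cells)
    retained_genes = filter_low_pcgs(m_qc, ann, cfg.pcg_min_cells, cfg.pcg_expr_threshold)
    m_qc = m_qc.subset(genes=retained_genes)
    io.write_cells(cell_table, outdir / "qc_cells.tsv")
    manifest["stages"]["preprocess"] = {
        "cells_in": int(m.shape[1]), "cells_out": len(retained_cells),
        "genes_in": int(m.shape[0]), "genes_out": len(retained_genes),
    }
    logger.info("preprocess: %d/%d cells, %d/%d genes retained",
                len(retained_cells), m.shape[1], len(retained_genes), m.shape[0])

    # --- cnv / malignancy -------------------------------------------------
    if cfg.normals:
        order = cnv.order_genes(ann.loc[m_qc.gene_ids])
        profiles = cnv.infer_cnv(m_qc.log2, order, cfg.cnv_window)
        normals = ExpressionMatrix(io.read_matrix_tsv(cfg.normals)).subset(genes=order)
        reference = cnv.build_reference(normals.log2, order, cfg.cnv_window)
        calls = cnv.call_malignant(profiles, reference, k=cfg.cnv_k)
        profiles.to_csv(outdir / "cnv_profiles.tsv", sep="\t", index_label="gene_id")
        calls.to_frame().to_csv(outdir / "malignant_calls.tsv", sep="\t", index_label="cell_id")
        malignant_cells = calls.index[calls].tolist()
        if not malignant_cells:
            raise DataError("cnv: every cell clustered with the normal reference")
        m_qc = m_qc.subset(cells=malignant_cells)
        manifest["stages"]["cnv"] = {
            "cells_in": len(calls), "cells_out": len(malignant_cells),
            "n_non_malignant": int((~calls).sum()),
        }
    else:
        logger.warning("cnv: no normal samples configured; malignancy calling SKIPPED")
        manifest["stages"]["cnv"] = {"skipped": "no normals supplied"}

    # --- lncRNA noise filtering ------------------------------------------
    biotype = ann.loc[m_qc.gene_ids, "biotype"]
    lnc_ids = m_qc.gene_ids[biotype == "lncRNA"]
    if cfg.coverage and len(lnc_ids):
        cov = io.read_matrix_tsv(cfg.coverage)
        result = noise.denoise(
            m_qc.log2.loc[lnc_ids], cov,
            pos_fraction=cfg.pos_fraction, neg_max_cells=cfg.neg_max_cells,
            cv_folds=cfg.cv_folds, min_auc=cfg.min_auc, seed=cfg.seed,
        )
        result.summary.to_csv(outdir / "classifier_summary.tsv", sep="\t")
        result.calls.to_csv(outdir / "lnc_calls.tsv", sep="\t", index=False)
        if not result.retained_cells:
            raise DataError("denoise: no cell passed the AUC gate")
        m_qc = m_qc.subset(cells=result.retained_cells)
        log_view = m_qc.log2.copy()
        log_view.loc[lnc_ids] = result.denoised.loc[lnc_ids, result.retained_cells]
        manifest["stages"]["denoise"] = {
            "cells_in": int(result.summary.shape[0]),
            "cells_out": len(result.retained_cells),
            "noise_calls": int((result.calls["label"] == "noise").sum()),
            "expressed_calls": int((result.calls["label"] == "expressed").sum()),
        }
    else:
        if not cfg.coverage:
            logger.warning("denoise: no coverage matrix configured; noise filtering "
                           "SKIPPED, downstream runs on undenoised lncRNAs")
        log_view = m_qc.log2
        manifest["stages"]["denoise"] = {"skipped": "no coverage supplied"}
    io.write_matrix_tsv(log_view, outdir / "log_matrix.tsv")

    # --- rare-gene discovery ---------------------------------------------
    sample_ids = cells.loc[log_view.columns, "sample_id"]
    stats = rare.gene_stats(log_view, sample_ids, biotype=biotype)
    nulls = rare.permutation_null(log_view, cfg.n_perm, cfg.seed, cfg.shuffle_mode)
    calls = rare.identify_rare_genes(stats, nulls, cfg.rare_min_cells, cfg.max_sample_prop)
    screened, screen_summary = rare.quartile_screen(stats, cfg.max_prop, cfg.quartile)
    calls.to_csv(outdir / "rare_calls.tsv", sep="\t", index_label="gene_id")
    screened[["biotype", "avg_nonzero", "cell_proportion", "flagged"]].to_csv(
        outdir / "quartile_screen.tsv", sep="\t", index_label="gene_id")
    rare_ids = calls.index[calls["passed"]]
    manifest["stages"]["discover"] = {
        "n_perm": cfg.n_perm,
        "expr_threshold": nulls.expr_threshold,
        "prop_threshold": nulls.prop_threshold,
        "n_rare": int(len(rare_ids)),
        "n_rare_pcg": int((calls.loc[rare_ids, "biotype"] == "PCG").sum()),
        "n_rare_lnc": int((calls.loc[rare_ids, "biotype"] == "lncRNA").sum()),
        "quartile_screen": screen_summary,
    }
    logger.info("discover: %d rare genes", len(rare_ids))

    # --- signature scores -------------------------------------------------
    if cfg.gene_sets:
        table = pd.DataFrame(index=log_view.columns)
        loaded = {
            role: scores.GeneSet(role, tuple(io.read_gene_set(path)), role)
            for role, path in cfg.gene_sets.items()
        }
        if "stemness" in loaded:
            stem = scores.stemness_score(log_view, loaded["stemness"])
            table["stemness"] = stem
        for role in ("g1s", "g2m"):
            if role in loaded:
                table[role] = scores.set_score(log_view, loaded[role])
        inv_sets = [loaded[r] for r in sorted(loaded) if r.startswith("invasion")]
        if inv_sets:
            inv = scores.invasion_scores(log_view, inv_sets)
            table = pd.concat([table, inv], axis=1)
            table["invasion_cluster"] = scores.cluster_cells(inv, k=cfg.score_k)
        table.to_csv(outdir / "scores.tsv", sep="\t", index_label="cell_id")
        manifest["stages"]["scores"] = {"columns": list(table.columns)}
    else:
        manifest["stages"]["scores"] = {"skipped": "no gene sets supplied"}

    io.write_json(manifest, outdir / "manifest.json")
    return manifest
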