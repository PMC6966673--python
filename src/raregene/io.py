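"""Readers and writers for the plain-text formats used by the pipeline.

Expression matrices travel either as dense TSV (gene rows, cell columns) or
as Matrix Market triplets with sidecar row/column name files. Annotation,
cell metadata, ground truth and tabular stage outputs are TSV with a header
line; gene sets are one-gene-per-line text files.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from scipy import io as spio
from scipy import sparse

from ._errors import DataError
from .synthetic import GroundTruth, SyntheticDataset

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_matrix_mtx",
    "write_matrix_mtx",
    "read_annotation",
    "write_annotation",
    "read_cells",
    "write_cells",
    "read_gene_set",
    "write_gene_set",
    "write_dataset",
    "read_truth",
]


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    return df


def write_matrix_tsv(m: pd.DataFrame, path: str | Path) -> None:
    m.to_csv(path, sep="\t", index_label="gene_id")


def write_matrix_mtx(m: pd.DataFrame, prefix: str | Path) -> None:
    """Write ``<prefix>.mtx`` plus ``<prefix>.genes.txt`` / ``<prefix>.cells.txt``."""
    prefix = Path(prefix)
    spio.mmwrite(str(prefix.with_suffix(".mtx")), sparse.csr_matrix(m.to_numpy()))
    prefix.with_suffix(".genes.txt").write_text("\n".join(m.index) + "\n")
    prefix.with_suffix(".cells.txt").write_text("\n".join(m.columns) + "\n")


def read_matrix_mtx(prefix: str | Path) -> pd.DataFrame:
    prefix = Path(prefix)
    mtx = prefix.with_suffix(".mtx")
    if not mtx.exists():
        raise DataError(f"sparse matrix file not found: {mtx}")
    values = sparse.coo_matrix(spio.mmread(str(mtx))).toarray()
    genes = prefix.with_suffix(".genes.txt").read_text().splitlines()
    cells = prefix.with_suffix(".cells.txt").read_text().splitlines()
    if values.shape != (len(genes), len(cells)):
        raise DataError(
            f"matrix shape {values.shape} does not match sidecar names "
            f"({len(genes)} genes, {len(cells)} cells)"
        )
    return pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=cells)


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col="gene_id")
    required = {"biotype", "chrom", "start", "strand", "n_exons"}
    missing = required - set(ann.columns)
    if missing:
        raise DataError(f"annotation lacks columns: {sorted(missing)}")
    return ann


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, sep="\t", index_label="gene_id")


def read_cells(path: str | Path) -> pd.DataFrame:
    cells = pd.read_csv(path, sep="\t", index_col="cell_id")
    if "sample_id" not in cells.columns:
        raise DataError("cell metadata lacks a 'sample_id' column")
    return cells


def write_cells(cells: pd.DataFrame, path: str | Path) -> None:
    cells.to_csv(path, sep="\t", index_label="cell_id")


def read_gene_set(path: str | Path) -> list[str]:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    genes = [ln for ln in lines if ln and not ln.startswith("#")]
    if not genes:
        raise DataError(f"gene-set file {path} is empty")
    return genes


def write_gene_set(genes: list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def write_dataset(ds: SyntheticDataset, outdir: str | Path, fmt: str = "dense") -> None:
    """Write a synthetic dataset (and its ground truth) under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if fmt == "dense":
        write_matrix_tsv(ds.matrix, outdir / "matrix.tsv")
    elif fmt == "mtx":
        write_matrix_mtx(ds.matrix, outdir / "matrix")
    else:
        raise DataError(f"unknown matrix format {fmt!r}")
    write_annotation(ds.annotation, outdir / "annotation.tsv")
    write_cells(ds.cells, outdir / "cells.tsv")
    write_matrix_tsv(ds.coverage, outdir / "coverage.tsv")
    sets_dir = outdir / "gene_sets"
    sets_dir.mkdir(exist_ok=True)
    for name, genes in ds.gene_sets.items():
        write_gene_set(genes, sets_dir / f"{name}.txt")
    truth = ds.truth
    labels = pd.DataFrame(
        [("rare_gene", g) for g in sorted(truth.rare_gene_ids)]
        + [("noise_lnc", g) for g in sorted(truth.noise_lnc_ids)]
        + [("malignant_cell", c) for c in sorted(truth.malignant_cell_ids)]
        + [("stemlike_cell", c) for c in sorted(truth.stemlike_cell_ids)]
        + [("cnv_region_gene", g) for g in truth.cnv_region_gene_ids],
        columns=["kind", "id"],
    )
    labels.to_csv(outdir / "truth_labels.tsv", sep="\t", index=False)
    mask = truth.noise_entry_mask
    rows, cols = mask.to_numpy().nonzero()
    pd.DataFrame(
        {"gene_id": mask.index[rows], "cell_id": mask.columns[cols]}
    ).to_csv(outdir / "truth_noise_entries.tsv", sep="\t", index=False)


def read_truth(outdir: str | Path, gene_ids: pd.Index, cell_ids: pd.Index) -> GroundTruth:
    """Reload ground truth written by :func:`write_dataset`."""
    outdir = Path(outdir)
    labels = pd.read_csv(outdir / "truth_labels.tsv", sep="\t")
    by_kind = {k: set(v["id"]) for k, v in labels.groupby("kind")}
    entries = pd.read_csv(outdir / "truth_noise_entries.tsv", sep="\t")
    mask = pd.DataFrame(False, index=gene_ids, columns=cell_ids)
    for g, c in zip(entries["gene_id"], entries["cell_id"]):
        mask.at[g, c] = True
    cnv_genes = labels.loc[labels["kind"] == "cnv_region_gene", "id"].tolist()
    return GroundTruth(
        rare_gene_ids=by_kind.get("rare_gene", set()),
        noise_lnc_ids=by_kind.get("noise_lnc", set()),
        malignant_cell_ids=by_kind.get("malignant_cell", set()),
        stemlike_cell_ids=by_kind.get("stemlike_cell", set()),
        noise_entry_mask=mask,
        cnv_region_gene_ids=cnv_genes,
    )


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
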