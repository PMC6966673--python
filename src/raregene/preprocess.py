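"""Loading, QC and log transformation of expression matrices.

Expression is handled as TPM (transcripts per million) in a genes x cells
table; all analysis happens on the log2(TPM + 1) view. "Detected" means
log2(TPM + 1) > 0, i.e. TPM > 0. Cell QC excludes cells with fewer than
``min_reads`` aligned reads or fewer than ``min_genes`` detected genes;
thresholds are exclusive, so boundary values pass.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._errors import DataError

__all__ = [
    "ExpressionMatrix",
    "log_transform",
    "detected_genes_per_cell",
    "qc_filter_cells",
    "filter_low_pcgs",
]


class ExpressionMatrix:
    """Genes x cells TPM matrix with named axes and a log2(TPM+1) view.

    Parameters
    ----------
    tpm
        Non-negative, finite matrix with unique gene and cell identifiers.
    """

    def __init__(self, tpm: pd.DataFrame):
        if tpm.index.has_duplicates:
            dup = tpm.index[tpm.index.duplicated()][0]
            raise DataError(f"duplicate gene id {dup!r}")
        if tpm.columns.has_duplicates:
            dup = tpm.columns[tpm.columns.duplicated()][0]
            raise DataError(f"duplicate cell id {dup!r}")
        values = tpm.to_numpy(dtype=float)
        bad = ~np.isfinite(values)
        if bad.any():
            g, c = np.argwhere(bad)[0]
            raise DataError(f"non-finite TPM at gene {tpm.index[g]!r}, cell {tpm.columns[c]!r}")
        neg = values < 0
        if neg.any():
            g, c = np.argwhere(neg)[0]
            raise DataError(f"negative TPM at gene {tpm.index[g]!r}, cell {tpm.columns[c]!r}")
        self.tpm = tpm.astype(float)
        self._log: pd.DataFrame | None = None

    @property
    def gene_ids(self) -> pd.Index:
        return self.tpm.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.tpm.columns

    @property
    def log2(self) -> pd.DataFrame:
        """log2(TPM + 1) view, computed lazily and cached."""
        if self._log is None:
            self._log = log_transform(self.tpm)
        return self._log

    def subset(self, genes=None, cells=None) -> "ExpressionMatrix":
        tpm = self.tpm
        if genes is not None:
            tpm = tpm.loc[list(genes)]
        if cells is not None:
            tpm = tpm[list(cells)]
        return ExpressionMatrix(tpm)

    @property
    def shape(self) -> tuple[int, int]:
        return self.tpm.shape


def log_transform(tpm: pd.DataFrame) -> pd.DataFrame:
    """log2(TPM + 1), entrywise; raises :class:`DataError` with coordinates
    on any negative entry."""
    values = tpm.to_numpy(dtype=float)
    neg = values < 0
    if neg.any():
        g, c = np.argwhere(neg)[0]
        raise DataError(f"negative TPM at gene {tpm.index[g]!r}, cell {tpm.columns[c]!r}")
    return pd.DataFrame(np.log2(values + 1.0), index=tpm.index, columns=tpm.columns)


def detected_genes_per_cell(log_m: pd.DataFrame) -> pd.Series:
    """Number of genes with log2(TPM+1) > 0 in each cell."""
    return (log_m > 0).sum(axis=0)


def qc_filter_cells(
    m: ExpressionMatrix,
    cells: pd.DataFrame,
    min_reads: int = 200_000,
    min_genes: int = 3000,
) -> tuple[list[str], pd.DataFrame]:
    """Cell-level QC.

    Retains exactly the cells with ``aligned_reads >= min_reads`` and
    ``detected_genes >= min_genes`` (exclusion is "less than", so boundary
    cells pass). Returns the retained cell ids and an updated copy of the
    metadata table with ``detected_genes`` and ``qc_pass`` columns.
    """
    missing = m.cell_ids.difference(cells.index)
    if len(missing):
        raise DataError(f"no metadata row for matrix cell {missing[0]!r}")
    if "aligned_reads" not in cells.columns:
        raise DataError("cell metadata lacks an 'aligned_reads' column")
    out = cells.loc[m.cell_ids].copy()
    out["detected_genes"] = detected_genes_per_cell(m.log2)
    out["qc_pass"] = (out["aligned_reads"] >= min_reads) & (out["detected_genes"] >= min_genes)
    retained = out.index[out["qc_pass"]].tolist()
    return retained, out


def filter_low_pcgs(
    m: ExpressionMatrix,
    ann: pd.DataFrame,
    min_cells: int = 2,
    expr_threshold: float = 1.0,
) -> list[str]:
    """Gene-level filter for protein-coding genes.

    A PCG is retained iff at least ``min_cells`` cells show
    log2(TPM+1) strictly greater than ``expr_threshold``. lncRNAs (and any
    gene without annotation biotype "PCG") are untouched by this filter and
    always retained.
    """
    missing = m.gene_ids.difference(ann.index)
    if len(missing):
        raise DataError(f"no annotation row for gene {missing[0]!r}")
    biotype = ann.loc[m.gene_ids, "biotype"]
    is_pcg = (biotype == "PCG").to_numpy()
    n_high = (m.log2.to_numpy() > expr_threshold).sum(axis=1)
    keep = ~is_pcg | (n_high >= min_cells)
    return m.gene_ids[keep].tolist()
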