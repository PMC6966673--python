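import numpy as np
import pandas as pd
import pytest

from raregene.preprocess import ExpressionMatrix
from raregene.synthetic import SyntheticConfig, generate_dataset


def tiny_config(**overrides) -> SyntheticConfig:
    """A config small enough for per-test generation (~1s)."""
    base = dict(
        n_cells=60,
        n_samples=4,
        n_pcg=300,
        n_lnc=200,
        n_chromosomes=4,
        n_rare_genes=6,
        rare_cell_fraction=0.17,
        n_noise_lnc=80,
        n_malignant=48,
        cnv_region_length=100,
        cnv_log2_shift=1.0,
        n_stemlike=8,
        stem_marker_count=20,
        seed=0,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


def classifier_config(**overrides) -> SyntheticConfig:
    """More lncRNAs than cells, so every cell sees enough negative
    training points for the noise classifier."""
    base = dict(
        n_cells=60,
        n_samples=4,
        n_pcg=200,
        n_lnc=800,
        n_chromosomes=4,
        n_rare_genes=2,
        rare_cell_fraction=0.18,
        n_noise_lnc=400,
        n_malignant=48,
        cnv_region_length=100,
        n_stemlike=6,
        stem_marker_count=20,
        seed=0,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def tiny_dataset():
    return generate_dataset(tiny_config())


@pytest.fixture(scope="session")
def tiny_matrix(tiny_dataset):
    return ExpressionMatrix(tiny_dataset.matrix)


def matrix_from_log(log_values, gene_ids=None, cell_ids=None) -> pd.DataFrame:
    """TPM DataFrame whose log2(TPM+1) view equals ``log_values``."""
    log_values = np.asarray(log_values, dtype=float)
    genes = gene_ids or [f"G{i}" for i in range(log_values.shape[0])]
    cells = cell_ids or [f"C{j}" for j in range(log_values.shape[1])]
    return pd.DataFrame(np.exp2(log_values) - 1.0, index=genes, columns=cells)
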