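"""Gene statistics, permutation nulls and rare-gene calls."""

import numpy as np
import pandas as pd
import pytest

from raregene import ConfigurationError, DataError, rare

from conftest import matrix_from_log


def _samples(cells, mapping):
    return pd.Series([mapping[c] for c in cells], index=cells)


class TestGeneStats:
    def test_average_nonzero_and_proportion(self):
        log = np.log2(matrix_from_log([[0, 0, 2, 4]]) + 1)
        stats = rare.gene_stats(log, _samples(log.columns, dict.fromkeys(log.columns, "A")))
        assert stats.loc["G0", "avg_nonzero"] == pytest.approx(3.0)
        assert stats.loc["G0", "cell_proportion"] == 0.5

    def test_undetected_gene_is_nan_not_zero(self):
        log = np.log2(matrix_from_log([[0, 0], [1, 2]]) + 1)
        stats = rare.gene_stats(log, _samples(log.columns, dict.fromkeys(log.columns, "A")))
        assert np.isnan(stats.loc["G0", "avg_nonzero"])
        assert stats.loc["G0", "cell_proportion"] == 0.0

    def test_per_sample_proportions(self):
        values = np.zeros((1, 20))
        values[0, :5] = 2.0  # 5 detected cells, all in sample A
        log = np.log2(matrix_from_log(values) + 1)
        mapping = {c: ("A" if i < 10 else "B") for i, c in enumerate(log.columns)}
        stats = rare.gene_stats(log, _samples(log.columns, mapping))
        assert stats.loc["G0", "prop_A"] == 0.5
        assert stats.loc["G0", "prop_B"] == 0.0
        assert stats.loc["G0", "max_sample_proportion"] == 0.5

    def test_missing_sample_id_is_data_error(self):
        log = np.log2(matrix_from_log([[1, 2]]) + 1)
        with pytest.raises(DataError):
            rare.gene_stats(log, pd.Series({"C0": "A"}))


def _null_oracle(values: np.ndarray, n_perm: int, seed: int):
    """Brute-force re-implementation with explicit loops, sharing the
    implementation's shuffle stream call-for-call."""
    rng = np.random.default_rng(seed)
    flat = values.ravel()
    n_genes, n_cells = values.shape
    expr_pool, prop_pool = [], []
    for _ in range(n_perm):
        perm = rng.permutation(flat).reshape(n_genes, n_cells)
        for g in range(n_genes):
            row = perm[g]
            nz = [v for v in row if v > 0]
            prop_pool.append(len(nz) / n_cells)
            if nz:
                expr_pool.append(sum(nz) / len(nz))
    return (
        float(np.percentile(expr_pool, 99)),
        float(np.percentile(prop_pool, 1)),
    )


class TestPermutationNull:
    def test_matches_bruteforce_oracle_exactly(self):
        rng = np.random.default_rng(123)
        values = rng.exponential(1.0, size=(10, 10))
        values[rng.random((10, 10)) < 0.5] = 0.0
        log = pd.DataFrame(values, index=[f"g{i}" for i in range(10)],
                           columns=[f"c{j}" for j in range(10)])
        nulls = rare.permutation_null(log, n_perm=20, seed=9)
        expr_t, prop_t = _null_oracle(values, 20, 9)
        assert nulls.expr_threshold == expr_t
        assert nulls.prop_threshold == prop_t

    def test_constant_matrix_thresholds_are_c_and_one(self):
        c = 2.5
        log = pd.DataFrame(np.full((6, 7), c))
        nulls = rare.permutation_null(log, n_perm=5, seed=0)
        assert nulls.expr_threshold == pytest.approx(c)
        assert nulls.prop_threshold == 1.0

    def test_shuffle_preserves_entry_multiset(self):
        rng = np.random.default_rng(0)
        values = rng.exponential(1.0, size=(8, 5))
        log = pd.DataFrame(values)
        for mode in ("global", "within-cell"):
            nulls = rare.permutation_null(log, n_perm=30, seed=1, mode=mode)
            # detected-entry count conserved: every permutation contributes
            # exactly n_genes proportions averaging to the global density
            per_perm = nulls.prop_null.reshape(30, 8)
            np.testing.assert_allclose(
                per_perm.mean(axis=1), (values > 0).mean(), atol=1e-12
            )

    def test_thresholds_stabilize_with_more_permutations(self):
        rng = np.random.default_rng(5)
        values = rng.exponential(1.0, size=(40, 30))
        values[rng.random((40, 30)) < 0.4] = 0.0
        log = pd.DataFrame(values)
        small = [rare.permutation_null(log, 50, seed=s).expr_threshold for s in range(6)]
        big = [rare.permutation_null(log, 400, seed=s).expr_threshold for s in range(6)]
        assert np.std(big) < np.std(small)

    def test_invalid_parameters(self):
        log = pd.DataFrame(np.ones((2, 2)))
        with pytest.raises(ConfigurationError):
            rare.permutation_null(log, n_perm=0)
        with pytest.raises(ConfigurationError):
            rare.permutation_null(log, mode="per-gene")


def _stats_row(**kw):
    base = dict(biotype="PCG", avg_nonzero=5.0, n_detected_cells=15,
                cell_proportion=0.05, prop_A=0.05, prop_B=0.05,
                max_sample_proportion=0.05)
    base.update(kw)
    return base


def _nulls(expr=2.0, prop=0.3):
    return rare.NullDistributions(1, 0, "global", np.array([expr]),
                                  np.array([prop]), expr, prop)


class TestIdentify:
    def test_failure_reasons_are_recorded(self):
        stats = pd.DataFrame(
            {
                "ok": _stats_row(),
                "dim": _stats_row(avg_nonzero=1.5),
                "ubiquitous": _stats_row(cell_proportion=0.5),
                "few_cells": _stats_row(n_detected_cells=9),
                "sample_heavy": _stats_row(prop_A=0.25, max_sample_proportion=0.25),
                "undetected": _stats_row(avg_nonzero=np.nan, n_detected_cells=0,
                                         cell_proportion=0.0),
            }
        ).T
        calls = rare.identify_rare_genes(stats, _nulls())
        assert calls.loc["ok", "passed"]
        assert calls.loc["dim", "fail_reasons"] == rare.FAIL_LOW_EXPR
        assert calls.loc["ubiquitous", "fail_reasons"] == rare.FAIL_HIGH_PROPORTION
        assert calls.loc["few_cells", "fail_reasons"] == rare.FAIL_TOO_FEW_CELLS
        assert calls.loc["sample_heavy", "fail_reasons"] == rare.FAIL_ABUNDANT_IN_SAMPLE
        assert rare.FAIL_LOW_EXPR in calls.loc["undetected", "fail_reasons"]
        assert (calls["passed"] == (calls["fail_reasons"] == "")).all()

    def test_thresholds_are_strict_inequalities(self):
        stats = pd.DataFrame(
            {
                "at_expr": _stats_row(avg_nonzero=2.0),
                "at_prop": _stats_row(cell_proportion=0.3),
                "at_sample": _stats_row(prop_A=0.2, max_sample_proportion=0.2),
            }
        ).T
        calls = rare.identify_rare_genes(stats, _nulls())
        assert not calls.loc["at_expr", "passed"]        # needs > threshold
        assert not calls.loc["at_prop", "passed"]        # needs < threshold
        assert calls.loc["at_sample", "passed"]          # 0.2 is allowed (> fails)

    def test_deterministic_end_to_end(self):
        rng = np.random.default_rng(3)
        values = rng.exponential(1.0, size=(30, 20))
        values[rng.random((30, 20)) < 0.5] = 0
        log = pd.DataFrame(values, index=[f"g{i}" for i in range(30)],
                           columns=[f"c{j}" for j in range(20)])
        samples = _samples(log.columns, {c: "A" for c in log.columns})

        def run():
            stats = rare.gene_stats(log, samples)
            nulls = rare.permutation_null(log, 50, seed=4)
            return rare.identify_rare_genes(stats, nulls)

        pd.testing.assert_frame_equal(run(), run())


class TestQuartileScreen:
    def _stats(self, rows):
        return pd.DataFrame(rows, columns=["biotype", "avg_nonzero", "cell_proportion"],
                            index=[f"g{i}" for i in range(len(rows))])

    def test_flagging_rule(self):
        stats = self._stats(
            [("PCG", 1.0, 0.9), ("PCG", 2.0, 0.9), ("PCG", 3.0, 0.9),
             ("PCG", 4.0, 0.9), ("lncRNA", 3.6, 0.1)]
        )
        out, summary = rare.quartile_screen(stats)
        # linear interpolation between order statistics: Q3({1,2,3,4}) = 3.25
        assert summary["q3"] == pytest.approx(3.25)
        assert out.loc["g4", "flagged"]
        assert not out.loc["g3", "flagged"]  # above Q3 but ubiquitous

    def test_proportion_boundary_is_strict(self):
        stats = self._stats([("PCG", 1.0, 0.9), ("lncRNA", 5.0, 0.2)])
        out, _ = rare.quartile_screen(stats)
        assert not out["flagged"].any()

    def test_all_ubiquitous_flags_nothing(self):
        stats = self._stats([("PCG", v, 1.0) for v in (1.0, 2.0, 5.0)])
        out, summary = rare.quartile_screen(stats)
        assert summary["n_flagged"] == 0

    def test_no_pcgs_is_error(self):
        stats = self._stats([("lncRNA", 5.0, 0.1)])
        with pytest.raises(DataError):
            rare.quartile_screen(stats)
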