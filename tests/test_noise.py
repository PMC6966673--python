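"""Noise-classifier components: training sets, features, KDE ratios,
cutoff selection, cross-validation and denoising."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from raregene import ClassifierNotTrainableError, DataError, noise
from raregene.preprocess import ExpressionMatrix
from raregene.synthetic import generate_dataset

from conftest import classifier_config, matrix_from_log


class TestTrainingSets:
    def _m(self, detected_counts, n_cells=10):
        rows = []
        for k in detected_counts:
            row = np.zeros(n_cells)
            row[:k] = 2.0
            rows.append(row)
        return matrix_from_log(np.array(rows))

    def test_strict_positive_fraction_and_negative_ceiling(self):
        m = self._m([9, 8, 2, 0, 5])
        sets = noise.build_training_sets(m, pos_fraction=0.8, neg_max_cells=2)
        assert sets.positive_ids == ["G0"]      # 0.9 > 0.8
        assert "G1" not in sets.positive_ids    # 0.8 is not > 0.8
        assert sets.negative_ids == ["G2"]      # 2 cells; 0-detected excluded

    def test_empty_set_raises(self):
        with pytest.raises(ClassifierNotTrainableError, match="positive"):
            noise.build_training_sets(self._m([5, 5, 2]))


class TestFeatures:
    def test_relative_abundance_is_ecdf_rank(self):
        expr = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        out = noise.relative_abundance(expr)
        assert out.tolist() == pytest.approx([1 / 3, 2 / 3, 1.0])

    def test_ties_share_maximal_rank(self):
        expr = pd.Series([5.0, 5.0], index=["a", "b"])
        assert noise.relative_abundance(expr).tolist() == [1.0, 1.0]

    def test_empty_input_empty_output(self):
        assert noise.relative_abundance(pd.Series(dtype=float)).empty

    def test_coverage_passthrough_and_validation(self):
        cov = pd.DataFrame({"c1": [0.75, 1.0, 1.5]}, index=["a", "b", "c"])
        ok = noise.exon_coverage_feature(cov, "c1", ["a", "b"])
        assert ok.tolist() == [0.75, 1.0]
        with pytest.raises(DataError, match="'c'.*'c1'"):
            noise.exon_coverage_feature(cov, "c1", ["c"])
        with pytest.raises(DataError, match="'z'"):
            noise.exon_coverage_feature(cov, "c1", ["z"])


def _separated_points(rng, n=40):
    pos = np.column_stack([rng.uniform(0.6, 1.0, n), rng.beta(8, 2, n)])
    neg = np.column_stack([rng.uniform(0.0, 0.4, n), rng.beta(2, 8, n)])
    return pos, neg


class TestClassifier:
    def test_grid_node_interpolation_identity(self):
        rng = np.random.default_rng(0)
        pos, neg = _separated_points(rng)
        clf = noise.fit_cell_classifier("cell", pos, neg, grid_resolution=21)
        i, j = 13, 5
        query = np.array([[clf.grid_x[i], clf.grid_y[j]]])
        expected = (clf.pos_density[i, j] + clf.epsilon) / (clf.neg_density[i, j] + clf.epsilon)
        assert clf.likelihood_ratio(query)[0] == pytest.approx(expected, rel=1e-9)

    def test_epsilon_dominates_where_both_densities_vanish(self):
        rng = np.random.default_rng(1)
        pos = np.column_stack([rng.normal(0.9, 0.01, 30), rng.normal(0.9, 0.01, 30)])
        neg = np.column_stack([rng.normal(0.8, 0.01, 30), rng.normal(0.8, 0.01, 30)])
        clf = noise.fit_cell_classifier("cell", pos.clip(0, 1), neg.clip(0, 1))
        ratio = clf.likelihood_ratio(np.array([[0.05, 0.05]]))[0]
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_identical_distributions_give_ratios_near_one(self):
        medians = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            pts = lambda: np.column_stack([rng.uniform(0, 1, 60), rng.beta(2, 2, 60)])
            clf = noise.fit_cell_classifier("cell", pts(), pts())
            ratios = clf.likelihood_ratio(pts())
            medians.append(np.median(ratios))
        assert 0.5 <= np.median(medians) <= 2.0

    def test_degenerate_training_points_not_trainable(self):
        same = np.tile([[0.5, 0.5]], (10, 1))
        with pytest.raises(ClassifierNotTrainableError):
            noise.fit_cell_classifier("cell", same, same)


def _cutoff_oracle(ratios, labels):
    best = None
    for cut in sorted(set(ratios)):
        pred = ratios >= cut
        sens = (pred & labels).sum() / labels.sum()
        spec = (~pred & ~labels).sum() / (~labels).sum()
        ba = (sens + spec) / 2
        if best is None or ba > best[1]:
            best = (cut, ba)
    return best


class TestCutoff:
    def test_perfectly_separated(self):
        cut, ba = noise.select_cutoff(
            np.array([10.0, 5.0, 0.1, 0.2]), np.array([True, True, False, False])
        )
        assert cut == 5.0 and ba == 1.0

    def test_tied_instance_picks_smallest_cutoff(self):
        cut, ba = noise.select_cutoff(np.array([2.0, 2.0]), np.array([True, False]))
        assert cut == 2.0 and ba == 0.5

    def test_one_class_raises(self):
        with pytest.raises(DataError):
            noise.select_cutoff(np.array([1.0, 2.0]), np.array([True, True]))

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 40)
        ratios = rng.exponential(1.0, n).round(3)  # rounding forces ties
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        got = noise.select_cutoff(ratios, labels)
        assert got == pytest.approx(_cutoff_oracle(ratios, labels))
        assert got[1] >= 0.5  # predict-all-expressed is always in the sweep

    def test_labels_monotone_in_ratio(self):
        rng = np.random.default_rng(7)
        ratios = rng.exponential(1.0, 50)
        labels = ratios > np.median(ratios)
        cut, _ = noise.select_cutoff(ratios, labels)
        expressed = ratios >= cut
        bumped = np.where(expressed, ratios, ratios + rng.exponential(1.0, 50))
        # raising a ratio can never flip expressed -> noise
        assert ((bumped >= cut) >= expressed).all()


class TestCrossValidation:
    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        pos, neg = _separated_points(rng)
        a = noise.cross_validate_cell(pos, neg, seed=3)
        b = noise.cross_validate_cell(pos, neg, seed=3)
        assert a == b

    def test_separable_features_high_auc(self):
        aucs = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            pos, neg = _separated_points(rng)
            aucs.extend(noise.cross_validate_cell(pos, neg, seed=seed))
        assert np.mean(aucs) >= 0.9

    def test_class_smaller_than_folds_not_trainable(self):
        rng = np.random.default_rng(0)
        pos, neg = _separated_points(rng)
        with pytest.raises(ClassifierNotTrainableError):
            noise.cross_validate_cell(pos[:3], neg, k=5)


class TestGateAndApply:
    def test_gate_is_strict(self):
        def clf(auc):
            c = noise.CellClassifier("x", np.array([0.0, 1.0]), np.array([0.0, 1.0]),
                                     np.ones((2, 2)), np.ones((2, 2)))
            c.fold_aucs = [auc]
            return c

        kept = noise.gate_cells({"a": clf(0.80), "b": clf(0.81)}, min_auc=0.8)
        assert kept == ["b"]

    def test_ratio_exactly_at_cutoff_is_expressed(self):
        rng = np.random.default_rng(0)
        pos, neg = _separated_points(rng)
        clf = noise.fit_cell_classifier("cell", pos, neg)
        query = np.array([[0.7, 0.8]])
        clf.cutoff = float(clf.likelihood_ratio(query)[0])
        calls = noise.apply_classifier(clf, query, ["lnc1"])
        assert calls.loc[0, "label"] == "expressed"


@pytest.fixture(scope="module")
def result():
    ds = generate_dataset(classifier_config(seed=1))
    m = ExpressionMatrix(ds.matrix)
    lnc = ds.annotation.index[ds.annotation["biotype"] == "lncRNA"]
    return ds, noise.denoise(m.log2.loc[lnc], ds.coverage, seed=1)


class TestDenoise:
    def test_most_noise_entries_labeled_noise(self, result):
        ds, res = result
        lnc_mask = ds.truth.noise_entry_mask.loc[res.denoised.index, res.retained_cells]
        noisy = res.calls[res.calls["label"] == "noise"]
        called = set(zip(noisy["gene_id"], noisy["cell_id"]))
        genes, cells = np.nonzero(lnc_mask.to_numpy())
        truth_pairs = list(zip(lnc_mask.index[genes], lnc_mask.columns[cells]))
        hit = sum(p in called for p in truth_pairs)
        assert hit / len(truth_pairs) >= 0.8

    def test_denoising_never_increases_entries(self, result):
        ds, res = result
        lnc = res.denoised.index
        original = np.log2(ds.matrix.loc[lnc, res.retained_cells] + 1.0)
        assert (res.denoised.to_numpy() <= original.to_numpy() + 1e-12).all()

    def test_undetected_lncs_get_no_call(self, result):
        ds, res = result
        log = np.log2(ds.matrix + 1.0)
        for _, row in res.calls.head(50).iterrows():
            assert log.at[row["gene_id"], row["cell_id"]] > 0

    def test_summary_accounts_for_every_cell(self, result):
        ds, res = result
        assert set(res.summary.index) == set(ds.matrix.columns)
        dropped = res.summary[~res.summary["retained"]]
        assert (dropped["reason"] != "").all()
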