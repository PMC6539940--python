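"""Mutual information and mRMR selection against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import mutual_info_score

from shpcvm import FeatureTable, mrmr_select, mutual_information
from shpcvm.datasets import make_feature_table
from shpcvm.featsel import discretize


class TestMutualInformation:
    def test_identical_balanced_binary_gives_ln2(self):
        x = np.array([0, 1] * 50)
        assert mutual_information(x, x) == pytest.approx(np.log(2), abs=1e-12)

    def test_exactly_factorized_joint_gives_zero(self):
        # joint table is the product of its marginals by construction
        x = np.repeat([0, 0, 1, 1], 25)
        y = np.tile([0, 1], 50)
        assert mutual_information(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_constant_vector_gives_zero(self):
        x = np.zeros(40)
        y = np.array([0, 1] * 20)
        assert mutual_information(x, y) == 0.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            mutual_information(np.zeros(5), np.zeros(6))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_symmetric_and_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 4, 60)
        y = rng.integers(0, 3, 60)
        ixy = mutual_information(x, y)
        iyx = mutual_information(y, x)
        assert ixy == pytest.approx(iyx, abs=1e-12)
        assert ixy >= -1e-12

    @pytest.mark.parametrize("seed", [0, 7, 19])
    def test_matches_sklearn_on_discrete_tables(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 5, 200)
        y = rng.integers(0, 4, 200)
        assert mutual_information(x, y) == pytest.approx(
            mutual_info_score(x, y), abs=1e-12)

    def test_continuous_input_discretized_first(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=500)
        y = (x > 0).astype(int)
        # thresholded copy carries about one bit through 10-bin coding
        assert mutual_information(x, y, n_bins=10) > 0.5


def brute_force_mrmr(X, y, k, n_bins=10):
    """Independent step-by-step re-implementation of the greedy rule,
    scoring every candidate set with sklearn's MI."""
    codes = [discretize(X[:, j], n_bins) for j in range(X.shape[1])]
    ycode = discretize(np.asarray(y), n_bins)
    rel = [mutual_info_score(c, ycode) for c in codes]
    order, scores = [], []
    remaining = list(range(X.shape[1]))
    for _ in range(k):
        best, best_psi = None, -np.inf
        for i in remaining:
            cand = order + [i]
            D = np.mean([rel[j] for j in cand])
            pairs = [mutual_info_score(codes[a], codes[b])
                     for a in cand for b in cand if a < b]
            psi = D - (np.mean(pairs) if pairs else 0.0)
            if psi > best_psi + 1e-15 or best is None:
                best, best_psi = i, psi
        order.append(best)
        scores.append(best_psi)
        remaining.remove(best)
    return order, scores


class TestMRMRSelect:
    def test_redundant_copy_loses_to_independent_noise(self):
        # f0 = label copy, f1 = duplicate of f0, f2 = noise: the duplicate
        # is fully redundant, so the second pick must be the noise feature
        rng = np.random.default_rng(0)
        y = np.array([1, -1] * 100)
        f0 = y.astype(float)
        f2 = rng.normal(size=200)
        X = np.column_stack([f0, f0.copy(), f2])
        table = FeatureTable(matrix=X, feature_names=("f0", "f1", "f2"),
                             labels=y)
        ranking = mrmr_select(table, k=2)
        assert ranking.order[0] == 0
        assert ranking.order[1] == 2

    def test_k1_reduces_to_max_relevance(self):
        table = make_feature_table(200, 5, "separable", seed=3)
        ranking = mrmr_select(table, k=1)
        rels = [mutual_information(table.matrix[:, j], table.labels)
                for j in range(5)]
        assert ranking.order == (int(np.argmax(rels)),)
        assert ranking.scores[0] == pytest.approx(max(rels))

    @pytest.mark.parametrize("structure,seed", [("separable", 0),
                                                ("redundant-pair", 1),
                                                ("noise", 2)])
    def test_greedy_trace_matches_brute_force(self, structure, seed):
        table = make_feature_table(150, 6, structure, seed=seed)
        ranking = mrmr_select(table, k=4)
        order, scores = brute_force_mrmr(table.matrix, table.labels, k=4)
        assert list(ranking.order) == order
        np.testing.assert_allclose(ranking.scores, scores, atol=1e-12)

    def test_selected_indices_unique_and_scores_finite(self):
        table = make_feature_table(100, 8, "separable", seed=4)
        ranking = mrmr_select(table, k=8)
        assert len(set(ranking.order)) == 8
        assert np.all(np.isfinite(ranking.scores))

    def test_duplicated_column_never_displaces_original(self):
        # append an exact duplicate of the best feature; top-k for k < d
        # must still contain the original before the duplicate
        table = make_feature_table(200, 4, "separable", seed=5)
        X = np.column_stack([table.matrix, table.matrix[:, 0]])
        aug = FeatureTable(matrix=X,
                           feature_names=table.feature_names + ("dup",),
                           labels=table.labels)
        ranking = mrmr_select(aug, k=4)
        assert 0 in ranking.order
        if 4 in ranking.order:
            assert ranking.order.index(0) < ranking.order.index(4)

    def test_invalid_k_and_single_class_rejected(self):
        table = make_feature_table(50, 3, "noise", seed=0)
        with pytest.raises(ValueError):
            mrmr_select(table, k=4)
        with pytest.raises(ValueError):
            bad = FeatureTable(matrix=table.matrix,
                               feature_names=table.feature_names,
                               labels=np.ones(50))
            mrmr_select(bad, k=2)
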