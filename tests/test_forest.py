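"""Honest causal forest: pseudo-outcomes, splitting, weights, predictions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hetforest import ForestParams
from hetforest.forest import (CausalForest, RegressionForest, best_split,
                              grow_tree, node_pseudo_outcomes)


def brute_force_split(X, rho, min_node, features=None):
    """Exhaustive maximizer of the split criterion over every covariate
    and every midpoint between consecutive sorted values (test oracle)."""
    rho = rho - rho.mean()
    feats = range(X.shape[1]) if features is None else features
    best, best_gain = None, 0.0
    for v in feats:
        xs = np.unique(X[:, v])
        for a, b in zip(xs[:-1], xs[1:]):
            thr = 0.5 * (a + b)
            if thr >= b:
                thr = a
            left = X[:, v] <= thr
            n_l, n_r = int(left.sum()), int((~left).sum())
            if min(n_l, n_r) < min_node:
                continue
            gain = rho[left].sum() ** 2 / n_l + rho[~left].sum() ** 2 / n_r
            if gain > best_gain:
                best_gain, best = gain, (v, thr)
    return best


class TestPseudoOutcomes:
    def test_perfect_homogeneous_fit_gives_zero_gradients(self):
        tau, rho = node_pseudo_outcomes([0.5, -0.5], [0.5, -0.5])
        assert tau == pytest.approx(1.0)
        assert np.allclose(rho, 0.0)

    def test_four_row_hand_example(self):
        # tau_P = sum(w~ y~)/sum(w~^2) = 0.5/1 = 0.5; A_P = 0.25;
        # rho_i = w~_i (y~_i - w~_i tau_P) / A_P, worked by hand
        tau, rho = node_pseudo_outcomes([1.0, 0.0, 0.0, 0.0], [0.5, 0.5, -0.5, -0.5])
        assert tau == pytest.approx(0.5)
        assert rho == pytest.approx([1.5, -0.5, -0.5, -0.5])

    @given(st.integers(0, 1000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_gradients_sum_to_zero_exactly(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(2, 60))
        w = r.normal(size=n)
        y = r.normal(size=n)
        if np.sum(w**2) == 0:
            return
        _, rho = node_pseudo_outcomes(y, w)
        assert abs(rho.sum()) < 1e-9 * max(1.0, np.abs(rho).max()) * n

    def test_no_treatment_variation_rejected(self):
        with pytest.raises(ValueError, match="treatment variation"):
            node_pseudo_outcomes([1.0, 2.0], [0.0, 0.0])


class TestBestSplit:
    def test_node_smaller_than_twice_min_node_unsplittable(self, rng):
        X = rng.standard_normal((9, 3))
        rho = rng.standard_normal(9)
        assert best_split(X, rho, min_node_size=5) is None

    def test_strong_signal_splits_true_modifier_near_zero(self):
        hits = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            X = r.standard_normal((400, 5))
            w = r.integers(0, 2, 400) - 0.5
            tau = np.where(X[:, 0] > 0, 1.0, -1.0)
            y = tau * w + 0.1 * r.standard_normal(400)
            _, rho = node_pseudo_outcomes(y, w)
            sc = best_split(X, rho, min_node_size=5)
            if sc is not None and sc.feature == 0 and abs(sc.threshold) < 0.3:
                hits += 1
        assert hits >= 38  # >= 95% of seeds

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_exhaustive_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(10, 101))
        p = int(r.integers(1, 6))
        X = r.standard_normal((n, p))
        if r.random() < 0.3:  # exercise ties via discrete covariates
            X = np.round(X)
        rho = r.standard_normal(n)
        sc = best_split(X, rho, min_node_size=5)
        oracle = brute_force_split(X, rho, 5)
        got = None if sc is None else (sc.feature, sc.threshold)
        assert got == oracle


class TestGrowTree:
    def _toy(self, n=120, p=4, seed=0):
        r = np.random.default_rng(seed)
        X = r.standard_normal((n, p))
        w = r.integers(0, 2, n) - 0.5
        y = np.where(X[:, 1] > 0, 1.0, -1.0) * w + 0.2 * r.standard_normal(n)
        return X, y, w

    def test_min_node_at_least_half_gives_single_leaf(self):
        X, y, w = self._toy()
        j1, j2 = np.arange(60), np.arange(60, 120)
        t = grow_tree(X, y, w, j1, j2, ForestParams(min_node_size=60))
        assert t.n_nodes == 1
        assert t.feature[0] == -1
        assert set(t.leaf_members(0)) == set(j2)

    def test_identical_covariate_rows_give_single_leaf(self):
        X = np.ones((40, 3))
        r = np.random.default_rng(1)
        w = r.integers(0, 2, 40) - 0.5
        y = r.standard_normal(40)
        t = grow_tree(X, y, w, np.arange(20), np.arange(20, 40),
                      ForestParams(min_node_size=2))
        assert t.n_nodes == 1

    def test_structure_independent_of_estimation_half_responses(self):
        X, y, w = self._toy(n=200, seed=2)
        j1, j2 = np.arange(100), np.arange(100, 200)
        params = ForestParams(min_node_size=5, mtry=4)
        rng1 = np.random.default_rng(77)
        t1 = grow_tree(X, y, w, j1, j2, params, rng=rng1)
        y2 = y.copy()
        w2 = w.copy()
        y2[j2] = np.random.default_rng(3).standard_normal(100)  # scramble J2 responses
        w2[j2] = -w2[j2]
        rng2 = np.random.default_rng(77)
        t2 = grow_tree(X, y2, w2, j1, j2, params, rng=rng2)
        assert t1.structure() == t2.structure()

    def test_first_split_finds_true_modifier(self):
        hits = 0
        for seed in range(200):
            X, y, w = self._toy(n=300, seed=seed + 10)
            t = grow_tree(X, y, w, np.arange(150), np.arange(150, 300),
                          ForestParams(min_node_size=10, mtry=4),
                          rng=np.random.default_rng(seed))
            if t.n_nodes > 1 and t.feature[0] == 1:
                hits += 1
        assert hits >= 180  # >= 90% over 200 trees

    def test_overlapping_halves_rejected(self):
        X, y, w = self._toy()
        with pytest.raises(ValueError, match="disjoint"):
            grow_tree(X, y, w, np.arange(61), np.arange(60, 120), ForestParams())

    def test_leaves_respect_min_node_in_estimation_half(self):
        X, y, w = self._toy(n=400, seed=5)
        t = grow_tree(X, y, w, np.arange(200), np.arange(200, 400),
                      ForestParams(min_node_size=12))
        n = t.n_nodes
        leaf = t.feature[:n] == -1
        assert (t.leaf_member_count[:n][leaf] >= 12).all()


@pytest.fixture(scope="module")
def toy_forest():
    r = np.random.default_rng(8)
    n = 600
    X = r.standard_normal((n, 4))
    w = r.integers(0, 2, n).astype(float)
    y = (1.0 + X[:, 0]) * w + X[:, 1] + 0.3 * r.standard_normal(n)
    wt = w - 0.5
    yt = y - y.mean()
    cf = CausalForest(ForestParams(n_trees=60, min_node_size=10)).fit(X, yt, wt, seed=4)
    return cf, X, yt, wt


class TestForestWeights:
    def test_weights_nonnegative_and_sum_to_one(self, toy_forest):
        cf, X, _, _ = toy_forest
        r = np.random.default_rng(9)
        Xq = r.standard_normal((50, 4))
        alpha = cf.forest_weights(Xq)
        assert (alpha >= 0).all()
        assert np.abs(alpha.sum(axis=1) - 1.0).max() < 1e-12

    def test_oob_weights_exclude_own_trees(self, toy_forest):
        cf, X, _, _ = toy_forest
        rows = np.arange(10)
        alpha = cf.forest_weights(X[rows], oob_rows=rows)
        # row i itself can never be a J2 co-leaf member of an excluded tree
        for i in rows:
            assert alpha[i, i] == 0.0

    def test_single_stump_tree_weights_uniform_over_leaf(self):
        r = np.random.default_rng(10)
        X = r.standard_normal((40, 2))
        wt = r.integers(0, 2, 40) - 0.5
        yt = r.standard_normal(40)
        cf = CausalForest(ForestParams(n_trees=1, subsample_fraction=1.0,
                                       min_node_size=40)).fit(X, yt, wt, seed=1)
        alpha = cf.forest_weights(X[:3])
        members = np.nonzero(alpha[0] > 0)[0]
        assert np.allclose(alpha[0, members], 1.0 / len(members))
        # hand case: a leaf holding members {a, b} weights each at 1/2
        assert alpha.shape == (3, 40)

    def test_weights_reproduce_cate_prediction(self, toy_forest):
        cf, X, yt, wt = toy_forest
        Xq = X[:5] + 0.01
        alpha = cf.forest_weights(Xq)
        manual = (alpha @ (wt * yt)) / (alpha @ (wt**2))
        assert cf.predict_cate(Xq) == pytest.approx(manual, rel=1e-10)


class TestPredictCate:
    def test_exact_linear_relation_recovered_everywhere(self):
        r = np.random.default_rng(11)
        X = r.standard_normal((300, 3))
        wt = r.normal(size=300)
        yt = 3.0 * wt
        cf = CausalForest(ForestParams(n_trees=40, min_node_size=10)).fit(X, yt, wt, seed=2)
        tau = cf.predict_cate(r.standard_normal((20, 3)))
        assert tau == pytest.approx(np.full(20, 3.0), abs=1e-10)

    def test_constant_effect_recovery(self):
        r = np.random.default_rng(12)
        n = 2000
        X = r.standard_normal((n, 5))
        w = r.integers(0, 2, n).astype(float)
        y = X[:, 0] + 2.0 * w + r.standard_normal(n)
        cf = CausalForest(ForestParams(n_trees=200, min_node_size=10)).fit(
            X, y - y.mean(), w - w.mean(), seed=3)
        tau = cf.predict_cate_oob()
        assert tau.mean() == pytest.approx(2.0, abs=0.2)

    def test_rmse_decreases_with_sample_size(self):
        rmses = []
        for n in (1000, 4000, 16000):
            r = np.random.default_rng(n)
            X = r.standard_normal((n, 4))
            w = r.integers(0, 2, n).astype(float)
            tau = 1.0 + np.tanh(X[:, 0])
            y = 0.5 * X[:, 1] + tau * w + 0.5 * r.standard_normal(n)
            cf = CausalForest(ForestParams(n_trees=150, min_node_size=20)).fit(
                X, y - y.mean(), w - w.mean(), seed=5)
            rmses.append(float(np.sqrt(np.mean((cf.predict_cate_oob() - tau) ** 2))))
        assert rmses[0] > rmses[1] > rmses[2]

    def test_deterministic_under_seed(self):
        r = np.random.default_rng(13)
        X = r.standard_normal((500, 4))
        wt = r.integers(0, 2, 500) - 0.5
        yt = r.standard_normal(500)
        p = ForestParams(n_trees=30, min_node_size=10)
        a = CausalForest(p).fit(X, yt, wt, seed=6).predict_cate_oob()
        b = CausalForest(p).fit(X, yt, wt, seed=6).predict_cate_oob()
        c = CausalForest(p).fit(X, yt, wt, seed=7).predict_cate_oob()
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)


class TestVariableImportance:
    def test_single_informative_binary_covariate_gets_all_importance(self):
        r = np.random.default_rng(14)
        n = 400
        X = np.column_stack([np.zeros(n), np.zeros(n), r.integers(0, 2, n).astype(float)])
        wt = r.integers(0, 2, n) - 0.5
        yt = 4.0 * X[:, 2] * wt  # only covariate 2 modifies the effect
        # min_node just under half the J1 half: at most one split per tree
        cf = CausalForest(ForestParams(n_trees=30, min_node_size=45)).fit(X, yt, wt, seed=8)
        imp = cf.variable_importance()
        assert imp == pytest.approx([0.0, 0.0, 1.0])

    def test_stump_forest_importance_is_zero_vector(self):
        r = np.random.default_rng(15)
        X = r.standard_normal((60, 3))
        cf = CausalForest(ForestParams(n_trees=10, min_node_size=60)).fit(
            X, r.standard_normal(60), r.integers(0, 2, 60) - 0.5, seed=9)
        imp = cf.variable_importance()
        assert np.array_equal(imp, np.zeros(3))

    def test_true_modifier_ranks_first(self):
        r = np.random.default_rng(16)
        n = 5000
        X = r.standard_normal((n, 10))
        w = r.integers(0, 2, n).astype(float)
        y = (1.0 + 2.0 * (X[:, 3] > 0)) * w + r.standard_normal(n)
        cf = CausalForest(ForestParams(n_trees=100, min_node_size=20)).fit(
            X, y - y.mean(), w - 0.5, seed=10)
        imp = cf.variable_importance()
        assert imp.argmax() == 3

    def test_serialization_roundtrip_contains_trees(self, toy_forest):
        import json

        cf, _, _, _ = toy_forest
        payload = json.loads(cf.to_json())
        assert payload["mode"] == "causal"
        assert len(payload["trees"]) == cf.params.n_trees
        t0 = payload["trees"][0]
        assert len(t0["feature"]) == int(cf.tree_n_nodes[0])


class TestRegressionForestBasics:
    def test_oob_never_uses_own_trees(self):
        r = np.random.default_rng(17)
        X = r.standard_normal((200, 3))
        y = X[:, 0] + 0.1 * r.standard_normal(200)
        f = RegressionForest(ForestParams(n_trees=40, min_node_size=10)).fit(X, y, seed=11)
        leafmat = f._leafmat(X)
        preds = f.predict_oob()
        for i in (0, 17, 150):
            vals = [f.val_a[leafmat[i, b]] for b in range(40)
                    if not f.in_sample[b, i] and f.leaf_member_count[leafmat[i, b]] > 0]
            assert preds[i] == pytest.approx(np.mean(vals))
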