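"""Boosting core against closed forms and an independent brute-force oracle."""

import json
import warnings

import numpy as np
import pytest

from dermrad.gbdt import (
    GradientBoostingBernoulli,
    bernoulli_deviance,
    init_f0,
    leaf_values,
    negative_gradient,
)
from dermrad._tree import RegressionTree
from dermrad.evaluation import auc


# ------------------------------------------------------------------- oracle

def oracle_boost(X, y01, n_iter, nu, max_depth, min_leaf):
    """Straight-line re-implementation of the boosting recursion, using an
    exhaustive split search independent of the production tree code."""
    z = np.where(np.asarray(y01) > 0, 1.0, -1.0)
    n = len(z)
    f0 = np.log((z > 0).sum() / (z < 0).sum())
    f = np.full(n, f0)

    def exhaustive_tree(rows, r, depth):
        rows = np.asarray(rows)
        if depth == 0 or len(rows) < 2 * min_leaf or np.ptp(r[rows]) == 0:
            return ("leaf", rows)
        best = None
        for feat in range(X.shape[1]):
            vals = np.unique(X[rows, feat])
            for a, b in zip(vals[:-1], vals[1:]):
                thr = (a + b) / 2.0
                left = rows[X[rows, feat] <= thr]
                right = rows[X[rows, feat] > thr]
                if len(left) < min_leaf or len(right) < min_leaf:
                    continue
                sse = (((r[left] - r[left].mean()) ** 2).sum()
                       + ((r[right] - r[right].mean()) ** 2).sum())
                key = (sse, feat, thr)
                if best is None or key < best[0]:
                    best = (key, feat, thr, left, right)
        if best is None:
            return ("leaf", rows)
        base_sse = ((r[rows] - r[rows].mean()) ** 2).sum()
        if base_sse - best[0][0] <= 1e-12:
            return ("leaf", rows)
        _, feat, thr, left, right = best
        return ("split", feat, thr,
                exhaustive_tree(left, r, depth - 1),
                exhaustive_tree(right, r, depth - 1))

    def leaves_of(node):
        if node[0] == "leaf":
            return [node[1]]
        return leaves_of(node[3]) + leaves_of(node[4])

    for _ in range(n_iter):
        r = z / (1.0 + np.exp(z * f))
        tree = exhaustive_tree(np.arange(n), r, max_depth)
        for rows in leaves_of(tree):
            num = r[rows].sum()
            den = (np.abs(r[rows]) * (1 - np.abs(r[rows]))).sum()
            c = 0.0 if den < 1e-12 else num / den
            f[rows] = f[rows] + nu * c
    return f0, f


# ------------------------------------------------------------- closed forms

def test_init_f0_balanced_zero():
    assert init_f0(np.array([1, 1, -1, -1])) == 0.0


def test_init_f0_matches_1d_search():
    z = np.array([1.0, 1.0, 1.0, -1.0])
    grid = np.linspace(-3, 3, 20001)
    losses = [np.log1p(np.exp(-z * g)).sum() for g in grid]
    assert init_f0(z) == pytest.approx(np.log(3.0))
    assert init_f0(z) == pytest.approx(grid[int(np.argmin(losses))], abs=1e-3)


def test_init_f0_single_class_clamps_with_warning():
    with pytest.warns(UserWarning):
        assert init_f0(np.ones(5)) == 10.0


def test_negative_gradient_closed_forms():
    assert negative_gradient(np.array([1.0]), np.array([0.0]))[0] == 0.5
    assert negative_gradient(np.array([-1.0]), np.array([0.0]))[0] == -0.5
    assert negative_gradient(np.array([1.0]), np.array([50.0]))[0] == pytest.approx(0.0, abs=1e-20)
    r = negative_gradient(np.array([1.0, -1.0, 1.0]), np.array([-3.0, 2.0, 0.4]))
    assert np.all(np.abs(r) < 1.0)


def test_leaf_values_hand_arithmetic():
    # r = {0.5, 0.5}: c = 1.0 / (2 * 0.25) = 2.0
    c = leaf_values(np.array([0.5, 0.5]), np.array([0, 0]), 1)
    assert c[0] == pytest.approx(2.0)
    # cancellation: r = {0.5, -0.5} -> c = 0
    c = leaf_values(np.array([0.5, -0.5]), np.array([0, 0]), 1)
    assert c[0] == 0.0
    # vanishing |r|: guard returns 0
    c = leaf_values(np.array([1e-13, 1e-13]), np.array([0, 0]), 1)
    assert c[0] == 0.0


# ------------------------------------------------------------------- trees

def test_tree_finds_perfect_split():
    X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
    r = np.array([1.0, 1.0, -1.0, -1.0])
    t = RegressionTree(max_depth=1, min_leaf=1).fit(X, r)
    assert t.root.feature == 0
    assert -1.0 < t.root.threshold < 1.0
    np.testing.assert_allclose(t.predict(X), r)


def test_tree_split_matches_exhaustive_search():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(8, 1))
    r = rng.normal(size=8)
    t = RegressionTree(max_depth=1, min_leaf=1).fit(X, r)
    best = (np.inf, None)
    xs = np.sort(X[:, 0])
    for a, b in zip(xs[:-1], xs[1:]):
        thr = (a + b) / 2
        l, rr = r[X[:, 0] <= thr], r[X[:, 0] > thr]
        sse = ((l - l.mean()) ** 2).sum() + ((rr - rr.mean()) ** 2).sum()
        if sse < best[0]:
            best = (sse, thr)
    assert t.root.threshold == pytest.approx(best[1])


def test_tree_min_leaf_n_single_leaf():
    X = np.arange(10.0).reshape(-1, 1)
    r = np.sin(X[:, 0])
    t = RegressionTree(max_depth=3, min_leaf=10).fit(X, r)
    assert t.n_leaves == 1
    np.testing.assert_allclose(t.predict(X), r.mean())


# -------------------------------------------------------------------- boost

def test_one_iteration_matches_oracle_12_rows():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(12, 3))
    y = np.array([1, 0, 1, 1, 0, 1, 0, 1, 1, 0, 1, 0])
    model = GradientBoostingBernoulli(n_trees=1, learning_rate=0.05,
                                      max_depth=2, min_leaf=2).fit(X, y)
    f0, f_oracle = oracle_boost(X, y, 1, 0.05, 2, 2)
    assert model.f0_ == pytest.approx(f0, abs=1e-15)
    np.testing.assert_allclose(model.decision_function(X), f_oracle, atol=1e-12)


def test_multi_iteration_oracle_equivalence():
    rng = np.random.default_rng(11)
    X = rng.normal(size=(20, 3))
    y = (X[:, 0] + 0.5 * X[:, 1] + 0.3 * rng.normal(size=20) > 0).astype(int)
    model = GradientBoostingBernoulli(n_trees=3, learning_rate=0.05,
                                      max_depth=2, min_leaf=2).fit(X, y)
    _, f_oracle = oracle_boost(X, y, 3, 0.05, 2, 2)
    np.testing.assert_allclose(model.decision_function(X), f_oracle, atol=1e-12)


def test_separable_data_reaches_auc_one():
    rng = np.random.default_rng(1)
    X = np.r_[rng.normal(-2, 0.3, size=(30, 2)), rng.normal(2, 0.3, size=(30, 2))]
    y = np.r_[np.zeros(30), np.ones(30)].astype(int)
    model = GradientBoostingBernoulli(n_trees=50, max_depth=1).fit(X, y)
    assert auc(model.decision_function(X), y) == 1.0


def test_zero_learning_rate_constant_prediction():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(20, 2))
    y = (rng.random(20) > 0.5).astype(int)
    model = GradientBoostingBernoulli(n_trees=10, learning_rate=0.0).fit(X, y)
    np.testing.assert_allclose(model.decision_function(X), model.f0_)


def test_training_deviance_non_increasing_without_bagging():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(60, 4))
    y = (X[:, 0] > 0).astype(int)
    model = GradientBoostingBernoulli(n_trees=40, bag_fraction=1.0).fit(X, y)
    assert all(np.diff(model.train_deviance_) <= 1e-12)


def test_rejects_bad_inputs():
    X = np.zeros((10, 2))
    with pytest.raises(ValueError):
        GradientBoostingBernoulli().fit(X, np.arange(10))  # non-binary
    Xn = X.copy(); Xn[0, 0] = np.nan
    with pytest.raises(ValueError):
        GradientBoostingBernoulli().fit(Xn, np.r_[np.zeros(5), np.ones(5)])


def test_predict_proba_closed_forms_and_monotone():
    model = GradientBoostingBernoulli(n_trees=1)
    rng = np.random.default_rng(0)
    X = rng.normal(size=(20, 2))
    y = (X[:, 0] > 0).astype(int)
    model.fit(X, y)
    f = model.decision_function(X)
    p = model.predict_proba(X)[:, 1]
    np.testing.assert_allclose(p, 1 / (1 + np.exp(-f)))
    order = np.argsort(f)
    assert np.all(np.diff(p[order]) >= 0)
    # closed form: f = log 3 -> p = 0.75
    assert 1 / (1 + np.exp(-np.log(3))) == pytest.approx(0.75)


def test_optimal_iterations_noise_vs_signal():
    rng = np.random.default_rng(5)
    hits = 0
    for seed in range(10):
        r = np.random.default_rng(seed)
        X = r.normal(size=(60, 5))
        y = (r.random(60) > 0.5).astype(int)
        m = GradientBoostingBernoulli(n_trees=100, random_state=seed)
        if m.optimal_iterations(X, y) <= 10:
            hits += 1
    assert hits >= 8  # pure noise: early stopping almost always

    X = rng.normal(size=(80, 3))
    y = (X[:, 0] + 0.2 * rng.normal(size=80) > 0).astype(int)
    m = GradientBoostingBernoulli(n_trees=100, random_state=0)
    m_star = m.optimal_iterations(X, y)
    m.fit(X, y)
    assert m_star == m.optimal_iterations(X, y)  # deterministic under seed


def test_variable_importance_properties():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(100, 3))
    y = (X[:, 0] > 0).astype(int)
    m = GradientBoostingBernoulli(n_trees=30, max_depth=1).fit(X, y)
    imp = m.variable_importance()
    assert imp.sum() == pytest.approx(100.0)
    assert imp[0] > 95.0
    assert imp[2] == pytest.approx(0.0, abs=1e-12) or imp[2] < 5.0


def test_duplicated_feature_shares_importance():
    rng = np.random.default_rng(7)
    base = rng.normal(size=(150, 1))
    noise = rng.normal(size=(150, 2))
    y = (base[:, 0] > 0).astype(int)
    single = GradientBoostingBernoulli(n_trees=40, random_state=0).fit(
        np.c_[base, noise], y
    ).variable_importance()[0]
    dup = GradientBoostingBernoulli(n_trees=40, random_state=0).fit(
        np.c_[base, base, noise], y
    ).variable_importance()
    assert dup[0] + dup[1] == pytest.approx(single, rel=0.20)


def test_partial_dependence_shapes():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(80, 2))
    y = (X[:, 0] > 0).astype(int)
    m = GradientBoostingBernoulli(n_trees=30).fit(X, y)
    grid = np.linspace(-2, 2, 9)
    pd0 = m.partial_dependence(X, 0, grid)
    assert pd0[-1] > pd0[0]  # monotone in the planted direction
    pd1 = m.partial_dependence(X, 1, grid)
    assert np.ptp(pd1) < np.ptp(pd0) * 0.2  # near-flat for the inert feature

    const = GradientBoostingBernoulli(n_trees=5, learning_rate=0.0).fit(X, y)
    np.testing.assert_allclose(const.partial_dependence(X, 0, grid), const.f0_)


def test_serialization_round_trip_bit_identical(tmp_path):
    rng = np.random.default_rng(9)
    X = rng.normal(size=(50, 4))
    y = (X[:, 0] - X[:, 2] > 0).astype(int)
    m = GradientBoostingBernoulli(n_trees=20).fit(X, y)
    path = tmp_path / "model.json"
    m.save(path)
    m2 = GradientBoostingBernoulli.load(path)
    np.testing.assert_array_equal(m.decision_function(X), m2.decision_function(X))
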