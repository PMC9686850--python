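"""Binary gradient-boosted decision trees with Bernoulli (logistic) loss.

The model is the stagewise additive expansion

    f_0(x) = log(n+ / n-),
    f_m(x) = f_{m-1}(x) + nu * sum_j c_jm I(x in R_jm),

with labels coded y in {-1, +1}, loss L(y, f) = log(1 + exp(-y f)) (note: no
factor 2 in the exponent, so p = 1 / (1 + exp(-f))), negative gradient

    r_i = y_i / (1 + exp(y_i f(x_i))),

regression trees fitted to r by squared error, and the closed-form leaf
value approximation to the per-leaf line search

    c_j = sum_{i in leaf} r_i / sum_{i in leaf} |r_i| (1 - |r_i|).

Shrinkage nu, tree count M, depth and minimum leaf size are configurable;
the published configuration is nu = 0.05 with M = 10000 trees, and the
number of useful iterations is picked by stratified internal
cross-validation on held-out Bernoulli deviance.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np

from ._estimator import ParamsMixin
from ._tree import RegressionTree

__all__ = [
    "GradientBoostingBernoulli",
    "init_f0",
    "negative_gradient",
    "leaf_values",
    "bernoulli_deviance",
]

_F0_CLAMP = 10.0
_LEAF_CAP = 1e3


def init_f0(y_signed: np.ndarray) -> float:
    """Loss-minimising constant score: log(n+/n-); clamped if a class is absent."""
    y = np.asarray(y_signed)
    n_pos = int((y > 0).sum())
    n_neg = int((y < 0).sum())
    if n_pos == 0 or n_neg == 0:
        warnings.warn("single-class labels: clamping initial score", stacklevel=2)
        return _F0_CLAMP if n_neg == 0 else -_F0_CLAMP
    return float(np.log(n_pos / n_neg))


def negative_gradient(y_signed: np.ndarray, f: np.ndarray) -> np.ndarray:
    """r_i = y_i / (1 + exp(y_i f_i)); always in (-1, 1)."""
    y = np.asarray(y_signed, float)
    return y / (1.0 + np.exp(y * np.asarray(f, float)))


def leaf_values(r: np.ndarray, leaf_ids: np.ndarray, n_leaves: int) -> np.ndarray:
    """Closed-form per-leaf updates c_j = sum r / sum |r|(1-|r|), guarded."""
    num = np.bincount(leaf_ids, weights=r, minlength=n_leaves)
    den = np.bincount(leaf_ids, weights=np.abs(r) * (1.0 - np.abs(r)), minlength=n_leaves)
    c = np.where(den < 1e-12, 0.0, num / np.maximum(den, 1e-300))
    if np.any(np.abs(c) > _LEAF_CAP):
        warnings.warn("capping extreme leaf values", stacklevel=2)
        c = np.clip(c, -_LEAF_CAP, _LEAF_CAP)
    return c


def bernoulli_deviance(y_signed: np.ndarray, f: np.ndarray) -> float:
    """Mean 2*log(1 + exp(-y f)) (-2/n times the log-likelihood)."""
    m = np.asarray(y_signed, float) * np.asarray(f, float)
    # numerically stable log(1+exp(-m))
    return float(2.0 * np.mean(np.logaddexp(0.0, -m)))


class GradientBoostingBernoulli(ParamsMixin):
    """Binary GBDT classifier (labels 0/1) with shrinkage and optional bagging.

    Parameters
    ----------
    n_trees : boosting iterations M (desk-scale default 500; the published
        configuration uses 10000).
    learning_rate : shrinkage nu applied to every leaf update.
    max_depth, min_leaf : regression-tree limits.
    bag_fraction : subsampling fraction per iteration (1.0 = off).
    cv_folds : internal stratified folds for ``optimal_iterations``.
    random_state : seed for bagging and internal CV.

    Fitted attributes end in an underscore: ``f0_``, ``trees_``,
    ``train_deviance_``, ``n_features_``.
    """

    def __init__(self, n_trees: int = 500, learning_rate: float = 0.05,
                 max_depth: int = 3, min_leaf: int = 5, bag_fraction: float = 1.0,
                 cv_folds: int = 5, random_state: int = 0):
        self.n_trees = n_trees
        self.learning_rate = learning_rate
        self.max_depth = max_depth
        self.min_leaf = min_leaf
        self.bag_fraction = bag_fraction
        self.cv_folds = cv_folds
        self.random_state = random_state

    # ------------------------------------------------------------------ fit
    def fit(self, X: np.ndarray, y: np.ndarray) -> "GradientBoostingBernoulli":
        X = np.asarray(X, float)
        y = np.asarray(y)
        if X.ndim != 2 or np.isnan(X).any():
            raise ValueError("X must be 2-D without NaN")
        classes = np.unique(y)
        if not np.isin(classes, (0, 1)).all() or classes.size > 2:
            raise ValueError("y must be binary 0/1")
        if not 0 < self.learning_rate <= 1 and self.learning_rate != 0:
            raise ValueError("learning_rate must be in (0, 1] (or 0 for a constant model)")
        z = np.where(y > 0, 1.0, -1.0)
        n = X.shape[0]
        rng = np.random.default_rng(self.random_state)

        self.n_features_ = X.shape[1]
        self.f0_ = init_f0(z)
        self.trees_: list[RegressionTree] = []
        self.train_deviance_: list[float] = []
        f = np.full(n, self.f0_)
        for _ in range(self.n_trees):
            r = negative_gradient(z, f)
            if self.bag_fraction < 1.0:
                rows = rng.permutation(n)[: max(2 * self.min_leaf, int(self.bag_fraction * n))]
            else:
                rows = np.arange(n)
            tree = RegressionTree(self.max_depth, self.min_leaf).fit(X[rows], r[rows])
            c = leaf_values(r[rows], tree.apply(X[rows]), tree.n_leaves)
            tree.set_leaf_values(c)
            self.trees_.append(tree)
            f = f + self.learning_rate * tree.predict(X)
            self.train_deviance_.append(bernoulli_deviance(z, f))
        return self

    # -------------------------------------------------------------- predict
    def decision_function(self, X: np.ndarray, n_trees: int | None = None) -> np.ndarray:
        X = np.asarray(X, float)
        f = np.full(X.shape[0], self.f0_)
        trees = self.trees_ if n_trees is None else self.trees_[:n_trees]
        for tree in trees:
            f += self.learning_rate * tree.predict(X)
        return f

    def staged_decision_function(self, X: np.ndarray):
        X = np.asarray(X, float)
        f = np.full(X.shape[0], self.f0_)
        for tree in self.trees_:
            f = f + self.learning_rate * tree.predict(X)
            yield f

    def predict_proba(self, X: np.ndarray, n_trees: int | None = None) -> np.ndarray:
        p1 = 1.0 / (1.0 + np.exp(-self.decision_function(X, n_trees)))
        return np.c_[1.0 - p1, p1]

    def predict(self, X: np.ndarray, n_trees: int | None = None) -> np.ndarray:
        return (self.predict_proba(X, n_trees)[:, 1] >= 0.5).astype(int)

    # ------------------------------------------------- CV-optimal iterations
    def optimal_iterations(self, X: np.ndarray, y: np.ndarray) -> int:
        """M* minimising mean held-out Bernoulli deviance over stratified folds."""
        X = np.asarray(X, float)
        y = np.asarray(y)
        rng = np.random.default_rng(self.random_state)
        folds = _stratified_folds(y, self.cv_folds, rng)
        curves = np.zeros((self.cv_folds, self.n_trees))
        for k, val_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(len(y)), val_idx)
            sub = GradientBoostingBernoulli(**{**self.get_params(),
                                               "random_state": self.random_state + 1 + k})
            sub.fit(X[train_idx], y[train_idx])
            z_val = np.where(y[val_idx] > 0, 1.0, -1.0)
            for m, f_val in enumerate(sub.staged_decision_function(X[val_idx])):
                curves[k, m] = bernoulli_deviance(z_val, f_val)
        return int(np.argmin(curves.mean(axis=0))) + 1

    # ------------------------------------------------------------ importances
    def variable_importance(self) -> np.ndarray:
        """Relative influence: split SSE improvements summed per feature over
        all trees, normalised to percent (sums to 100)."""
        acc = np.zeros(self.n_features_)
        for tree in self.trees_:
            acc += tree.feature_improvements(self.n_features_)
        total = acc.sum()
        return 100.0 * acc / total if total > 0 else acc

    def partial_dependence(self, X: np.ndarray, feature: int, grid: np.ndarray) -> np.ndarray:
        """Mean decision score with one feature clamped across a value grid."""
        X = np.asarray(X, float)
        out = np.empty(len(grid))
        for g, v in enumerate(np.asarray(grid, float)):
            Xg = X.copy()
            Xg[:, feature] = v
            out[g] = self.decision_function(Xg).mean()
        return out

    # -------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        return {
            "params": self.get_params(),
            "f0": self.f0_,
            "n_features": self.n_features_,
            "train_deviance": self.train_deviance_,
            "trees": [t.to_dict() for t in self.trees_],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, d: dict) -> "GradientBoostingBernoulli":
        model = cls(**d["params"])
        model.f0_ = d["f0"]
        model.n_features_ = d["n_features"]
        model.train_deviance_ = list(d["train_deviance"])
        model.trees_ = [RegressionTree.from_dict(t) for t in d["trees"]]
        return model

    @classmethod
    def load(cls, path: str | Path) -> "GradientBoostingBernoulli":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _stratified_folds(y: np.ndarray, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Class-balanced fold index lists (validation indices per fold)."""
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(len(idx))]
        for k, chunk in enumerate(np.array_split(idx, n_folds)):
            folds[k].extend(chunk.tolist())
    return [np.sort(np.asarray(f, dtype=int)) for f in folds]
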