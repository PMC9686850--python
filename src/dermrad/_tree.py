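"""Least-squares regression trees and a bagged forest built on them.

The tree is the weak learner of the boosting model and, bagged with feature
subsampling, the scorer behind wrapper (encapsulation) feature selection.
Splits greedily minimise the squared error of the targets; ties are broken
deterministically towards the lower feature index, then the lower threshold,
so a fit is a pure function of its inputs.
"""

from __future__ import annotations

import numpy as np

__all__ = ["RegressionTree", "BaggedForest"]


class _Node:
    __slots__ = ("feature", "threshold", "left", "right", "value", "improvement", "leaf_id")

    def __init__(self) -> None:
        self.feature = -1
        self.threshold = 0.0
        self.left = None
        self.right = None
        self.value = 0.0
        self.improvement = 0.0
        self.leaf_id = -1


def _best_split(X: np.ndarray, r: np.ndarray, feat_ids: np.ndarray, min_leaf: int):
    """Vectorised exhaustive split search over the given feature columns.

    Returns (feature, threshold, gain_improvement) or None. Gain is the SSE
    reduction versus the unsplit node.
    """
    n = X.shape[0]
    if n < 2 * min_leaf:
        return None
    Xs = X[:, feat_ids]
    order = np.argsort(Xs, axis=0, kind="stable")
    xs = np.take_along_axis(Xs, order, axis=0)
    rs = r[order]
    csum = np.cumsum(rs, axis=0)
    total = csum[-1]
    k = np.arange(1, n, dtype=float)[:, None]
    left_sum = csum[:-1]
    with np.errstate(invalid="ignore"):
        score = left_sum**2 / k + (total - left_sum) ** 2 / (n - k)
    valid = (xs[:-1] < xs[1:]) & (k >= min_leaf) & ((n - k) >= min_leaf)
    score = np.where(valid, score, -np.inf)
    best = score.max()
    if not np.isfinite(best):
        return None
    # every column sums the same targets, so the unsplit baseline is shared
    base = float(total[0] ** 2 / n)
    cand = np.argwhere(score == best)
    col = int(cand[:, 1].min())  # lower feature index wins ties
    pos = int(cand[cand[:, 1] == col][:, 0].min())  # then lower threshold
    thr = float((xs[pos, col] + xs[pos + 1, col]) / 2.0)
    return int(feat_ids[col]), thr, float(best - base)


class RegressionTree:
    """Greedy binary regression tree with depth and leaf-size limits."""

    def __init__(self, max_depth: int = 3, min_leaf: int = 5):
        self.max_depth = max_depth
        self.min_leaf = min_leaf
        self.root: _Node | None = None
        self.n_leaves = 0

    def fit(self, X: np.ndarray, r: np.ndarray, feat_ids: np.ndarray | None = None) -> "RegressionTree":
        X = np.asarray(X, float)
        r = np.asarray(r, float)
        if feat_ids is None:
            feat_ids = np.arange(X.shape[1])
        self.n_leaves = 0
        self.root = self._grow(X, r, np.sort(np.asarray(feat_ids)), self.max_depth)
        return self

    def _grow(self, X, r, feat_ids, depth) -> _Node:
        node = _Node()
        node.value = float(r.mean())
        split = None
        if depth > 0 and r.size >= 2 * self.min_leaf and np.ptp(r) > 0:
            split = _best_split(X, r, feat_ids, self.min_leaf)
        if split is None or split[2] <= 1e-12:
            node.leaf_id = self.n_leaves
            self.n_leaves += 1
            return node
        feat, thr, gain = split
        node.feature, node.threshold, node.improvement = feat, thr, gain
        go_left = X[:, feat] <= thr
        node.left = self._grow(X[go_left], r[go_left], feat_ids, depth - 1)
        node.right = self._grow(X[~go_left], r[~go_left], feat_ids, depth - 1)
        return node

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf id for every row."""
        X = np.asarray(X, float)
        out = np.empty(X.shape[0], dtype=np.int64)

        def rec(node: _Node, idx: np.ndarray) -> None:
            if node.leaf_id >= 0:
                out[idx] = node.leaf_id
                return
            go_left = X[idx, node.feature] <= node.threshold
            rec(node.left, idx[go_left])
            rec(node.right, idx[~go_left])

        rec(self.root, np.arange(X.shape[0]))
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.leaf_values_array()[self.apply(X)]

    def leaf_values_array(self) -> np.ndarray:
        vals = np.zeros(self.n_leaves)

        def rec(node: _Node) -> None:
            if node.leaf_id >= 0:
                vals[node.leaf_id] = node.value
            else:
                rec(node.left)
                rec(node.right)

        rec(self.root)
        return vals

    def set_leaf_values(self, values: np.ndarray) -> None:
        def rec(node: _Node) -> None:
            if node.leaf_id >= 0:
                node.value = float(values[node.leaf_id])
            else:
                rec(node.left)
                rec(node.right)

        rec(self.root)

    def feature_improvements(self, n_features: int) -> np.ndarray:
        """Total squared-error improvement attributed to each feature."""
        acc = np.zeros(n_features)

        def rec(node: _Node) -> None:
            if node.leaf_id < 0:
                acc[node.feature] += node.improvement
                rec(node.left)
                rec(node.right)

        rec(self.root)
        return acc

    def used_features(self) -> set[int]:
        used: set[int] = set()

        def rec(node: _Node) -> None:
            if node.leaf_id < 0:
                used.add(node.feature)
                rec(node.left)
                rec(node.right)

        rec(self.root)
        return used

    # -- JSON-serialisable structure ---------------------------------------
    def to_dict(self) -> dict:
        def rec(node: _Node):
            if node.leaf_id >= 0:
                return {"leaf": node.leaf_id, "value": node.value}
            return {
                "feature": node.feature,
                "threshold": node.threshold,
                "improvement": node.improvement,
                "left": rec(node.left),
                "right": rec(node.right),
            }

        return {"max_depth": self.max_depth, "min_leaf": self.min_leaf,
                "n_leaves": self.n_leaves, "root": rec(self.root)}

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionTree":
        tree = cls(d["max_depth"], d["min_leaf"])
        tree.n_leaves = d["n_leaves"]

        def rec(dd) -> _Node:
            node = _Node()
            if "leaf" in dd:
                node.leaf_id = dd["leaf"]
                node.value = dd["value"]
            else:
                node.feature = dd["feature"]
                node.threshold = dd["threshold"]
                node.improvement = dd["improvement"]
                node.left = rec(dd["left"])
                node.right = rec(dd["right"])
            return node

        tree.root = rec(d["root"])
        return tree


class BaggedForest:
    """Bootstrap-aggregated regression trees with feature subsampling.

    Fitting 0/1 labels as regression targets makes the averaged prediction a
    probability-like score, which is all that AUC-based wrapper selection
    and permutation importance need.
    """

    def __init__(self, n_trees: int = 500, max_depth: int = 6, min_leaf: int = 3,
                 max_features: str | int = "sqrt", seed: int = 0):
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.min_leaf = min_leaf
        self.max_features = max_features
        self.seed = seed
        self.trees_: list[RegressionTree] = []
        self.oob_masks_: list[np.ndarray] = []
        self.n_features_: int = 0

    def _n_sub(self, p: int) -> int:
        if self.max_features == "sqrt":
            return max(1, int(np.sqrt(p)))
        return min(int(self.max_features), p)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BaggedForest":
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        n, p = X.shape
        self.n_features_ = p
        rng = np.random.default_rng(self.seed)
        self.trees_ = []
        self.oob_masks_ = []
        m = self._n_sub(p)
        for _ in range(self.n_trees):
            rows = rng.integers(0, n, size=n)
            oob = np.ones(n, bool)
            oob[rows] = False
            feats = rng.choice(p, size=m, replace=False)
            tree = RegressionTree(self.max_depth, self.min_leaf).fit(X[rows], y[rows], feats)
            self.trees_.append(tree)
            self.oob_masks_.append(oob)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        out = np.zeros(X.shape[0])
        for tree in self.trees_:
            out += tree.predict(X)
        return out / len(self.trees_)

    def oob_prediction(self, X: np.ndarray) -> np.ndarray:
        """Per-row average over trees whose bootstrap missed the row."""
        n = X.shape[0]
        tot = np.zeros(n)
        cnt = np.zeros(n)
        for tree, oob in zip(self.trees_, self.oob_masks_):
            if oob.any():
                tot[oob] += tree.predict(X[oob])
                cnt[oob] += 1
        with np.errstate(invalid="ignore"):
            return np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)

    def permutation_importance(self, X: np.ndarray, y: np.ndarray, score_fn, seed: int = 0) -> np.ndarray:
        """Out-of-bag permutation importance: drop in score when one feature
        is shuffled. Only trees that actually use the feature are re-evaluated."""
        X = np.asarray(X, float)
        n, p = X.shape
        rng = np.random.default_rng(seed)
        base_contrib = []
        cnt = np.zeros(n)
        tot = np.zeros(n)
        for tree, oob in zip(self.trees_, self.oob_masks_):
            pred = np.zeros(n)
            pred[oob] = tree.predict(X[oob])
            base_contrib.append(pred)
            tot += pred
            cnt += oob
        ok = cnt > 0
        base_score = score_fn(tot[ok] / cnt[ok], y[ok])
        by_feature = {}
        for t, tree in enumerate(self.trees_):
            for f in tree.used_features():
                by_feature.setdefault(f, []).append(t)
        imp = np.zeros(p)
        for f in range(p):
            trees_f = by_feature.get(f, [])
            if not trees_f:
                continue
            Xp = X.copy()
            Xp[:, f] = X[rng.permutation(n), f]
            tot_p = tot.copy()
            for t in trees_f:
                oob = self.oob_masks_[t]
                tot_p -= base_contrib[t]
                upd = np.zeros(n)
                upd[oob] = self.trees_[t].predict(Xp[oob])
                tot_p += upd
            imp[f] = base_score - score_fn(tot_p[ok] / cnt[ok], y[ok])
        return imp
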