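"""Train/validation evaluation: repeated stratified 70/30 splits, rank AUC,
DeLong confidence intervals, and the three-predictor-set experiment
(clinical | radiomics | combined).

The five "models" are five independent stratified 70/30 splits of the full
dataset (a per-sub-fold literal reading -- split each of 5 disjoint folds
internally 70/30 -- is available via ``scheme.per_subfold=True``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gbdt import GradientBoostingBernoulli

__all__ = ["SplitScheme", "EvalReport", "make_splits", "auc", "delong_variance",
           "delong_ci", "run_experiment"]


@dataclass
class SplitScheme:
    n_models: int = 5
    train_fraction: float = 0.70
    stratified: bool = True
    seed: int = 0
    per_subfold: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


def make_splits(y: np.ndarray, scheme: SplitScheme) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-model (train, validation) index pairs, class-stratified."""
    y = np.asarray(y)
    n = len(y)
    rng = np.random.default_rng(scheme.seed)
    pairs = []
    if scheme.per_subfold:
        # literal reading: 5 disjoint folds, each split 70/30 internally
        folds: list[list[int]] = [[] for _ in range(scheme.n_models)]
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            idx = idx[rng.permutation(len(idx))]
            for k, chunk in enumerate(np.array_split(idx, scheme.n_models)):
                folds[k].extend(chunk.tolist())
        for fold in folds:
            fold = np.asarray(sorted(fold))
            tr, va = _stratified_take(y[fold], scheme.train_fraction, rng)
            pairs.append((fold[tr], fold[va]))
        return pairs
    for _ in range(scheme.n_models):
        tr, va = _stratified_take(y, scheme.train_fraction, rng)
        pairs.append((tr, va))
    return pairs


def _stratified_take(y: np.ndarray, frac: float, rng: np.random.Generator):
    train, val = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(len(idx))]
        k = int(round(frac * len(idx)))
        train.extend(idx[:k].tolist())
        val.extend(idx[k:].tolist())
    return np.sort(np.asarray(train, int)), np.sort(np.asarray(val, int))


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalised Mann-Whitney U statistic; ties count one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = labels > 0
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _midrank_components(scores_pos: np.ndarray, scores_neg: np.ndarray):
    """DeLong structural components V10 (per positive) and V01 (per negative)."""
    m, n = len(scores_pos), len(scores_neg)
    allv = np.concatenate([scores_pos, scores_neg])
    tz = stats.rankdata(allv)
    tx = stats.rankdata(scores_pos)
    ty = stats.rankdata(scores_neg)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return v10, v01


def delong_variance(scores: np.ndarray, labels: np.ndarray) -> float:
    """Nonparametric AUC variance from the DeLong structural components."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = labels > 0
    if pos.sum() < 2 or (~pos).sum() < 2:
        raise ValueError("DeLong variance needs >= 2 members per class")
    v10, v01 = _midrank_components(scores[pos], scores[~pos])
    return float(np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01))


def delong_ci(scores: np.ndarray, labels: np.ndarray, level: float = 0.95):
    """(AUC, low, high): Wald interval on the DeLong SE, truncated to [0, 1]."""
    a = auc(scores, labels)
    se = float(np.sqrt(delong_variance(scores, labels)))
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    return a, max(0.0, a - z * se), min(1.0, a + z * se)


@dataclass
class ModelResult:
    train_auc: float
    train_ci: tuple[float, float]
    val_auc: float
    val_ci: tuple[float, float]
    n_trees_used: int
    roc_points: pd.DataFrame | None = None


@dataclass
class EvalReport:
    kind: str
    feature_names: list[str]
    models: list[ModelResult] = field(default_factory=list)
    importance_mean: pd.Series | None = None
    importance_sd: pd.Series | None = None

    @property
    def mean_validation_auc(self) -> float:
        return float(np.mean([m.val_auc for m in self.models]))

    @property
    def best_validation_auc(self) -> float:
        return float(np.max([m.val_auc for m in self.models]))

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "feature_names": list(self.feature_names),
            "models": [
                {
                    "train_auc": m.train_auc, "train_ci": list(m.train_ci),
                    "val_auc": m.val_auc, "val_ci": list(m.val_ci),
                    "n_trees_used": m.n_trees_used,
                }
                for m in self.models
            ],
            "importance_mean": None if self.importance_mean is None
            else self.importance_mean.to_dict(),
            "importance_sd": None if self.importance_sd is None
            else self.importance_sd.to_dict(),
        }


def _roc_points(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    order = np.argsort(-scores, kind="stable")
    lab = np.asarray(labels)[order] > 0
    tp = np.concatenate([[0], np.cumsum(lab)])
    fp = np.concatenate([[0], np.cumsum(~lab)])
    return pd.DataFrame({"fpr": fp / max(fp[-1], 1), "tpr": tp / max(tp[-1], 1)})


def run_experiment(
    features: pd.DataFrame | None,
    clinical: pd.DataFrame | None,
    labels: np.ndarray,
    kind: str,
    gbdt_params: dict | None = None,
    scheme: SplitScheme | None = None,
    select_iterations: bool = True,
    keep_roc: bool = False,
) -> EvalReport:
    """Train/validate the GBDT over the split scheme on one predictor set.

    ``kind`` picks the predictors: ``clinical`` (screened clinical and
    dosimetric variables), ``radiomics`` (screened radiomics features) or
    ``combined`` (their union). Validation scores never see training rows.
    """
    if kind == "clinical":
        table = clinical
    elif kind == "radiomics":
        table = features
    elif kind == "combined":
        table = pd.concat([clinical, features], axis=1)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    if table is None or table.shape[1] == 0:
        raise ValueError(f"no predictors available for kind {kind!r}")
    X = table.to_numpy(float)
    y = np.asarray(labels)
    scheme = scheme or SplitScheme()
    params = {"random_state": scheme.seed, **(gbdt_params or {})}

    report = EvalReport(kind=kind, feature_names=list(table.columns))
    importances = []
    for k, (tr, va) in enumerate(make_splits(y, scheme)):
        model = GradientBoostingBernoulli(**{**params, "random_state": params["random_state"] + k})
        if select_iterations:
            m_star = model.optimal_iterations(X[tr], y[tr])
        else:
            m_star = params.get("n_trees", model.n_trees)
        model.fit(X[tr], y[tr])
        s_tr = model.decision_function(X[tr], n_trees=m_star)
        s_va = model.decision_function(X[va], n_trees=m_star)
        a_tr, lo_tr, hi_tr = delong_ci(s_tr, y[tr])
        a_va, lo_va, hi_va = delong_ci(s_va, y[va])
        res = ModelResult(a_tr, (lo_tr, hi_tr), a_va, (lo_va, hi_va), m_star)
        if keep_roc:
            res.roc_points = _roc_points(s_va, y[va])
        report.models.append(res)
        importances.append(model.variable_importance())
    imp = np.vstack(importances)
    report.importance_mean = pd.Series(imp.mean(axis=0), index=table.columns)
    report.importance_sd = pd.Series(imp.std(axis=0, ddof=1), index=table.columns)
    return report
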