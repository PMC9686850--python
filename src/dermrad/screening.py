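"""Radiomics feature-screening cascade and clinical pre-screen.

Fixed stage order: Mann-Whitney U filter (p < 0.05) -> variance filter
(min-max-scaled variance > 0.05) -> pairwise-correlation filter (|r| >= 0.9,
keep the member more correlated with the outcome) -> iterative VIF filter
(remove max-VIF while any VIF >= 10) -> wrapper (encapsulation) selection by
backward elimination of a bagged-tree forest scored by stratified CV AUC.
Every stage can only shrink the set; a replayable report records each drop
with its reason and statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._estimator import ParamsMixin
from ._tree import BaggedForest
from .evaluation import auc

__all__ = ["ScreeningConfig", "ScreeningReport", "mwu_filter", "variance_filter",
           "correlation_filter", "vif_filter", "wrapper_select",
           "clinical_prescreen", "ScreeningCascade"]


@dataclass
class ScreeningConfig:
    mwu_alpha: float = 0.05
    variance_threshold: float = 0.05
    corr_threshold: float = 0.9
    vif_threshold: float = 10.0
    wrapper_max_features: int = 20
    wrapper_forest_size: int = 500
    wrapper_step_fraction: float = 0.1
    cv_folds: int = 5
    seed: int = 0
    force_k: int | None = None

    def __post_init__(self) -> None:
        if min(self.mwu_alpha, self.variance_threshold, self.corr_threshold,
               self.vif_threshold) <= 0:
            raise ValueError("thresholds must be positive")
        if self.wrapper_max_features < 1:
            raise ValueError("wrapper_max_features must be >= 1")


@dataclass
class ScreeningReport:
    stages: list[dict] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)
    wrapper_trajectory: list[dict] = field(default_factory=list)
    final_vif: dict = field(default_factory=dict)

    def add_stage(self, name: str, dropped: dict) -> None:
        self.stages.append({"stage": name, "dropped": dropped})

    def replay(self, columns: list[str]) -> list[str]:
        """Re-apply the recorded drop sequence; must reproduce ``retained``."""
        cols = list(columns)
        for st in self.stages:
            cols = [c for c in cols if c not in st["dropped"]]
        return cols

    def to_dict(self) -> dict:
        return {"stages": self.stages, "retained": self.retained,
                "wrapper_trajectory": self.wrapper_trajectory,
                "final_vif": self.final_vif}


def _minmax(X: np.ndarray) -> np.ndarray:
    lo, hi = np.nanmin(X, axis=0), np.nanmax(X, axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    return (X - lo) / span


def mwu_filter(X: pd.DataFrame, y: np.ndarray, alpha: float = 0.05):
    """Two-sided Mann-Whitney U per feature (normal approximation with tie
    correction); keep p < alpha. Constant features get p = 1."""
    y = np.asarray(y)
    A = X.to_numpy(float)
    g1, g0 = A[y > 0], A[y <= 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.mannwhitneyu(g1, g0, axis=0, method="asymptotic",
                                 alternative="two-sided")
    pvals = np.asarray(res.pvalue, float)
    constant = np.ptp(A, axis=0) == 0
    pvals = np.where(constant | ~np.isfinite(pvals), 1.0, pvals)
    pseries = pd.Series(pvals, index=X.columns)
    keep = pseries.index[pvals < alpha].tolist()
    return keep, pseries


def variance_filter(X: pd.DataFrame, threshold: float = 0.05):
    """Keep features whose min-max-scaled variance exceeds the threshold."""
    v = _minmax(X.to_numpy(float)).var(axis=0)  # population variance
    vs = pd.Series(v, index=X.columns)
    return vs.index[v > threshold].tolist(), vs


def correlation_filter(X: pd.DataFrame, y: np.ndarray, threshold: float = 0.9):
    """Drop one member of every near-duplicate pair (|Pearson r| >= threshold).

    Pairs are processed in descending |r| (ties by name); the member with the
    smaller |point-biserial correlation to the outcome| is dropped, later
    pairs involving an already-dropped feature are skipped.
    """
    cols = list(X.columns)
    A = X.to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(A, rowvar=False)
    R = np.nan_to_num(R, nan=0.0)
    yv = np.asarray(y, float)
    yc = yv - yv.mean()
    Ac = A - A.mean(axis=0)
    denom = np.sqrt((Ac**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r_y = np.where(denom > 0, (Ac * yc[:, None]).sum(axis=0) / denom, 0.0)

    iu = np.triu_indices(len(cols), k=1)
    absr = np.abs(R[iu])
    hits = np.flatnonzero(absr >= threshold)
    order = sorted(
        hits, key=lambda h: (-absr[h], cols[iu[0][h]], cols[iu[1][h]])
    )
    dropped: dict = {}
    for h in order:
        i, j = int(iu[0][h]), int(iu[1][h])
        ci, cj = cols[i], cols[j]
        if ci in dropped or cj in dropped:
            continue
        # drop the one less correlated with the classification result
        if abs(r_y[i]) > abs(r_y[j]) or (abs(r_y[i]) == abs(r_y[j]) and ci < cj):
            victim, corr = cj, absr[h]
        else:
            victim, corr = ci, absr[h]
        dropped[victim] = float(corr)
    return [c for c in cols if c not in dropped], dropped


def _vifs(A: np.ndarray) -> np.ndarray:
    """VIF_j = 1 / (1 - R^2_j) from regressing column j on the others."""
    n, p = A.shape
    if p == 1:
        return np.ones(1)
    Z = A - A.mean(axis=0)
    out = np.empty(p)
    for j in range(p):
        yj = Z[:, j]
        ss_tot = float(yj @ yj)
        if ss_tot == 0:
            out[j] = 1.0
            continue
        Xj = np.c_[np.ones(n), np.delete(Z, j, axis=1)]
        beta, *_ = np.linalg.lstsq(Xj, yj, rcond=None)
        resid = yj - Xj @ beta
        r2 = 1.0 - float(resid @ resid) / ss_tot
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_filter(X: pd.DataFrame, threshold: float = 10.0):
    """Iteratively remove the max-VIF feature while any VIF >= threshold."""
    cols = list(X.columns)
    A = X.to_numpy(float)
    dropped: dict = {}
    while len(cols) > 1:
        v = _vifs(A)
        worst = int(np.argmax(v))
        if not (v[worst] >= threshold):
            break
        dropped[cols[worst]] = float(v[worst])
        cols.pop(worst)
        A = np.delete(A, worst, axis=1)
    final = dict(zip(cols, _vifs(A))) if cols else {}
    return cols, dropped, final


def wrapper_select(X: pd.DataFrame, y: np.ndarray, cfg: ScreeningConfig | None = None):
    """Encapsulation (wrapper) selection: backward elimination guided by
    forest permutation importance, scored by stratified CV AUC.

    Returns (selected columns, trajectory). The subset maximising mean CV
    AUC among sizes <= wrapper_max_features wins; ties go to the smaller
    subset. ``cfg.force_k`` pins the returned size instead.
    """
    cfg = cfg or ScreeningConfig()
    cols = list(X.columns)
    if len(cols) < 2:
        return cols, []
    y = np.asarray(y)
    A = _minmax(X.to_numpy(float))
    rng = np.random.default_rng(cfg.seed)
    current = list(range(len(cols)))
    trajectory = []
    best_sets: dict[int, tuple[float, list[int]]] = {}
    step = 0
    while True:
        cv_auc = _cv_forest_auc(A[:, current], y, cfg, seed=cfg.seed + 7919 * step)
        trajectory.append({"size": len(current),
                           "features": [cols[i] for i in current],
                           "cv_auc": cv_auc})
        best_sets[len(current)] = (cv_auc, list(current))
        if len(current) <= 1 or cfg.wrapper_step_fraction <= 0:
            break  # step fraction 0 = zero elimination steps
        forest = BaggedForest(cfg.wrapper_forest_size, seed=cfg.seed + step).fit(
            A[:, current], y
        )
        imp = forest.permutation_importance(A[:, current], y, auc, seed=cfg.seed + step)
        n_drop = max(1, int(np.ceil(cfg.wrapper_step_fraction * len(current))))
        n_drop = min(n_drop, len(current) - 1)
        order = np.argsort(imp, kind="stable")  # least important first
        drop_local = set(order[:n_drop].tolist())
        current = [c for k, c in enumerate(current) if k not in drop_local]
        step += 1

    if cfg.force_k is not None:
        sizes = sorted(best_sets)
        k = min(sizes, key=lambda s: (abs(s - cfg.force_k), s))
        chosen = best_sets[k][1]
    else:
        eligible = {s: v for s, v in best_sets.items() if s <= cfg.wrapper_max_features}
        if not eligible:
            s_min = min(best_sets)
            eligible = {s_min: best_sets[s_min]}
        # max mean CV AUC; ties -> smaller subset
        k = sorted(eligible, key=lambda s: (-eligible[s][0], s))[0]
        chosen = eligible[k][1]
    return [cols[i] for i in chosen], trajectory


def _cv_forest_auc(A: np.ndarray, y: np.ndarray, cfg: ScreeningConfig, seed: int) -> float:
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(cfg.cv_folds)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(len(idx))]
        for k, chunk in enumerate(np.array_split(idx, cfg.cv_folds)):
            folds[k].extend(chunk.tolist())
    aucs = []
    for k, val in enumerate(folds):
        val = np.asarray(sorted(val))
        tr = np.setdiff1d(np.arange(len(y)), val)
        forest = BaggedForest(cfg.wrapper_forest_size, seed=seed + k).fit(A[tr], y[tr])
        aucs.append(auc(forest.predict(A[val]), y[val]))
    return float(np.mean(aucs))


def clinical_prescreen(univariate_pvalues: pd.Series, alpha: float = 0.5) -> list[str]:
    """Variables whose univariate p-value is strictly below alpha."""
    return univariate_pvalues.index[univariate_pvalues < alpha].tolist()


class ScreeningCascade(ParamsMixin):
    """Transformer running the full radiomics cascade with a replayable report.

    ``fit`` learns the retained feature set; ``transform`` subsets any table
    with the same columns. Fitted attributes: ``selected_``, ``report_``.
    """

    def __init__(self, mwu_alpha: float = 0.05, variance_threshold: float = 0.05,
                 corr_threshold: float = 0.9, vif_threshold: float = 10.0,
                 wrapper_max_features: int = 20, wrapper_forest_size: int = 500,
                 wrapper_step_fraction: float = 0.1, cv_folds: int = 5,
                 random_state: int = 0, force_k: int | None = None):
        self.mwu_alpha = mwu_alpha
        self.variance_threshold = variance_threshold
        self.corr_threshold = corr_threshold
        self.vif_threshold = vif_threshold
        self.wrapper_max_features = wrapper_max_features
        self.wrapper_forest_size = wrapper_forest_size
        self.wrapper_step_fraction = wrapper_step_fraction
        self.cv_folds = cv_folds
        self.random_state = random_state
        self.force_k = force_k

    def _config(self) -> ScreeningConfig:
        return ScreeningConfig(
            mwu_alpha=self.mwu_alpha, variance_threshold=self.variance_threshold,
            corr_threshold=self.corr_threshold, vif_threshold=self.vif_threshold,
            wrapper_max_features=self.wrapper_max_features,
            wrapper_forest_size=self.wrapper_forest_size,
            wrapper_step_fraction=self.wrapper_step_fraction,
            cv_folds=self.cv_folds, seed=self.random_state, force_k=self.force_k,
        )

    def fit(self, X: pd.DataFrame, y: np.ndarray) -> "ScreeningCascade":
        cfg = self._config()
        report = ScreeningReport()

        keep, pvals = mwu_filter(X, y, cfg.mwu_alpha)
        report.add_stage("mwu", {c: float(pvals[c]) for c in X.columns if c not in keep})
        Xc = X[keep]

        keep, variances = variance_filter(Xc, cfg.variance_threshold)
        report.add_stage("variance",
                         {c: float(variances[c]) for c in Xc.columns if c not in keep})
        Xc = Xc[keep]

        keep, dropped = correlation_filter(Xc, y, cfg.corr_threshold)
        report.add_stage("correlation", dropped)
        Xc = Xc[keep]

        keep, dropped, final_vif = vif_filter(Xc, cfg.vif_threshold)
        report.add_stage("vif", dropped)
        report.final_vif = final_vif
        Xc = Xc[keep]

        keep, trajectory = wrapper_select(Xc, y, cfg)
        report.add_stage("wrapper", {c: None for c in Xc.columns if c not in keep})
        report.wrapper_trajectory = trajectory
        report.retained = list(keep)

        self.selected_ = list(keep)
        self.report_ = report
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.selected_]

    def fit_transform(self, X: pd.DataFrame, y: np.ndarray) -> pd.DataFrame:
        return self.fit(X, y).transform(X)
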