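"""Null handling and class rebalancing.

Clinical nulls: continuous columns are completed by iterative regression
imputation under a multivariate-normal working model (EM-style, each
incomplete column regressed on the others until the imputed values
stabilise); categorical columns by chained-equation multiple imputation
(m = 5 stochastic draws combined by modal value). Observed cells are never
altered.

Radiomics nulls: any feature column containing a null is dropped outright
(the null fraction is low and the bank is highly redundant), with a
per-ROI retention report.

SMOTE: synthetic minority rows are convex combinations x + u (x_nn - x),
u ~ U(0, 1), with the neighbour drawn among the k minority nearest
neighbours in min-max-scaled Euclidean space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._estimator import ParamsMixin

__all__ = ["impute_clinical", "drop_null_features", "Smote", "smote", "encode_clinical"]


# ---------------------------------------------------------------------------
# clinical imputation


def _iterative_continuous(df: pd.DataFrame, cols: list[str], tol: float = 1e-6,
                          max_iter: int = 100) -> pd.DataFrame:
    """Regression (EM-style) imputation of continuous columns."""
    work = df[cols].astype(float).copy()
    null_mask = work.isna()
    # start from column means
    work = work.fillna(work.mean())
    X = work.to_numpy()
    miss = null_mask.to_numpy()
    for _ in range(max_iter):
        delta = 0.0
        for j, col in enumerate(cols):
            rows = miss[:, j]
            if not rows.any():
                continue
            others = np.delete(X, j, axis=1)
            A = np.c_[np.ones(len(X)), others]
            beta, *_ = np.linalg.lstsq(A[~rows], X[~rows, j], rcond=None)
            pred = A[rows] @ beta
            delta = max(delta, float(np.abs(pred - X[rows, j]).max(initial=0.0)))
            X[rows, j] = pred
        if delta < tol:
            break
    out = df.copy()
    out[cols] = X
    return out


def _chained_categorical(df: pd.DataFrame, cols: list[str], numeric_cols: list[str],
                         m: int = 5, seed: int = 0) -> pd.DataFrame:
    """Chained-equation MI for categoricals: m draws from per-category
    probabilities fitted by multinomial logit on the numeric columns,
    combined by modal value. Falls back to the marginal mode when a model
    cannot be fitted."""
    rng = np.random.default_rng(seed)
    out = df.copy()
    Z = df[numeric_cols].astype(float)
    Z = Z.fillna(Z.mean()).to_numpy() if numeric_cols else np.empty((len(df), 0))
    for col in cols:
        nulls = out[col].isna()
        if not nulls.any():
            continue
        obs = ~nulls
        levels = pd.unique(out.loc[obs, col].astype(str))
        if len(levels) < 2 or obs.sum() < 10 or Z.shape[1] == 0:
            out.loc[nulls, col] = out.loc[obs, col].mode().iloc[0]
            continue
        try:
            import statsmodels.api as sm

            ycode = pd.Categorical(out.loc[obs, col].astype(str), categories=levels).codes
            A = sm.add_constant(Z[obs.to_numpy()], has_constant="add")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.MNLogit(ycode, A).fit(disp=0, maxiter=100)
            An = sm.add_constant(Z[nulls.to_numpy()], has_constant="add")
            probs = np.asarray(fit.predict(An))
        except Exception:
            p = out.loc[obs, col].astype(str).value_counts(normalize=True)
            probs = np.tile(p.reindex(levels).fillna(0).to_numpy(), (int(nulls.sum()), 1))
        draws = np.stack(
            [[rng.choice(len(levels), p=pr / pr.sum()) for pr in probs] for _ in range(m)]
        )
        modal = pd.DataFrame(draws).mode(axis=0).iloc[0].to_numpy().astype(int)
        out.loc[nulls, col] = np.asarray(levels)[modal]
    return out


def impute_clinical(table: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Complete a clinical table; continuous and categorical columns are
    detected from dtype. Rejects columns that are entirely null."""
    all_null = [c for c in table.columns if table[c].isna().all()]
    if all_null:
        raise ValueError(f"column(s) entirely null: {all_null}")
    frac = table.isna().mean()
    bad = frac[frac >= 0.5]
    if len(bad):
        raise ValueError(f"null fraction >= 50% in: {list(bad.index)}")
    cont = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    cat = [c for c in table.columns if c not in cont]
    out = table.copy()
    if cont:
        out = _iterative_continuous(out, cont)
    if cat:
        out = _chained_categorical(out, cat, cont, seed=seed)
    return out


# ---------------------------------------------------------------------------
# radiomics null-column removal


def drop_null_features(features: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Remove every feature column containing at least one null.

    Returns the reduced table plus a retention report with per-ROI retained
    counts (ROI inferred from the column-name prefix before ``_F``).
    """
    has_null = features.isna().any(axis=0)
    kept = features.loc[:, ~has_null]
    report: dict = {"n_input": int(features.shape[1]),
                    "n_retained": int(kept.shape[1]),
                    "dropped": list(features.columns[has_null]),
                    "per_roi_retained": {}}
    rois = sorted({c.split("_F")[0] for c in features.columns if "_F" in c})
    for roi in rois:
        cols = [c for c in kept.columns if c.startswith(roi + "_F")]
        report["per_roi_retained"][roi] = len(cols)
    return kept, report


# ---------------------------------------------------------------------------
# SMOTE


@dataclass
class SmoteConfig:
    k_neighbors: int = 5
    target_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if not 0 < self.target_ratio <= 1:
            raise ValueError("target_ratio must be in (0, 1]")


class Smote(ParamsMixin):
    """Synthetic Minority Oversampling: sampler with ``fit_resample``.

    Originals are preserved and the majority class untouched. With
    ``integer_magnification`` (the default, classic SMOTE) the minority is
    oversampled by whole multiples of itself up to
    ``round(target_ratio * majority count)``; disabling it synthesises
    exactly up to that target. Neighbour
    search runs in min-max-scaled space so no single feature dominates the
    Euclidean distance; synthesis happens in the original space.
    ``categorical_features`` (column indices) are rounded back to the nearest
    integer code after interpolation.
    """

    def __init__(self, k_neighbors: int = 5, target_ratio: float = 1.0,
                 categorical_features: tuple = (), random_state: int = 0,
                 integer_magnification: bool = True):
        self.k_neighbors = k_neighbors
        self.target_ratio = target_ratio
        self.categorical_features = categorical_features
        self.random_state = random_state
        self.integer_magnification = integer_magnification

    def fit_resample(self, X: np.ndarray, y: np.ndarray):
        SmoteConfig(self.k_neighbors, self.target_ratio, self.random_state)
        X = np.asarray(X, float)
        y = np.asarray(y)
        if np.isnan(X).any():
            raise ValueError("SMOTE requires complete numeric features")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ValueError("SMOTE expects exactly two classes")
        minority = classes[np.argmin(counts)]
        idx_min = np.flatnonzero(y == minority)
        n_min, n_maj = counts.min(), counts.max()
        if n_min < 2:
            raise ValueError("minority class needs >= 2 members")
        n_target = int(round(self.target_ratio * n_maj))
        n_new = max(0, n_target - n_min)
        if self.integer_magnification and n_new >= n_min:
            # classic SMOTE oversamples by whole multiples of the minority
            # class ("a number of magnification"), e.g. 70 -> 140
            n_new = (n_new // n_min) * n_min
        if n_new == 0:
            return X.copy(), y.copy()

        k = self.k_neighbors
        if k > n_min - 1:
            warnings.warn(f"k_neighbors clamped to {n_min - 1}", stacklevel=2)
            k = n_min - 1

        lo, hi = X.min(axis=0), X.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        S = (X[idx_min] - lo) / span
        d2 = ((S[:, None, :] - S[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)
        nn = np.argsort(d2, axis=1, kind="stable")[:, :k]

        rng = np.random.default_rng(self.random_state)
        base = np.tile(np.arange(n_min), int(np.ceil(n_new / n_min)))[:n_new]
        picked = nn[base, rng.integers(0, k, size=n_new)]
        u = rng.random(n_new)[:, None]
        Xb, Xn = X[idx_min[base]], X[idx_min[picked]]
        synth = Xb + u * (Xn - Xb)
        for j in self.categorical_features:
            synth[:, j] = np.round(synth[:, j])
        X_out = np.vstack([X, synth])
        y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
        return X_out, y_out


def smote(X: np.ndarray, y: np.ndarray, cfg: SmoteConfig | None = None,
          categorical_features: tuple = ()):
    """Functional wrapper over :class:`Smote`."""
    cfg = cfg or SmoteConfig()
    sampler = Smote(cfg.k_neighbors, cfg.target_ratio, categorical_features, cfg.seed)
    return sampler.fit_resample(X, y)


def encode_clinical(table: pd.DataFrame) -> pd.DataFrame:
    """Integer-code categorical clinical columns (ordinal by level order used
    at generation; unknown tables fall back to sorted-unique codes)."""
    from .cohort import TABLE1_MARGINALS

    out = pd.DataFrame(index=table.index)
    for col in table.columns:
        if pd.api.types.is_numeric_dtype(table[col]):
            out[col] = table[col].astype(float)
        else:
            levels = None
            if col in TABLE1_MARGINALS and TABLE1_MARGINALS[col]["kind"] == "categorical":
                levels = TABLE1_MARGINALS[col]["levels"]
            else:
                levels = sorted(table[col].dropna().astype(str).unique())
            codes = pd.Categorical(table[col].astype("string"), categories=levels).codes
            out[col] = np.where(codes < 0, np.nan, codes).astype(float)
    return out
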