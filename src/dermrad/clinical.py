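"""Univariate clinical tests and multivariable logistic regression.

Categorical variables default to a Pearson chi-square without continuity
correction; when any expected cell count falls below 5 a Fisher exact test
takes over (exact for 2x2, seeded Monte-Carlo permutation for larger
tables). Continuous variables use the two-sided Mann-Whitney U test.

The logistic model is fitted by Newton-Raphson maximum likelihood with
Wald inference, reporting Coefficient, Wald Z and Pr(>|Z|) per variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["UnivariateResult", "LogisticFit", "univariate_table", "fit_logistic"]


@dataclass
class UnivariateResult:
    variable: str
    test: str  # chi-square | fisher | mwu
    statistic: float
    p_value: float
    note: str = ""


def _fisher_rxk(table: np.ndarray, seed: int = 0, n_perm: int = 2000) -> float:
    """Monte-Carlo conditional (permutation) p-value for r x k tables,
    referenced to the chi-square statistic."""
    rng = np.random.default_rng(seed)
    obs_stat = stats.chi2_contingency(table, correction=False)[0]
    rows = np.repeat(np.arange(table.shape[0]), table.sum(axis=1).astype(int))
    cols = np.repeat(np.arange(table.shape[1]), table.sum(axis=0).astype(int))
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(cols)
        t = np.zeros_like(table)
        np.add.at(t, (rows, perm), 1)
        if stats.chi2_contingency(t, correction=False)[0] >= obs_stat - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def univariate_table(
    clinical: pd.DataFrame, labels: np.ndarray, yates: bool = False, seed: int = 0
) -> list[UnivariateResult]:
    """One test per clinical column against the binary outcome."""
    y = np.asarray(labels)
    results = []
    for col in clinical.columns:
        series = clinical[col]
        if pd.api.types.is_numeric_dtype(series) and series.nunique() > 6:
            v = series.to_numpy(float)
            ok = ~np.isnan(v)
            res = stats.mannwhitneyu(v[ok & (y > 0)], v[ok & (y <= 0)],
                                     alternative="two-sided", method="asymptotic")
            results.append(UnivariateResult(col, "mwu", float(res.statistic),
                                            float(res.pvalue)))
            continue
        tab = pd.crosstab(series.astype(str), y).to_numpy(float)
        if tab.shape[0] < 2:
            results.append(UnivariateResult(col, "chi-square", 0.0, 1.0,
                                            note="single category"))
            continue
        expected = stats.contingency.expected_freq(tab)
        if (expected < 5).any():
            if tab.shape == (2, 2):
                _, p = stats.fisher_exact(tab.astype(int))
                results.append(UnivariateResult(col, "fisher", float("nan"), float(p),
                                                note="expected count < 5"))
            else:
                p = _fisher_rxk(tab, seed=seed)
                results.append(UnivariateResult(col, "fisher", float("nan"), float(p),
                                                note="expected count < 5; Monte-Carlo"))
        else:
            chi2, p, _, _ = stats.chi2_contingency(tab, correction=yates)
            results.append(UnivariateResult(col, "chi-square", float(chi2), float(p)))
    return results


@dataclass
class LogisticFit:
    variables: list[str]
    coefficients: np.ndarray
    std_errors: np.ndarray
    wald_z: np.ndarray
    p_values: np.ndarray
    converged: bool
    n_used: int
    deviance_path: list[float] = field(default_factory=list)
    note: str = ""

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"Coefficient": self.coefficients, "Wald Z": self.wald_z,
             "Pr(>|Z|)": self.p_values},
            index=self.variables,
        )


def fit_logistic(
    X: np.ndarray | pd.DataFrame, y: np.ndarray,
    variable_names: list[str] | None = None,
    tol: float = 1e-8, max_iter: int = 50,
) -> LogisticFit:
    """Newton-Raphson ML logistic regression with an intercept.

    Perfect or quasi-separation is flagged (``converged=False``) and the
    coefficients are capped rather than diverging.
    """
    if isinstance(X, pd.DataFrame):
        variable_names = variable_names or list(X.columns)
        X = X.to_numpy(float)
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need n > number of variables + 1")
    names = ["(Intercept)"] + list(variable_names or [f"x{j+1}" for j in range(p)])
    A = np.c_[np.ones(n), X]
    beta = np.zeros(p + 1)
    deviances = []
    converged = False
    note = ""
    for _ in range(max_iter):
        eta = A @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        deviances.append(float(-2.0 * np.sum(
            y * np.log(np.clip(mu, 1e-12, 1)) + (1 - y) * np.log(np.clip(1 - mu, 1e-12, 1))
        )))
        W = mu * (1.0 - mu)
        grad = A.T @ (y - mu)
        H = (A * W[:, None]).T @ A
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(p + 1), grad)
        except np.linalg.LinAlgError:
            note = "singular Hessian"
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
        if np.max(np.abs(beta)) > 30:
            note = "separation detected: coefficients capped"
            beta = np.clip(beta, -30, 30)
            break
    if not converged and not note and np.max(np.abs(beta)) > 10:
        note = "separation detected: coefficients diverging"
    eta = A @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    W = mu * (1.0 - mu)
    H = (A * W[:, None]).T @ A
    try:
        cov = np.linalg.inv(H + 1e-10 * np.eye(p + 1))
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p + 1, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return LogisticFit(names, beta, se, z, pvals, converged, n, deviances, note)
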