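"""Inference layer: repeated-measures ANOVA, normality check, one-tailed
Pearson correlation, stepwise multiple regression, and the closed-form
consistency relations among a regression model's F, adjusted R-squared and
standardized beta.

Everything here is computed from explicit sums of squares / normal equations
rather than delegated, so that each statistic can be cross-checked against
independent oracles in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class AnovaResult:
    """One-way repeated-measures ANOVA (factor with k levels, n subjects)."""

    F: float
    df1: int
    df2: int
    p: float
    ss_factor: float
    ss_error: float
    ss_subject: float


@dataclass
class CorrelationResult:
    """Pearson correlation with a one-tailed t-test and KS normality checks."""

    r: float
    t: float
    df: int
    p_one_tailed: float
    ks_p: tuple[float, float]


@dataclass
class RegressionResult:
    """Final model of a stepwise multiple regression."""

    selected: list[str]
    beta_std: dict[str, float]
    coef: dict[str, float]          # unstandardized, includes "intercept"
    r2: float
    adj_r2: float
    F: float
    df1: int
    df2: int
    p: float
    trace: list[dict] = field(default_factory=list)


def rm_anova_oneway(data: np.ndarray) -> AnovaResult:
    """Repeated-measures ANOVA from the subjects x levels matrix.

    Two-way additive decomposition with subjects as a blocking factor:
    F = MS_factor / MS_error with df = (k - 1, (n - 1)(k - 1)); no sphericity
    correction is applied.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need an n x k matrix with n >= 2 subjects, k >= 2 levels")
    if not np.all(np.isfinite(data)):
        raise ValueError("matrix contains missing or non-finite cells")
    n, k = data.shape
    grand = data.mean()
    ss_subject = k * np.sum((data.mean(axis=1) - grand) ** 2)
    ss_factor = n * np.sum((data.mean(axis=0) - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_error = ss_total - ss_subject - ss_factor
    df1, df2 = k - 1, (n - 1) * (k - 1)
    ms_error = ss_error / df2
    F = (ss_factor / df1) / ms_error if ms_error > 0 else (0.0 if ss_factor == 0 else np.inf)
    p = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return AnovaResult(float(F), df1, df2, p, float(ss_factor), float(ss_error),
                       float(ss_subject))


def ks_normality(x: np.ndarray) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test against N(mean(x), sd(x)).

    D is the maximum ECDF deviation computed directly from the order
    statistics; the p-value uses the asymptotic Kolmogorov distribution.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance sample")
    cdf = sps.norm.cdf(np.sort(x), loc=x.mean(), scale=sd)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - cdf)
    d_minus = np.max(cdf - (i - 1) / n)
    D = max(d_plus, d_minus)
    p = float(sps.kstwobign.sf(np.sqrt(n) * D))
    return float(D), p


def pearson_one_tailed(x: np.ndarray, y: np.ndarray,
                       alternative: str = "greater") -> CorrelationResult:
    """Pearson r with a one-tailed Student-t significance test.

    The KS normality check is computed for both variables and reported
    alongside (it does not gate the test).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1-d vectors with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt(np.sum(xc ** 2) * np.sum(yc ** 2))
    if denom == 0:
        raise ValueError("undefined correlation: zero variance in x or y")
    r = float(np.sum(xc * yc) / denom)
    df = x.size - 2
    if abs(r) >= 1.0:
        t = np.inf * np.sign(r)
    else:
        t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    if alternative == "greater":
        p = float(sps.t.sf(t, df))
    elif alternative == "less":
        p = float(sps.t.cdf(t, df))
    else:
        raise ValueError("alternative must be 'greater' or 'less'")
    if x.size >= 5:
        ks = (ks_normality(x)[1], ks_normality(y)[1])
    else:
        ks = (np.nan, np.nan)            # KS undefined at such small n
    return CorrelationResult(r=r, t=float(t), df=df, p_one_tailed=p, ks_p=ks)


def one_tailed_p_from_r(r: float, n: int) -> float:
    """Upper-tail p of a printed Pearson r at sample size n (Student t)."""
    if n <= 2:
        raise ValueError("need n > 2")
    if abs(r) >= 1:
        return 0.0 if r > 0 else 1.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(sps.t.sf(t, n - 2))


def _ols(X: np.ndarray, y: np.ndarray):
    """OLS with intercept: coefficients, their two-tailed p, R^2."""
    n = y.size
    design = np.column_stack([np.ones(n), X])
    k = design.shape[1]
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    df_resid = n - k
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = rss / df_resid
    cov = sigma2 * np.linalg.inv(design.T @ design)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, coef / se, np.inf * np.sign(coef))
    pvals = 2.0 * sps.t.sf(np.abs(tvals), df_resid)
    return coef, pvals, r2


def stepwise_regression(X: pd.DataFrame, y: np.ndarray, entry_p: float = 0.05,
                        removal_p: float = 0.10, max_steps: int = 100,
                        condition_limit: float = 1e8) -> RegressionResult:
    """Stepwise predictor selection with p-value entry/removal criteria.

    At each step the candidate with the smallest coefficient p-value below
    ``entry_p`` (given the current model) enters; afterwards any included
    predictor whose p-value exceeds ``removal_p`` is removed (worst first).
    Iteration stops when no entry or removal occurs.  An empty selection is a
    valid outcome.  Candidates that would make the standardized design matrix
    ill-conditioned (condition number above ``condition_limit``) are skipped
    with a warning.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if X.shape[0] != n or n <= 2:
        raise ValueError("X rows must match y and n must exceed 2")
    if not 0 < entry_p <= removal_p < 1:
        raise ValueError("require 0 < entry_p <= removal_p < 1")
    cols = list(X.columns)
    Xm = X.to_numpy(dtype=float)
    sx = Xm.std(axis=0, ddof=1)
    sy = y.std(ddof=1)
    Xz = (Xm - Xm.mean(axis=0)) / np.where(sx > 0, sx, 1.0)

    selected: list[int] = []
    trace: list[dict] = []
    for _ in range(max_steps):
        changed = False
        # --- entry scan
        best_j, best_p = None, np.inf
        if n - (len(selected) + 1) - 1 >= 1:
            for j, name in enumerate(cols):
                if j in selected or sx[j] == 0:
                    continue
                trial = Xz[:, selected + [j]]
                if np.linalg.cond(np.column_stack([np.ones(n), trial])) > condition_limit:
                    warnings.warn(f"skipping collinear predictor {name}", stacklevel=2)
                    trace.append({"action": "skip_collinear", "predictor": name})
                    continue
                _, pvals, _ = _ols(trial, y)
                p_cand = pvals[-1]
                if p_cand < best_p:
                    best_j, best_p = j, p_cand
        if best_j is not None and best_p < entry_p:
            selected.append(best_j)
            trace.append({"action": "enter", "predictor": cols[best_j], "p": float(best_p)})
            changed = True
        # --- removal scan
        while selected:
            _, pvals, _ = _ols(Xm[:, selected], y)
            worst = int(np.argmax(pvals[1:]))
            if pvals[1 + worst] > removal_p:
                name = cols[selected[worst]]
                trace.append({"action": "remove", "predictor": name,
                              "p": float(pvals[1 + worst])})
                del selected[worst]
                changed = True
            else:
                break
        if not changed:
            break

    names = [cols[j] for j in selected]
    if not selected:
        return RegressionResult(selected=[], beta_std={}, coef={"intercept": float(y.mean())},
                                r2=0.0, adj_r2=0.0, F=np.nan, df1=0, df2=n - 1,
                                p=np.nan, trace=trace)
    coef, _, r2 = _ols(Xm[:, selected], y)
    k = len(selected)
    df1, df2 = k, n - k - 1
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df2
    F = (r2 / df1) / ((1.0 - r2) / df2)
    p = float(sps.f.sf(F, df1, df2))
    beta_std = {name: float(coef[1 + i] * sx[selected[i]] / sy)
                for i, name in enumerate(names)}
    coefs = {"intercept": float(coef[0])}
    coefs.update({name: float(coef[1 + i]) for i, name in enumerate(names)})
    return RegressionResult(selected=names, beta_std=beta_std, coef=coefs, r2=float(r2),
                            adj_r2=float(adj_r2), F=float(F), df1=df1, df2=df2, p=p,
                            trace=trace)


def model_f_from_adj_r2(adj_r2: float, n: int, k: int) -> float:
    """Invert adjusted R^2 to recover the model F statistic.

    adj R^2 = 1 - (1 - R^2)(n - 1)/(n - k - 1); F = (R^2/k) / ((1 - R^2)/(n - k - 1)).
    """
    if k < 1 or n <= k + 1:
        raise ValueError("need k >= 1 and n > k + 1")
    if adj_r2 >= 1:
        raise ValueError("adjusted R^2 must be < 1")
    df2 = n - k - 1
    r2 = 1.0 - (1.0 - adj_r2) * df2 / (n - 1)
    if not 0.0 <= r2 < 1.0:
        raise ValueError(f"implied R^2 = {r2:.4f} outside [0, 1)")
    return (r2 / k) / ((1.0 - r2) / df2)


def f_from_single_beta(beta_std: float, n: int) -> float:
    """Model F implied by the standardized beta of a single-predictor model.

    In a one-predictor regression beta equals Pearson r, so
    F = t^2 with t = beta * sqrt((n - 2) / (1 - beta^2)).
    """
    if n <= 2:
        raise ValueError("need n > 2")
    if abs(beta_std) >= 1:
        raise ValueError("|standardized beta| must be < 1 for a single predictor")
    t = beta_std * np.sqrt((n - 2) / (1.0 - beta_std ** 2))
    return float(t * t)
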