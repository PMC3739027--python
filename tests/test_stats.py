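"""Inference layer vs independent oracles and closed-form identities."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import fmtheta as fm
from fmtheta.rois import gm_columns, wm_columns
from fmtheta.stats import _ols


# ---------------------------------------------------------------------------
# repeated-measures ANOVA

def brute_force_rm_anova(data):
    """Explicit cell-by-cell sums of squares (independent of the implementation)."""
    n, k = data.shape
    grand = sum(data[i][j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(data[i]) / k for i in range(n)]
    col = [sum(data[i][j] for i in range(n)) / n for j in range(k)]
    ss_f = n * sum((c - grand) ** 2 for c in col)
    ss_e = sum((data[i][j] - row[i] - col[j] + grand) ** 2
               for i in range(n) for j in range(k))
    df1, df2 = k - 1, (n - 1) * (k - 1)
    return (ss_f / df1) / (ss_e / df2), df1, df2


@pytest.mark.parametrize("n,k", [(5, 3), (6, 4), (8, 8), (19, 8)])
def test_rm_anova_matches_brute_force(n, k):
    rng = np.random.default_rng(n * 100 + k)
    data = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
    res = fm.rm_anova_oneway(data)
    F, df1, df2 = brute_force_rm_anova(data)
    assert res.F == pytest.approx(F, abs=1e-10)
    assert (res.df1, res.df2) == (df1, df2)
    assert 0 <= res.p <= 1


def test_rm_anova_matches_statsmodels():
    from statsmodels.stats.anova import AnovaRM

    rng = np.random.default_rng(42)
    data = rng.normal(size=(12, 5))
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(12), 5),
        "level": np.tile(np.arange(5), 12),
        "value": data.ravel()})
    sm = AnovaRM(long, "value", "subject", within=["level"]).fit()
    res = fm.rm_anova_oneway(data)
    assert res.F == pytest.approx(float(sm.anova_table["F Value"].iloc[0]), rel=1e-8)
    assert res.df1 == int(sm.anova_table["Num DF"].iloc[0])
    assert res.df2 == int(sm.anova_table["Den DF"].iloc[0])


def test_rm_anova_degrees_of_freedom_and_degenerate_input():
    res = fm.rm_anova_oneway(np.random.default_rng(0).normal(size=(19, 8)))
    assert (res.df1, res.df2) == (7, 126)
    # no variation across levels -> zero factor effect
    data = np.tile(np.arange(1.0, 6.0)[:, None], (1, 4))
    res0 = fm.rm_anova_oneway(data)
    assert res0.ss_factor == pytest.approx(0.0)
    assert res0.F == pytest.approx(0.0)
    with pytest.raises(ValueError):
        fm.rm_anova_oneway(np.array([[1.0, np.nan], [2.0, 3.0]]))


# ---------------------------------------------------------------------------
# Pearson one-tailed

def test_perfect_linearity():
    x = np.arange(10.0)
    res = fm.pearson_one_tailed(x, 2 * x + 1)
    assert res.r == pytest.approx(1.0)
    assert res.p_one_tailed < 1e-12


def test_matches_scipy_one_tailed():
    rng = np.random.default_rng(7)
    for _ in range(10):
        x, y = rng.normal(size=(2, 25))
        res = fm.pearson_one_tailed(x, y)
        ref = sps.pearsonr(x, y, alternative="greater")
        assert res.r == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_one_tailed == pytest.approx(ref.pvalue, rel=1e-9)
        assert res.t == pytest.approx(res.r * np.sqrt(res.df / (1 - res.r ** 2)),
                                      abs=1e-12)


def test_zero_variance_is_an_error():
    with pytest.raises(ValueError):
        fm.pearson_one_tailed(np.ones(10), np.arange(10.0))


def test_one_tailed_type_one_error_calibrated():
    """Under independence the one-tailed test rejects at ~alpha."""
    rng = np.random.default_rng(11)
    n, reps = 20, 50_000        # binomial noise ~0.001 at this size
    x = rng.normal(size=(reps, n))
    y = rng.normal(size=(reps, n))
    xc = x - x.mean(1, keepdims=True)
    yc = y - y.mean(1, keepdims=True)
    r = (xc * yc).sum(1) / np.sqrt((xc ** 2).sum(1) * (yc ** 2).sum(1))
    t = r * np.sqrt((n - 2) / (1 - r ** 2))
    p = sps.t.sf(t, n - 2)
    rate = (p < 0.05).mean()
    assert 0.045 <= rate <= 0.055
    # spot-check the vectorized replica against the implementation
    res = fm.pearson_one_tailed(x[0], y[0])
    assert res.p_one_tailed == pytest.approx(p[0], rel=1e-9)


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov normality

def test_ks_statistic_matches_direct_computation():
    x = np.array([1.1, 2.3, 0.4, 3.7, 1.9])
    D, p = fm.ks_normality(x)
    mu, sd = x.mean(), x.std(ddof=1)
    xs = np.sort(x)
    n = len(x)
    d_direct = max(max(abs((i + 1) / n - sps.norm.cdf(v, mu, sd)),
                       abs(sps.norm.cdf(v, mu, sd) - i / n))
                   for i, v in enumerate(xs))
    assert D == pytest.approx(d_direct, abs=1e-12)
    ref = sps.kstest(x, "norm", args=(mu, sd))
    assert D == pytest.approx(ref.statistic, abs=1e-12)


def test_ks_monte_carlo_behaviour():
    rng = np.random.default_rng(13)
    p_norm = [fm.ks_normality(rng.normal(size=1000))[1] for _ in range(100)]
    assert np.mean(np.array(p_norm) > 0.05) >= 0.90
    p_exp = [fm.ks_normality(rng.exponential(size=1000))[1] for _ in range(50)]
    assert np.mean(np.array(p_exp) < 0.05) >= 0.95


def test_ks_input_validation():
    with pytest.raises(ValueError):
        fm.ks_normality(np.ones(10))
    with pytest.raises(ValueError):
        fm.ks_normality(np.arange(3.0))


# ---------------------------------------------------------------------------
# stepwise regression

def _noise_design(rng, n, p=40):
    return pd.DataFrame(rng.normal(size=(n, p)),
                        columns=[f"x{j}" for j in range(p)])


def test_stepwise_null_selection_inflation():
    """With 40 candidates at entry p = .05, some predictor usually enters:
    the non-empty rate tracks the minimum of ~40 level-.05 tests."""
    rng = np.random.default_rng(17)
    nonempty = 0
    reps = 200
    for _ in range(reps):
        X = _noise_design(rng, 19)
        y = rng.normal(size=19)
        res = fm.stepwise_regression(X, y)
        nonempty += bool(res.selected)
    rate = nonempty / reps
    assert 0.6 < rate < 0.98          # ~1 - 0.95**40, a known stepwise hazard


def test_stepwise_power_single_true_predictor():
    rng = np.random.default_rng(19)
    first_hits = 0
    reps = 40
    for _ in range(reps):
        X = _noise_design(rng, 200)
        y = 0.8 * X["x3"].to_numpy() + rng.normal(size=200)   # R^2 ~ 0.4
        res = fm.stepwise_regression(X, y)
        entered = [t["predictor"] for t in res.trace if t["action"] == "enter"]
        first_hits += bool(entered and entered[0] == "x3")
    assert first_hits / reps >= 0.95


def test_stepwise_trace_reproducible_and_consistent():
    rng = np.random.default_rng(23)
    X = _noise_design(rng, 50, p=10)
    y = X["x1"].to_numpy() - 0.5 * X["x7"].to_numpy() + rng.normal(size=50)
    a = fm.stepwise_regression(X, y)
    b = fm.stepwise_regression(X, y)
    assert a.trace == b.trace
    assert a.selected == b.selected
    assert a.df1 == len(a.selected)
    assert a.df2 == 50 - len(a.selected) - 1
    assert a.adj_r2 == pytest.approx(
        1 - (1 - a.r2) * (50 - 1) / (50 - len(a.selected) - 1), abs=1e-12)


def test_stepwise_recovers_morphometry_effects_without_eeg():
    """Direct parameter recovery: regress rho itself on the ROI table."""
    config = fm.GeneratorConfig(n_subjects=200)
    profiles = fm.generate_cohort_profiles(config, 29)
    rho = np.array([p.responsiveness for p in profiles])
    table = fm.generate_morphometry_table(profiles, config, 31)
    gm = fm.stepwise_regression(table[gm_columns()], rho)
    assert gm.selected and gm.selected[0] == "gm_vol_mcc_r"
    assert gm.beta_std["gm_vol_mcc_r"] > 0
    wm = fm.stepwise_regression(table[wm_columns()], rho)
    assert "wm_vol_cb_l" in wm.selected and "wm_conc_cb_r" in wm.selected
    assert wm.beta_std["wm_vol_cb_l"] > 0
    assert wm.beta_std["wm_conc_cb_r"] < 0


def test_collinear_candidate_is_skipped():
    rng = np.random.default_rng(37)
    X = _noise_design(rng, 30, p=3)
    X["x2"] = 2.0 * X["x0"]               # exact collinearity with x0
    y = X["x0"].to_numpy() + 0.01 * rng.normal(size=30)
    with pytest.warns(UserWarning, match="collinear"):
        res = fm.stepwise_regression(X, y, condition_limit=1e6)
    assert "x2" not in res.selected or "x0" not in res.selected


# ---------------------------------------------------------------------------
# consistency relations

def test_model_f_from_adj_r2_inverts_the_definition():
    rng = np.random.default_rng(41)
    for _ in range(25):
        n = int(rng.integers(8, 60))
        k = int(rng.integers(1, 5))
        if n <= k + 2:
            continue
        r2 = float(rng.uniform(0.01, 0.95))
        adj = 1 - (1 - r2) * (n - 1) / (n - k - 1)
        F = (r2 / k) / ((1 - r2) / (n - k - 1))
        assert fm.model_f_from_adj_r2(adj, n, k) == pytest.approx(F, rel=1e-10)


def test_adj_r2_zero_implies_f_equal_one():
    for n, k in [(10, 1), (19, 2), (40, 3)]:
        assert fm.model_f_from_adj_r2(0.0, n, k) == pytest.approx(1.0, rel=1e-12)


def test_f_from_single_beta_limits_and_domain():
    assert fm.f_from_single_beta(0.0, 19) == 0.0
    with pytest.raises(ValueError):
        fm.f_from_single_beta(1.0, 19)
    with pytest.raises(ValueError):
        fm.model_f_from_adj_r2(0.99, 10, 9)


def test_consistency_triangle_on_fitted_single_predictor_model():
    """F from the fit, from adj R^2, and from beta agree to 1e-8."""
    rng = np.random.default_rng(43)
    n = 19
    x = rng.normal(size=n)
    y = 1.5 * x + 0.5 * rng.normal(size=n)   # strong effect: selection certain
    res = fm.stepwise_regression(pd.DataFrame({"x": x}), y)
    assert res.selected == ["x"]
    beta = res.beta_std["x"]
    assert fm.f_from_single_beta(beta, n) == pytest.approx(res.F, rel=1e-8)
    assert fm.model_f_from_adj_r2(res.adj_r2, n, 1) == pytest.approx(res.F, rel=1e-8)
    # direct brute-force F from the correlation coefficient
    r = np.corrcoef(x, y)[0, 1]
    F_direct = r ** 2 * (n - 2) / (1 - r ** 2)
    assert res.F == pytest.approx(F_direct, rel=1e-8)
    # and the OLS helper agrees with numpy's polyfit residuals
    coef, _, r2 = _ols(x[:, None], y)
    assert r2 == pytest.approx(r ** 2, rel=1e-10)


def test_one_tailed_p_from_printed_r():
    assert fm.one_tailed_p_from_r(0.607, 19) < 0.01
    assert fm.one_tailed_p_from_r(0.0, 19) == pytest.approx(0.5)
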