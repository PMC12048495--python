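import numpy as np
import pandas as pd
import pytest

from suipath import (
    compute_vif,
    did_effect,
    fit_logistic,
    fit_ols,
    fit_stats,
    iptw_effect,
    iv_2sls,
    naive_effect,
)
from suipath.simulate import generate_causal_benchmark


# ---------------------------------------------------------------------------
# logistic regression

def test_logistic_two_by_two_slope_is_log_odds_ratio():
    # table a=10 (x=1,y=1), b=10 (x=1,y=0), c=5 (x=0,y=1), d=20 (x=0,y=0)
    df = pd.DataFrame(
        {"y": [1] * 10 + [0] * 10 + [1] * 5 + [0] * 20,
         "x": [1] * 20 + [0] * 25}
    )
    fit = fit_logistic(df, "y", ["x"])
    assert fit.coef("x") == pytest.approx(np.log((10 * 20) / (10 * 5)), abs=1e-6)


def test_logistic_null_slope_within_3se():
    rng = np.random.default_rng(1)
    n = 4000
    df = pd.DataFrame({"x": rng.standard_normal(n), "y": rng.integers(0, 2, n)})
    fit = fit_logistic(df, "y", ["x"])
    assert abs(fit.coef("x")) < 3 * fit.se_of("x")
    assert abs(fit.coef("const")) < 3 * fit.se_of("const")


def test_logistic_constant_outcome_raises():
    df = pd.DataFrame({"y": [0, 0, 0, 0], "x": [1.0, 2.0, 3.0, 4.0]})
    with pytest.raises(ValueError, match="constant"):
        fit_logistic(df, "y", ["x"])


def test_logistic_matches_statsmodels():
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(8)
    n = 800
    x1, x2 = rng.standard_normal(n), rng.standard_normal(n)
    p = 1 / (1 + np.exp(-(0.3 + 0.8 * x1 - 0.5 * x2)))
    y = (rng.uniform(size=n) < p).astype(int)
    df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
    fit = fit_logistic(df, "y", ["x1", "x2"])
    ref = sm.Logit(y, sm.add_constant(np.column_stack([x1, x2]))).fit(disp=0)
    np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-6)
    np.testing.assert_allclose(fit.se, ref.bse, atol=1e-5)


# ---------------------------------------------------------------------------
# VIF

def test_vif_orthogonal_variables_is_one():
    # exactly orthogonal, zero-mean columns
    x = np.array([1.0, -1.0, 1.0, -1.0])
    z = np.array([1.0, 1.0, -1.0, -1.0])
    vt = compute_vif(pd.DataFrame({"x": x, "z": z}), ["x", "z"])
    assert vt["x"] == pytest.approx(1.0, abs=1e-12)
    assert vt["z"] == pytest.approx(1.0, abs=1e-12)


def test_vif_two_variable_closed_form():
    rng = np.random.default_rng(3)
    n = 500
    x = rng.standard_normal(n)
    e = rng.standard_normal(n)
    # construct exact sample correlation sqrt(0.75)
    x = (x - x.mean()) / x.std()
    e = e - e.mean()
    e -= x * (x @ e) / (x @ x)   # orthogonalize
    e /= e.std()
    r = np.sqrt(0.75)
    z = r * x + np.sqrt(1 - r * r) * e
    vt = compute_vif(pd.DataFrame({"x": x, "z": z}), ["x", "z"])
    assert vt["x"] == pytest.approx(4.0, abs=1e-9)
    assert vt["z"] == pytest.approx(4.0, abs=1e-9)


def test_vif_exact_collinearity_flagged_infinite():
    rng = np.random.default_rng(5)
    a, b = rng.standard_normal(100), rng.standard_normal(100)
    df = pd.DataFrame({"a": a, "b": b, "c": a + b})
    vt = compute_vif(df, ["a", "b", "c"])
    assert set(vt.flagged) == {"a", "b", "c"}


def test_vif_matches_statsmodels_including_constant_row():
    vif_ref = pytest.importorskip("statsmodels.stats.outliers_influence")
    rng = np.random.default_rng(11)
    n = 300
    X = rng.standard_normal((n, 3))
    X[:, 2] = 0.6 * X[:, 0] + 0.8 * rng.standard_normal(n) + 1.5
    df = pd.DataFrame(X, columns=["v1", "v2", "v3"])
    vt = compute_vif(df, ["v1", "v2", "v3"])
    design = np.column_stack([np.ones(n), X])
    for j, name in enumerate(["const", "v1", "v2", "v3"]):
        ref = vif_ref.variance_inflation_factor(design, j)
        assert vt[name] == pytest.approx(ref, rel=1e-8)


# ---------------------------------------------------------------------------
# model-fit statistics

def test_perfect_fit_has_adjusted_r2_one():
    x = np.arange(10.0)
    df = pd.DataFrame({"x": x, "y": 3.0 * x + 1.0})
    fit = fit_ols(df, "y", ["x"])
    assert fit.adj_r2 == pytest.approx(1.0)


def test_null_fit_adjusted_r2_near_zero():
    rng = np.random.default_rng(50)
    n, p = 2000, 5
    df = pd.DataFrame(rng.standard_normal((n, p)), columns=[f"x{i}" for i in range(p)])
    df["y"] = rng.standard_normal(n)
    fit = fit_ols(df, "y", [f"x{i}" for i in range(p)])
    assert abs(fit.adj_r2) < 0.01
    assert fit.f_p > 0.01


def test_single_predictor_f_equals_t_squared():
    rng = np.random.default_rng(7)
    df = pd.DataFrame({"x": rng.standard_normal(100)})
    df["y"] = 0.5 * df["x"] + rng.standard_normal(100)
    fit = fit_ols(df, "y", ["x"])
    t = fit.coef("x") / fit.se_of("x")
    assert fit.f_stat == pytest.approx(t**2, rel=1e-9)


def test_fit_stats_requires_enough_rows():
    df = pd.DataFrame({"x": [1.0, 2.0], "y": [1.0, 2.0]})
    with pytest.raises(ValueError, match="n > p"):
        fit_ols(df, "y", ["x"])


def test_ols_matches_statsmodels():
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(9)
    n = 400
    X = rng.standard_normal((n, 2))
    y = 1.0 + 2.0 * X[:, 0] - X[:, 1] + rng.standard_normal(n)
    df = pd.DataFrame({"x1": X[:, 0], "x2": X[:, 1], "y": y})
    fit = fit_ols(df, "y", ["x1", "x2"])
    ref = sm.OLS(y, sm.add_constant(X)).fit()
    np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-10)
    np.testing.assert_allclose(fit.se, ref.bse, atol=1e-10)
    assert fit.adj_r2 == pytest.approx(ref.rsquared_adj)
    assert fit.f_stat == pytest.approx(ref.fvalue)


# ---------------------------------------------------------------------------
# IPTW

def test_constant_scores_reduce_to_naive_difference():
    rng = np.random.default_rng(10)
    df = pd.DataFrame({"y": rng.standard_normal(100), "aq": rng.integers(0, 2, 100)})
    rep = iptw_effect(df, np.full(100, 0.5), "y")
    assert rep.estimate == pytest.approx(naive_effect(df, "y").estimate)


def test_constant_outcome_gives_zero_effect():
    df = pd.DataFrame({"y": np.ones(50), "aq": [1] * 25 + [0] * 25})
    rep = iptw_effect(df, np.full(50, 0.4), "y")
    assert rep.estimate == 0.0


def test_degenerate_scores_error_and_truncation_flag():
    df = pd.DataFrame({"y": [1.0, 2.0], "aq": [1, 0]})
    with pytest.raises(ValueError, match="truncate"):
        iptw_effect(df, np.array([0.0, 1.0]), "y")
    rep = iptw_effect(df, np.array([0.0, 1.0]), "y", truncate=True)
    assert np.isfinite(rep.estimate)


def test_iptw_recovers_injected_effect(benchmark):
    from suipath import fit_propensity

    pm = fit_propensity(benchmark, ["x1", "x2"], arm="treat")
    rep = iptw_effect(benchmark, pm, "y", arm="treat")
    assert abs(rep.estimate - 42.154) < 3 * rep.se
    # Horvitz–Thompson balance: weighted arm sizes ~ n
    n = len(benchmark)
    assert rep.extra["sum_w_treated"] == pytest.approx(n, rel=0.10)
    assert rep.extra["sum_w_control"] == pytest.approx(n, rel=0.10)


# ---------------------------------------------------------------------------
# IV / 2SLS

def test_instrument_identical_to_treatment_reduces_to_ols():
    rng = np.random.default_rng(12)
    n = 200
    t = rng.integers(0, 2, n).astype(float)
    y = 1.0 + 2.5 * t + rng.standard_normal(n)
    df = pd.DataFrame({"t": t, "y": y, "z": t})
    iv = iv_2sls(df, "y", "t", "z")
    ols = fit_ols(df, "y", ["t"])
    assert iv.estimate == pytest.approx(ols.coef("t"), rel=1e-10)


def test_six_point_wald_ratio():
    df = pd.DataFrame(
        {"z": [0, 0, 0, 1, 1, 1], "t": [0.0, 1.0, 0.0, 1.0, 1.0, 0.0],
         "y": [1.0, 3.0, 2.0, 6.0, 7.0, 5.0]}
    )
    z, t, y = df["z"].to_numpy(float), df["t"].to_numpy(float), df["y"].to_numpy(float)
    wald = np.cov(z, y)[0, 1] / np.cov(z, t)[0, 1]
    with pytest.warns(UserWarning, match="weak instrument"):
        iv = iv_2sls(df, "y", "t", "z")
    assert iv.estimate == pytest.approx(wald, rel=1e-10)


def test_iv_recovers_effect_under_unobserved_confounding():
    df = generate_causal_benchmark(
        n=8000, effect=42.0, seed=14, confounding=0.5, unobserved=1.0, instrument_strength=2.0
    )
    iv = iv_2sls(df, "y", "treat", "z")
    assert abs(iv.estimate - 42.0) < 3 * iv.se
    assert iv.extra["first_stage_f"] > 10
    # the naive contrast is visibly biased by the unobserved confounder
    naive = naive_effect(df, "y", arm="treat")
    assert abs(naive.estimate - 42.0) > abs(iv.estimate - 42.0)


def test_degenerate_instrument_raises():
    df = pd.DataFrame({"z": np.zeros(20), "t": np.r_[np.ones(10), np.zeros(10)],
                       "y": np.arange(20.0)})
    with pytest.raises(ValueError, match="instrument"):
        iv_2sls(df, "y", "t", "z")


# ---------------------------------------------------------------------------
# DiD

def test_did_four_mean_arithmetic():
    df = pd.DataFrame(
        {"pre": [20.0, 20.0, 21.0, 21.0], "post": [8.0, 8.0, 15.0, 15.0],
         "aq": [1, 1, 0, 0]}
    )
    rep = did_effect(df, "pre", "post")
    assert rep.estimate == pytest.approx(-6.0)


def test_did_parallel_trends_is_zero():
    df = pd.DataFrame({"pre": [10.0, 20.0, 30.0, 40.0], "post": [15.0, 25.0, 35.0, 45.0],
                       "aq": [1, 1, 0, 0]})
    assert did_effect(df, "pre", "post").estimate == pytest.approx(0.0, abs=1e-12)


def test_did_noiseless_injected_effect_is_exact():
    rng = np.random.default_rng(15)
    n = 100
    arm = np.r_[np.ones(n), np.zeros(n)].astype(int)
    pre = rng.normal(70, 5, 2 * n)
    improvement = 30.0 + (-42.154) * arm      # negative improvement for treated
    df = pd.DataFrame({"aq": arm, "pre": pre, "post": pre - improvement})
    rep = did_effect(df, "pre", "post")
    assert rep.estimate == pytest.approx(42.154, abs=1e-9)


def test_did_missing_arm_errors():
    df = pd.DataFrame({"pre": [1.0, 2.0], "post": [2.0, 3.0], "aq": [1, 1]})
    with pytest.raises(ValueError, match="arm"):
        did_effect(df, "pre", "post")


def test_did_recovers_effect_under_parallel_trends():
    # confounders shift baseline levels only: DiD is unbiased, the naive
    # post-score contrast is not
    df = generate_causal_benchmark(n=4000, effect=42.154, seed=16, trend_confounding=0.0)
    rep = did_effect(df, "pre", "post", arm="treat")
    # post - pre = -y, so the panel DiD equals minus the injected improvement
    assert abs(-rep.estimate - 42.154) < 3 * rep.se
    naive_post = naive_effect(df, "post", arm="treat")
    assert abs(-naive_post.estimate - 42.154) > abs(-rep.estimate - 42.154)


# ---------------------------------------------------------------------------
# shared properties

def test_estimators_invariant_to_row_order(benchmark):
    from suipath import fit_propensity

    shuffled = benchmark.sample(frac=1.0, random_state=0)
    pm_a = fit_propensity(benchmark, ["x1", "x2"], arm="treat")
    pm_b = fit_propensity(shuffled, ["x1", "x2"], arm="treat")
    a = iptw_effect(benchmark, pm_a, "y", arm="treat").estimate
    b = iptw_effect(shuffled, pm_b, "y", arm="treat").estimate
    assert a == pytest.approx(b, rel=1e-8)
    assert did_effect(benchmark, "pre", "post", arm="treat").estimate == pytest.approx(
        did_effect(shuffled, "pre", "post", arm="treat").estimate, rel=1e-8
    )
    assert iv_2sls(benchmark, "y", "treat", "z").estimate == pytest.approx(
        iv_2sls(shuffled, "y", "treat", "z").estimate, rel=1e-8
    )
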