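"""From-scratch causal adjustment suite.

Everything here is written against plain numpy linear algebra on purpose: the
point of the pipeline is that each adjustment step (multivariate logistic
regression, VIF screening, IPTW, instrumental-variable 2SLS, and
difference-in-differences) is auditable down to its normal equations.
Inference is Wald-style throughout: CI = estimate ± 1.96·SE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._glm import SeparationError, fit_logit
from .simulate import ARM_COLUMN, Cohort

__all__ = [
    "RegressionFit",
    "VIFTable",
    "EffectReport",
    "fit_logistic",
    "fit_ols",
    "fit_stats",
    "compute_vif",
    "iptw_effect",
    "iv_2sls",
    "did_effect",
    "naive_effect",
]


def _as_df(data: Cohort | pd.DataFrame) -> pd.DataFrame:
    return data.df if isinstance(data, Cohort) else data


@dataclass
class RegressionFit:
    """One fitted regression (logistic or linear)."""

    kind: str                          # "logistic" | "linear"
    names: list[str]
    coefficients: np.ndarray
    se: np.ndarray
    p_values: np.ndarray
    ci95: np.ndarray                   # (p, 2)
    n: int
    converged: bool = True
    r2: float = float("nan")
    adj_r2: float = float("nan")
    f_stat: float = float("nan")
    f_p: float = float("nan")
    sigma2: float = float("nan")

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.names.index(name)])

    def se_of(self, name: str) -> float:
        return float(self.se[self.names.index(name)])

    def p_of(self, name: str) -> float:
        return float(self.p_values[self.names.index(name)])

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "se": self.se,
                "p": self.p_values,
                "ci_lo": self.ci95[:, 0],
                "ci_hi": self.ci95[:, 1],
            },
            index=self.names,
        )


@dataclass
class VIFTable:
    """Variance inflation factors; ``inf`` flags exact collinearity."""

    table: pd.DataFrame                # index variable (+ "const"); column "vif"

    def __getitem__(self, name: str) -> float:
        return float(self.table.loc[name, "vif"])

    @property
    def flagged(self) -> list[str]:
        t = self.table.drop(index="const", errors="ignore")
        return list(t.index[np.isinf(t["vif"])])


@dataclass
class EffectReport:
    """One causal estimate with Wald inference and a method tag."""

    method: str                        # naive | matched | iptw | iv | did | regression
    estimate: float
    se: float
    outcome: str
    n_used: int
    extra: dict = field(default_factory=dict)

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.estimate - 1.96 * self.se, self.estimate + 1.96 * self.se)

    @property
    def p(self) -> float:
        if self.se == 0:
            return 0.0 if self.estimate != 0 else 1.0
        return float(2.0 * stats.norm.sf(abs(self.estimate / self.se)))

    def as_dict(self) -> dict:
        lo, hi = self.ci95
        return {
            "method": self.method, "outcome": self.outcome, "estimate": self.estimate,
            "se": self.se, "ci_lo": lo, "ci_hi": hi, "p": self.p, "n_used": self.n_used,
        }


# ---------------------------------------------------------------------------
# regressions

def _outcome_series(df: pd.DataFrame, outcome) -> tuple[pd.Series, str]:
    if isinstance(outcome, (tuple, list)):
        base, follow = outcome
        return df[base] - df[follow], f"{base}-{follow}"
    return df[outcome], str(outcome)


def fit_logistic(data: Cohort | pd.DataFrame, outcome: str, predictors: list[str]) -> RegressionFit:
    """Newton–Raphson multivariate logistic regression.

    SEs come from the inverse observed information; p-values are Wald.
    A constant outcome is rejected; perfect separation raises
    :class:`SeparationError`; non-convergence within 100 iterations returns
    ``converged=False``.
    """
    df = _as_df(data)
    y = df[outcome].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is constant")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError(f"outcome {outcome!r} is not binary")
    X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in predictors])
    res = fit_logit(X, y, names=["const"] + list(predictors))
    return RegressionFit(
        kind="logistic", names=res.names, coefficients=res.coef, se=res.se,
        p_values=res.p, ci95=res.ci95(), n=len(df), converged=res.converged,
    )


def fit_ols(data: Cohort | pd.DataFrame, outcome, predictors: list[str]) -> RegressionFit:
    """Ordinary least squares with classical (homoskedastic) SEs and the
    overall model-fit statistics (R², adjusted R², F)."""
    df = _as_df(data)
    y, yname = _outcome_series(df, outcome)
    y = y.to_numpy(dtype=float)
    n = len(y)
    p = len(predictors)
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    X = np.column_stack([np.ones(n)] + [df[c].to_numpy(dtype=float) for c in predictors])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - p - 1
    sigma2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(XtX_inv) * sigma2, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    sst = float(((y - y.mean()) ** 2).sum())
    ssr = float(resid @ resid)
    r2 = 1.0 - ssr / sst if sst > 0 else float("nan")
    fit = RegressionFit(
        kind="linear", names=["const"] + list(predictors), coefficients=beta, se=se,
        p_values=pvals, ci95=np.column_stack([beta - 1.96 * se, beta + 1.96 * se]),
        n=n, r2=r2, sigma2=sigma2,
    )
    fit.adj_r2, fit.f_stat, fit.f_p = fit_stats(fit)
    return fit


def fit_stats(fit: RegressionFit) -> tuple[float, float, float]:
    """Adjusted R², overall F statistic, and its p-value for a linear fit.

    adj R² = 1 − (1 − R²)(n − 1)/(n − p − 1); F has (p, n − p − 1) df.
    """
    if fit.kind != "linear":
        raise ValueError("fit_stats requires a linear fit")
    p = len(fit.names) - 1
    n = fit.n
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    r2 = fit.r2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    if r2 >= 1.0:
        return 1.0, float("inf"), 0.0
    f = (r2 / p) / ((1.0 - r2) / (n - p - 1)) if p > 0 else float("nan")
    fp = float(stats.f.sf(f, p, n - p - 1)) if p > 0 else float("nan")
    return adj, f, fp


# ---------------------------------------------------------------------------
# VIF

def _r2_general(y: np.ndarray, X: np.ndarray, centered: bool) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ssr = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum()) if centered else float(y @ y)
    if sst <= 0:
        return 0.0
    return 1.0 - ssr / sst


def compute_vif(data: Cohort | pd.DataFrame, variables: list[str]) -> VIFTable:
    """VIF_j = 1/(1 − R²_j), regressing each variable on all others plus a
    constant.  The constant term's own VIF (regression of the constant column
    on the variables, uncentered R²) is reported in a separate ``const`` row.
    Exact collinearity is flagged as ``inf`` rather than raised.
    """
    df = _as_df(data)
    if len(variables) < 2:
        raise ValueError("need at least 2 variables")
    cols = [df[v].to_numpy(dtype=float) for v in variables]
    design = np.column_stack([np.ones(len(df))] + cols)
    names = ["const"] + list(variables)
    vifs = {}
    for j, name in enumerate(names):
        y = design[:, j]
        X = np.delete(design, j, axis=1)
        # centered R² when the remaining design still contains the constant
        centered = j != 0
        r2 = _r2_general(y, X, centered=centered)
        vifs[name] = float("inf") if 1.0 - r2 < 1e-10 else 1.0 / (1.0 - r2)
    table = pd.DataFrame({"vif": pd.Series(vifs)}).reindex(names)
    return VIFTable(table=table)


# ---------------------------------------------------------------------------
# IPTW

def iptw_effect(
    data: Cohort | pd.DataFrame,
    scores,
    outcome,
    arm: str = ARM_COLUMN,
    truncate: bool = False,
) -> EffectReport:
    """Inverse-probability-of-treatment-weighted arm contrast.

    Weights are 1/e for treated and 1/(1−e) for controls; the estimate is the
    difference of weighted outcome means and the SE is the robust weighted
    large-sample formula.  Scores exactly 0 or 1 are an error unless
    ``truncate`` clips them to [0.01, 0.99].
    """
    df = _as_df(data)
    from .matching import PropensityModel  # local import to avoid cycle

    if isinstance(scores, PropensityModel):
        e = scores.scores.to_numpy(dtype=float)
    else:
        e = np.asarray(scores, dtype=float)
    if truncate:
        e = np.clip(e, 0.01, 0.99)
    if np.any((e <= 0.0) | (e >= 1.0)):
        raise ValueError("propensity scores at 0 or 1; pass truncate=True to clip to [0.01, 0.99]")
    y, yname = _outcome_series(df, outcome)
    y = y.to_numpy(dtype=float)
    t = df[arm].to_numpy(dtype=int)
    w = np.where(t == 1, 1.0 / e, 1.0 / (1.0 - e))
    wt, wc = w[t == 1], w[t == 0]
    yt, yc = y[t == 1], y[t == 0]
    mu_t = float(np.sum(wt * yt) / np.sum(wt))
    mu_c = float(np.sum(wc * yc) / np.sum(wc))
    var_t = float(np.sum(wt**2 * (yt - mu_t) ** 2) / np.sum(wt) ** 2)
    var_c = float(np.sum(wc**2 * (yc - mu_c) ** 2) / np.sum(wc) ** 2)
    return EffectReport(
        method="iptw", estimate=mu_t - mu_c, se=float(np.sqrt(var_t + var_c)),
        outcome=yname, n_used=len(y),
        extra={"sum_w_treated": float(np.sum(wt)), "sum_w_control": float(np.sum(wc))},
    )


# ---------------------------------------------------------------------------
# IV / 2SLS

def iv_2sls(
    data: Cohort | pd.DataFrame,
    outcome,
    treatment: str,
    instrument: str,
) -> EffectReport:
    """Two-stage least squares with a single instrument.

    Stage 1 regresses treatment on the instrument; stage 2 regresses the
    outcome on the predicted treatment.  SEs use the standard 2SLS residual
    (outcome minus *actual*-treatment fit at the 2SLS coefficients).  A
    first-stage F below 10 triggers a weak-instrument warning.
    """
    df = _as_df(data)
    y, yname = _outcome_series(df, outcome)
    y = y.to_numpy(dtype=float)
    t = df[treatment].to_numpy(dtype=float)
    z = df[instrument].to_numpy(dtype=float)
    n = len(y)
    Z = np.column_stack([np.ones(n), z])
    gamma, *_ = np.linalg.lstsq(Z, t, rcond=None)
    t_hat = Z @ gamma
    if np.var(t_hat) < 1e-14:
        raise ValueError("weak/degenerate instrument: first-stage predictions are constant")
    # first-stage F for the single instrument = t² of its slope
    resid1 = t - t_hat
    s2_1 = float(resid1 @ resid1) / (n - 2)
    se_g = np.sqrt(s2_1 * np.linalg.pinv(Z.T @ Z)[1, 1])
    f_first = float((gamma[1] / se_g) ** 2) if se_g > 0 else float("inf")
    if f_first < 10:
        warnings.warn(f"weak instrument: first-stage F = {f_first:.2f} < 10", stacklevel=2)
    Xh = np.column_stack([np.ones(n), t_hat])
    beta, *_ = np.linalg.lstsq(Xh, y, rcond=None)
    # proper 2SLS residual uses the observed treatment
    resid2 = y - (beta[0] + beta[1] * t)
    s2 = float(resid2 @ resid2) / (n - 2)
    cov = s2 * np.linalg.pinv(Xh.T @ Xh)
    return EffectReport(
        method="iv", estimate=float(beta[1]), se=float(np.sqrt(cov[1, 1])),
        outcome=yname, n_used=n,
        extra={"intercept": float(beta[0]), "first_stage_f": f_first},
    )


# ---------------------------------------------------------------------------
# DiD

def did_effect(
    data: Cohort | pd.DataFrame,
    pre: str,
    post: str,
    arm: str = ARM_COLUMN,
) -> EffectReport:
    """Difference-in-differences on a two-period panel.

    estimate = (mean post − mean pre | treated) − (mean post − mean pre | control).
    The same quantity is recomputed as the interaction coefficient of the
    two-way (arm × period) regression on the stacked panel, and the two forms
    are asserted to agree to 1e-10; the regression supplies the SE.
    """
    df = _as_df(data)
    for col, label in ((pre, "pre"), (post, "post")):
        if col not in df.columns:
            raise ValueError(f"{label} column {col!r} missing")
    t = df[arm].to_numpy(dtype=int)
    if t.sum() == 0 or t.sum() == len(t):
        raise ValueError("an arm is missing from the panel")
    y_pre = df[pre].to_numpy(dtype=float)
    y_post = df[post].to_numpy(dtype=float)
    four_mean = (y_post[t == 1].mean() - y_pre[t == 1].mean()) - (
        y_post[t == 0].mean() - y_pre[t == 0].mean()
    )
    # stacked two-way regression
    n = len(t)
    y = np.concatenate([y_pre, y_post])
    treat = np.concatenate([t, t]).astype(float)
    period = np.concatenate([np.zeros(n), np.ones(n)])
    X = np.column_stack([np.ones(2 * n), treat, period, treat * period])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    est_reg = float(beta[3])
    if not np.isclose(est_reg, four_mean, rtol=1e-10, atol=1e-10 * max(1.0, abs(four_mean))):
        raise AssertionError(
            f"DiD forms disagree: arithmetic {four_mean!r} vs regression {est_reg!r}"
        )
    resid = y - X @ beta
    s2 = float(resid @ resid) / (2 * n - 4)
    cov = s2 * np.linalg.pinv(X.T @ X)
    return EffectReport(
        method="did", estimate=float(four_mean), se=float(np.sqrt(cov[3, 3])),
        outcome=f"{post}-{pre}", n_used=n,
    )


def naive_effect(data: Cohort | pd.DataFrame, outcome, arm: str = ARM_COLUMN) -> EffectReport:
    """Unadjusted arm difference in means (the biased reference point)."""
    df = _as_df(data)
    y, yname = _outcome_series(df, outcome)
    y = y.to_numpy(dtype=float)
    t = df[arm].to_numpy(dtype=int)
    yt, yc = y[t == 1], y[t == 0]
    se = float(np.sqrt(yt.var(ddof=1) / len(yt) + yc.var(ddof=1) / len(yc)))
    return EffectReport(
        method="naive", estimate=float(yt.mean() - yc.mean()), se=se,
        outcome=yname, n_used=len(y),
    )
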