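"""Propensity-score estimation, caliper matching, balance diagnostics, and the
covariate-set sensitivity resampler.

The matching design is one-to-one nearest-neighbor without replacement inside
a caliper of 0.2 standard deviations of the propensity-score logit, the
standard recommendation for observational treatment comparisons.  Treated
subjects are processed in a deterministic order (descending logit, row-id
tie-break) so that matched samples are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._glm import SeparationError, fit_logit
from .simulate import ARM_COLUMN, Cohort

__all__ = [
    "PropensityModel",
    "MatchResult",
    "BalanceReport",
    "SensitivityDistribution",
    "fit_propensity",
    "match_caliper",
    "smd",
    "balance_report",
    "covariate_set_sensitivity",
    "matched_difference",
    "SeparationError",
]


def _as_df(data: Cohort | pd.DataFrame) -> pd.DataFrame:
    return data.df if isinstance(data, Cohort) else data


@dataclass
class PropensityModel:
    covariates: list[str]
    dropped: list[str]
    coefficients: pd.Series           # includes "const"
    logits: pd.Series                 # indexed by cohort row id
    arm: pd.Series

    @property
    def scores(self) -> pd.Series:
        return pd.Series(1.0 / (1.0 + np.exp(-self.logits)), index=self.logits.index)


@dataclass
class MatchResult:
    pairs: list[tuple[int, int]]      # (treated id, control id)
    caliper_width: float
    unmatched_treated: int
    unmatched_control: int

    @property
    def treated_ids(self) -> list[int]:
        return [t for t, _ in self.pairs]

    @property
    def control_ids(self) -> list[int]:
        return [c for _, c in self.pairs]

    @property
    def matched_ids(self) -> list[int]:
        return self.treated_ids + self.control_ids

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["treated_id", "control_id"])


@dataclass
class BalanceReport:
    table: pd.DataFrame               # index covariate; columns smd_before, smd_after
    threshold: float = 0.1

    @property
    def balanced(self) -> bool:
        after = self.table["smd_after"].dropna()
        return bool((after < self.threshold).all())


@dataclass
class SensitivityDistribution:
    effects: list[float]
    n_sets: int
    set_size: int
    seed: int
    n_failed: int = 0
    covariate_sets: list[tuple[str, ...]] = field(default_factory=list)

    @property
    def valid_effects(self) -> np.ndarray:
        arr = np.asarray(self.effects, dtype=float)
        return arr[~np.isnan(arr)]

    @property
    def mean(self) -> float:
        v = self.valid_effects
        return float(np.mean(v)) if v.size else float("nan")

    @property
    def sd(self) -> float:
        v = self.valid_effects
        return float(np.std(v, ddof=1)) if v.size > 1 else float("nan")


def fit_propensity(
    data: Cohort | pd.DataFrame,
    covariates: Sequence[str],
    arm: str = ARM_COLUMN,
) -> PropensityModel:
    """Logistic regression of treatment arm on the covariates.

    Zero-variance covariates are dropped with a warning (their coefficient is
    not identified); perfect separation raises :class:`SeparationError`.
    """
    df = _as_df(data)
    if arm not in df.columns:
        raise ValueError(f"arm column {arm!r} not in data")
    kept, dropped = [], []
    for c in covariates:
        if c not in df.columns:
            raise ValueError(f"unknown covariate {c!r}")
        (kept if df[c].nunique() > 1 else dropped).append(c)
    if dropped:
        warnings.warn(f"dropping zero-variance covariates: {dropped}", stacklevel=2)
    X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in kept])
    y = df[arm].to_numpy(dtype=float)
    res = fit_logit(X, y, names=["const"] + kept)
    logits = pd.Series(X @ res.coef, index=df.index)
    return PropensityModel(
        covariates=kept,
        dropped=dropped,
        coefficients=pd.Series(res.coef, index=res.names),
        logits=logits,
        arm=df[arm],
    )


def match_caliper(pm: PropensityModel, caliper_sd: float = 0.2) -> MatchResult:
    """Greedy one-to-one nearest-neighbor matching on the logit of the PS.

    Caliper width = ``caliper_sd`` × SD of all logits.  Treated subjects are
    visited in descending-logit order (id tie-break); each consumes its
    nearest in-caliper control, without replacement.
    """
    if caliper_sd <= 0:
        raise ValueError("caliper_sd must be positive")
    logits = pm.logits
    sd = float(np.std(logits.to_numpy(), ddof=1)) if len(logits) > 1 else 0.0
    width = caliper_sd * sd
    treated = logits[pm.arm == 1]
    controls = logits[pm.arm == 0]
    n_treat = len(treated)
    if controls.empty:
        return MatchResult(pairs=[], caliper_width=width,
                           unmatched_treated=n_treat, unmatched_control=0)
    order = sorted(treated.items(), key=lambda kv: (-kv[1], kv[0]))
    # controls sorted by id: argmin picks the smallest id among exact ties
    ctrl = controls.sort_index()
    cids = ctrl.index.to_numpy()
    clog = ctrl.to_numpy(dtype=float)
    alive = np.ones(len(cids), dtype=bool)
    pairs: list[tuple[int, int]] = []
    for tid, tl in order:
        if not alive.any():
            break
        d = np.abs(clog - tl)
        d[~alive] = np.inf
        j = int(np.argmin(d))
        if d[j] <= width + 1e-12:
            pairs.append((tid, int(cids[j])))
            alive[j] = False
    return MatchResult(
        pairs=pairs,
        caliper_width=width,
        unmatched_treated=n_treat - len(pairs),
        unmatched_control=len(controls) - len(pairs),
    )


def _arm_moments(x: pd.Series, binary: bool) -> tuple[float, float]:
    m = float(x.mean())
    if binary:
        return m, m * (1.0 - m)
    v = float(x.var(ddof=1)) if len(x) > 1 else 0.0
    return m, v


def _smd_one(df: pd.DataFrame, covariate: str, arm: str) -> float:
    x = df[covariate].astype(float)
    binary = set(x.dropna().unique()) <= {0.0, 1.0}
    xt, xc = x[df[arm] == 1], x[df[arm] == 0]
    mt, vt = _arm_moments(xt, binary)
    mc, vc = _arm_moments(xc, binary)
    pooled = (vt + vc) / 2.0
    if pooled <= 0:
        return 0.0 if np.isclose(mt, mc) else float("inf")
    return abs(mt - mc) / np.sqrt(pooled)


def smd(
    data: Cohort | pd.DataFrame,
    pairs: MatchResult | Sequence[tuple[int, int]] | None,
    covariate: str,
    arm: str = ARM_COLUMN,
) -> tuple[float, float]:
    """Standardized mean difference before and after matching.

    |mean_t − mean_c| / sqrt((var_t + var_c)/2), with p(1−p) variances for
    binary covariates.  ``smd_after`` is computed on the matched subsample;
    with no pairs it is NaN.  Zero pooled variance yields 0 when the means
    agree and +inf otherwise.
    """
    df = _as_df(data)
    if covariate not in df.columns:
        raise ValueError(f"unknown covariate {covariate!r}")
    before = _smd_one(df, covariate, arm)
    ids: list[int] = []
    if isinstance(pairs, MatchResult):
        ids = pairs.matched_ids
    elif pairs:
        ids = [t for t, _ in pairs] + [c for _, c in pairs]
    after = _smd_one(df.loc[ids], covariate, arm) if ids else float("nan")
    return before, after


def balance_report(
    data: Cohort | pd.DataFrame,
    pairs: MatchResult | None,
    covariates: Sequence[str],
    arm: str = ARM_COLUMN,
    threshold: float = 0.1,
) -> BalanceReport:
    rows = {c: smd(data, pairs, c, arm) for c in covariates}
    table = pd.DataFrame(rows, index=["smd_before", "smd_after"]).T
    return BalanceReport(table=table, threshold=threshold)


def _outcome_series(df: pd.DataFrame, outcome) -> pd.Series:
    if isinstance(outcome, (tuple, list)):
        base, follow = outcome
        return df[base] - df[follow]
    return df[outcome]


def matched_difference(
    data: Cohort | pd.DataFrame,
    match: MatchResult,
    outcome,
    arm: str = ARM_COLUMN,
) -> float:
    """Mean(outcome | matched treated) − mean(outcome | matched controls).

    ``outcome`` is a column code, or a (baseline, follow-up) pair meaning the
    improvement baseline − follow-up.
    """
    df = _as_df(data)
    y = _outcome_series(df, outcome)
    if not match.pairs:
        return float("nan")
    return float(y.loc[match.treated_ids].mean() - y.loc[match.control_ids].mean())


def covariate_set_sensitivity(
    data: Cohort | pd.DataFrame,
    pool: Sequence[str],
    n_sets: int = 50,
    set_size: int = 4,
    outcome=("i", "m"),
    seed: int = 0,
    caliper_sd: float = 0.2,
    arm: str = ARM_COLUMN,
) -> SensitivityDistribution:
    """Distribution of matched treatment-effect estimates over random
    covariate sets.

    For each of ``n_sets`` draws, ``set_size`` covariates are sampled from
    ``pool`` without replacement (sets may repeat across draws), the PS model
    is refit, caliper matching is rerun, and the matched outcome difference
    is recorded.  Sets yielding zero matches (or a separated PS fit) are
    recorded as NaN and excluded from the summary mean/SD.  The default
    outcome is the one-year ICIQ-SF improvement (baseline ``i`` minus
    follow-up ``m``).
    """
    df = _as_df(data)
    pool = list(pool)
    if set_size > len(pool):
        raise ValueError("set_size exceeds pool size")
    rng = np.random.default_rng(seed)
    effects: list[float] = []
    sets: list[tuple[str, ...]] = []
    n_failed = 0
    for _ in range(n_sets):
        chosen = tuple(sorted(rng.choice(pool, size=set_size, replace=False).tolist()))
        sets.append(chosen)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pm = fit_propensity(df, list(chosen), arm=arm)
            match = match_caliper(pm, caliper_sd=caliper_sd)
        except SeparationError:
            match = None
        if match is None or not match.pairs:
            warnings.warn(f"covariate set {chosen} produced no matches; excluded", stacklevel=2)
            effects.append(float("nan"))
            n_failed += 1
            continue
        effects.append(matched_difference(df, match, outcome, arm=arm))
    return SensitivityDistribution(
        effects=effects, n_sets=n_sets, set_size=set_size, seed=seed,
        n_failed=n_failed, covariate_sets=sets,
    )
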