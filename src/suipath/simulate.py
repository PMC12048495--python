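"""Synthetic cohort generation.

Two generators live here:

``generate_cohort``
    A Gaussian-copula emulator of the matched two-arm study table: each arm's
    continuous variables reproduce the catalog's per-arm mean/SD, binary
    variables are produced by thresholding the latent normal at the arm
    prevalence, and the one-year outcomes are driven by explicit logistic
    (binary) and linear (continuous-improvement) structural models with a
    configurable treatment effect.  This is the substrate for the matching,
    network and pathway stages.

``generate_causal_benchmark``
    A small structural model with a genuine treatment-assignment mechanism
    (logistic selection on observed confounders, optional unobserved
    confounding, and a randomized-encouragement instrument).  It exists so
    that IPTW, IV/2SLS and DiD can be validated against a known average
    treatment effect — the copula emulator has no assignment mechanism and
    therefore no instrument.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

from .catalog import ALIASES, VariableCatalog, default_catalog

__all__ = [
    "CohortSpec",
    "Cohort",
    "default_corr_pairs",
    "default_cohort_spec",
    "null_cohort_spec",
    "generate_cohort",
    "generate_causal_benchmark",
    "improvement",
]

ARM_COLUMN = "aq"
INDEX_COLUMN = "a"
#: Columns computed from other columns rather than drawn from the copula.
DERIVED_COLUMNS = ("m", "n", "ar", "au", "bg", "bh")
#: Binary outcomes driven by structural logistic models.
LOGISTIC_OUTCOMES = ("bi", "bj")


def default_corr_pairs() -> dict[tuple[str, str], float]:
    """Default latent correlation targets.

    Signs and the printed magnitudes follow the reported pairwise
    associations (testosterone positively, T-cho negatively associated with
    return to sport; pelvic-floor contractility strongly tied to pad-test
    severity); the milestone chain ap → av is given a strong positive link so
    the assessment timeline is connected in the variable network.  All other
    off-diagonals are zero and the matrix is PSD-repaired by eigenvalue
    clipping.
    """
    return {
        ("ap", "av"): 0.75,
        ("ap", "ao"): 0.65,
        ("ap", "i"): 0.55,
        ("ap", "b"): 0.45,
        ("av", "ao"): 0.45,
        ("av", "i"): 0.40,
        ("av", "as"): 0.50,
        ("av", "at"): 0.50,
        ("av", "aw"): 0.40,
        ("ai", "ak"): -0.35,
        ("ai", "aa"): 0.30,
        ("ai", "ag"): -0.30,
        ("z", "ao"): 0.50,
        ("z", "b"): -0.30,
        ("z", "al"): 0.30,
        ("al", "b"): 0.40,
        ("b", "af"): 0.45,
        ("af", "av"): 0.25,
        ("an", "ah"): 0.35,
        ("an", "aw"): 0.60,
        ("an", "bd"): 0.55,
        ("aw", "bd"): 0.50,
        ("ah", "az"): 0.50,
        ("ah", "bc"): 0.50,
        ("az", "bc"): 0.50,
        ("i", "ao"): 0.50,
        ("d", "g"): 0.50,
        ("d", "r"): 0.20,
        ("f", "g"): 0.30,
        ("f", "an"): 0.25,
        ("l", "u"): 0.30,
    }


def _default_outcome_coefs() -> dict:
    # Logistic coefficients are on the log-odds scale applied to standardized
    # continuous columns (raw 0/1 for binaries); linear-improvement models are
    # in the outcome's own units.  Intercepts anchor the control-arm level.
    return {
        "bi": {"intercept": -0.9, "coefs": {"av": 0.8, "ai": 0.5, "b": -0.6, "an": 0.5}},
        "bj": {"intercept": -0.8, "coefs": {"bi": 1.5, "aq": 0.7, "ai": 0.6, "an": 0.6, "ak": -0.4, "l": 0.4}},
        "dpad": {"intercept": 32.78, "coefs": {"z": -4.0, "b": -3.0, "an": 3.0}, "sd": 12.0},
        "diciq": {"intercept": 1.66, "coefs": {"an": 1.0, "ai": 0.8}, "sd": 3.5},
    }


@dataclass
class CohortSpec:
    """Parameters of one simulated cohort.

    ``target_corr`` maps unordered code pairs to latent correlations;
    ``outcome_coefs`` holds the four structural outcome models (``bi``/``bj``
    logistic, ``dpad``/``diciq`` linear improvements).  ``treatment_effect_pad``
    is the injected pad-test improvement attributable to treatment (grams),
    ``treatment_effect_iciq`` the ICIQ-SF analogue, and
    ``treatment_effect_logodds`` the log-odds shift for the binary one-year
    outcomes.
    """

    n_treat: int = 41
    n_ctrl: int = 41
    target_corr: dict = field(default_factory=default_corr_pairs)
    outcome_coefs: dict = field(default_factory=_default_outcome_coefs)
    treatment_effect_pad: float = 42.154
    treatment_effect_iciq: float = 10.78
    treatment_effect_logodds: float = 3.2
    seed: int = 0
    repair_corr: bool = True

    def to_json(self) -> str:
        payload = {
            "n_treat": self.n_treat,
            "n_ctrl": self.n_ctrl,
            "target_corr": {f"{a}|{b}": v for (a, b), v in sorted(self.target_corr.items())},
            "outcome_coefs": self.outcome_coefs,
            "treatment_effect_pad": self.treatment_effect_pad,
            "treatment_effect_iciq": self.treatment_effect_iciq,
            "treatment_effect_logodds": self.treatment_effect_logodds,
            "seed": self.seed,
            "repair_corr": self.repair_corr,
        }
        return json.dumps(payload, sort_keys=True)

    def spec_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def default_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """Spec matching the study conditions (41 + 41 matched arms)."""
    return CohortSpec(seed=seed, **overrides)


def null_cohort_spec(n_per_arm: int = 1000, seed: int = 0) -> CohortSpec:
    """Zero treatment effect, zero outcome-confounding: every structural
    coefficient is zeroed while the covariate copula keeps its defaults."""
    coefs = _default_outcome_coefs()
    for model in coefs.values():
        model["coefs"] = {}
    return CohortSpec(
        n_treat=n_per_arm,
        n_ctrl=n_per_arm,
        outcome_coefs=coefs,
        treatment_effect_pad=0.0,
        treatment_effect_iciq=0.0,
        treatment_effect_logodds=0.0,
        seed=seed,
    )


@dataclass
class Cohort:
    """A patient-by-variable table plus simulation provenance.

    ``df`` has one row per patient and one column per catalog code;
    ``constant_columns`` flags zero-variance columns (they are legitimate —
    the study table itself contains rows whose p-value "could not be
    calculated due to the absence of variability").
    """

    df: pd.DataFrame
    catalog: VariableCatalog
    seed: int | None = None
    spec_hash: str | None = None
    potential: dict = field(default_factory=dict)

    @property
    def constant_columns(self) -> list[str]:
        return [c for c in self.df.columns if self.df[c].nunique(dropna=True) <= 1]

    @property
    def arm(self) -> pd.Series:
        return self.df[ARM_COLUMN]

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        path = Path(path)
        self.df.to_csv(path, index=False)
        if sidecar and self.seed is not None:
            meta = {"seed": self.seed, "spec_hash": self.spec_hash}
            path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path, catalog: VariableCatalog | None = None) -> "Cohort":
        catalog = catalog or default_catalog()
        df = pd.read_csv(path, float_precision="round_trip")
        unknown = [c for c in df.columns if c not in catalog]
        if unknown:
            raise ValueError(f"columns outside the catalog: {unknown}")
        return cls(df=df, catalog=catalog)


def _corr_matrix(codes: Sequence[str], pairs: Mapping[tuple[str, str], float], repair: bool) -> np.ndarray:
    idx = {c: i for i, c in enumerate(codes)}
    R = np.eye(len(codes))
    for (a, b), r in pairs.items():
        if a not in idx or b not in idx:
            continue  # pair refers to a derived/alias code; latent corr not applicable
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"target correlation ({a},{b})={r} outside [-1, 1]")
        R[idx[a], idx[b]] = R[idx[b], idx[a]] = r
    w, V = np.linalg.eigh(R)
    if w.min() < -1e-10:
        if not repair:
            raise ValueError(
                f"target_corr is not positive semi-definite (min eigenvalue {w.min():.3g}); "
                "set repair_corr=True to clip"
            )
        w = np.clip(w, 1e-6, None)
        R = V @ np.diag(w) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    return R


def _standardized(col: pd.Series, is_binary: bool) -> np.ndarray:
    x = col.to_numpy(dtype=float)
    if is_binary:
        return x
    sd = x.std()
    return np.zeros_like(x) if sd == 0 else (x - x.mean()) / sd


def _linear_predictor(df: pd.DataFrame, catalog: VariableCatalog, coefs: Mapping[str, float]) -> np.ndarray:
    eta = np.zeros(len(df))
    for code, beta in coefs.items():
        entry = catalog[code]
        eta += beta * _standardized(df[code], entry.is_binary)
    return eta


def _validate_outcome_codes(spec: CohortSpec, catalog: VariableCatalog) -> None:
    for model_name, model in spec.outcome_coefs.items():
        if model_name not in ("bi", "bj", "dpad", "diciq"):
            raise ValueError(f"unknown outcome model {model_name!r}")
        for code in model.get("coefs", {}):
            if code not in catalog:
                raise ValueError(f"outcome_coefs[{model_name!r}] references unknown code {code!r}")
        if model.get("sd", 0.0) < 0:
            raise ValueError(f"outcome_coefs[{model_name!r}]: negative noise SD")


def generate_cohort(spec: CohortSpec, catalog: VariableCatalog | None = None) -> Cohort:
    """Draw one cohort table from the Gaussian-copula emulator.

    The latent draw order, and therefore the output, is fully determined by
    ``spec.seed``: identical (spec, catalog, seed) give a byte-identical CSV.
    Potential outcomes under both arms (for the structural outcome models)
    are kept in ``Cohort.potential`` so the injected effect can be audited
    against a brute-force potential-outcomes average.
    """
    catalog = catalog or default_catalog()
    _validate_outcome_codes(spec, catalog)

    rng = np.random.default_rng(spec.seed)
    n = spec.n_treat + spec.n_ctrl
    arm = np.concatenate([np.ones(spec.n_treat, dtype=int), np.zeros(spec.n_ctrl, dtype=int)])

    special = set(DERIVED_COLUMNS) | set(LOGISTIC_OUTCOMES) | set(ALIASES) | {ARM_COLUMN, INDEX_COLUMN}
    base_codes = [c for c in catalog.codes if c not in special]

    R = _corr_matrix(base_codes, spec.target_corr, spec.repair_corr)
    L = np.linalg.cholesky(R + 1e-12 * np.eye(len(base_codes)))
    Z = rng.standard_normal((n, len(base_codes))) @ L.T

    df = pd.DataFrame(index=range(n))
    df[INDEX_COLUMN] = np.arange(1, n + 1)
    df[ARM_COLUMN] = arm
    for jcol, code in enumerate(base_codes):
        e = catalog[code]
        z = Z[:, jcol]
        mean = np.where(arm == 1, e.mean_treat, e.mean_ctrl)
        if e.is_binary:
            prev = mean
            df[code] = (z < ndtri(np.clip(prev, 1e-12, 1 - 1e-12))).astype(int)
            df.loc[prev <= 0.0, code] = 0
            df.loc[prev >= 1.0, code] = 1
        else:
            sd = np.where(arm == 1, e.sd_treat, e.sd_ctrl)
            df[code] = mean + sd * z

    potential: dict[str, np.ndarray] = {}

    # Binary one-year outcomes: shared uniforms give exact potential outcomes
    # under treated/control assignment.  The dryness outcome bi carries the
    # configurable log-odds treatment effect; the return outcome bj depends
    # on treatment through bi plus any explicit "aq" coefficient.  The
    # treatment column is excluded from the control-arm linear predictor so
    # the stored potential outcomes are genuine.
    for code in LOGISTIC_OUTCOMES:
        model = spec.outcome_coefs.get(code, {"intercept": 0.0, "coefs": {}})
        coefs = dict(model.get("coefs", {}))
        delta = coefs.pop(ARM_COLUMN, 0.0)
        if code == "bi":
            delta += spec.treatment_effect_logodds
        eta0 = model.get("intercept", 0.0) + _linear_predictor(df, catalog, coefs)
        u = rng.uniform(size=n)
        p0, p1 = expit(eta0), expit(eta0 + delta)
        y0, y1 = (u < p0).astype(int), (u < p1).astype(int)
        df[code] = np.where(arm == 1, y1, y0)
        potential[code] = np.column_stack([p0, p1, y0, y1])

    # Continuous improvements (baseline minus follow-up) with additive effects.
    for name, eff in (("dpad", spec.treatment_effect_pad), ("diciq", spec.treatment_effect_iciq)):
        model = spec.outcome_coefs.get(name, {"intercept": 0.0, "coefs": {}, "sd": 0.0})
        coefs = dict(model.get("coefs", {}))
        eff = eff + coefs.pop(ARM_COLUMN, 0.0)
        base = model.get("intercept", 0.0) + _linear_predictor(df, catalog, coefs)
        noise = rng.normal(scale=model.get("sd", 0.0), size=n) if model.get("sd", 0.0) > 0 else np.zeros(n)
        d0 = base + noise
        d1 = d0 + eff
        potential[name] = np.column_stack([d0, d1])
        potential[name + "_obs"] = np.where(arm == 1, d1, d0)

    dpad = potential["dpad_obs"]
    diciq = potential["diciq_obs"]
    df["n"] = df["ao"] - dpad
    df["m"] = df["i"] - diciq
    df["ar"] = df["ao"] - 0.6 * dpad
    df["au"] = df["i"] - 0.6 * diciq
    df["bh"] = (dpad > 0).astype(int)
    df["bg"] = (diciq > 0).astype(int)

    for alias, canonical in ALIASES.items():
        df[alias] = df[canonical]

    df = df[catalog.codes]
    return Cohort(df=df, catalog=catalog, seed=spec.seed, spec_hash=spec.spec_hash(), potential=potential)


def improvement(cohort: Cohort | pd.DataFrame, baseline: str = "i", followup: str = "m") -> pd.Series:
    """Improvement score = baseline minus follow-up (positive = better)."""
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    return df[baseline] - df[followup]


def generate_causal_benchmark(
    n: int = 10_000,
    effect: float = 42.154,
    seed: int = 0,
    confounding: float = 0.8,
    unobserved: float = 0.0,
    instrument_strength: float = 1.5,
    trend_confounding: float = 6.0,
    treated_fraction: float = 0.5,
) -> pd.DataFrame:
    """Structural benchmark with a known average treatment effect.

    Columns: observed confounders ``x1, x2``; randomized-encouragement
    instrument ``z`` (Bernoulli 0.5, independent of everything unobserved);
    treatment ``treat`` assigned by a logistic model in (x1, x2, u, z);
    ``pre``/``post`` pad-test panel (``pre − post == y``); ``y`` the
    improvement carrying the constant additive ``effect``, so the true ATE
    equals ``effect`` regardless of confounding.

    Each estimator is validated under its own identifying assumption:
    ``confounding`` moves both treatment odds and the improvement (IPTW /
    matching territory); ``unobserved`` adds an endogeneity component only
    the instrument can remove (IV territory); ``trend_confounding`` controls
    whether confounders shift the *change* as well as the baseline level —
    set it to 0 for a parallel-trends world where DiD is unbiased while the
    naive post-score contrast is not.
    """
    rng = np.random.default_rng(seed)
    x1 = rng.standard_normal(n)
    x2 = rng.standard_normal(n)
    u = rng.standard_normal(n)
    z = rng.integers(0, 2, size=n)
    intercept = float(np.log(treated_fraction / (1.0 - treated_fraction)))
    eta = intercept + confounding * (x1 + x2) + unobserved * u + instrument_strength * (z - 0.5)
    treat = (rng.uniform(size=n) < expit(eta)).astype(int)
    pre = 70.0 + 5.0 * x1 + 5.0 * x2 + rng.normal(scale=8.0, size=n)
    y = (
        30.0
        + trend_confounding * (x1 + x2)
        + 5.0 * unobserved * u
        + effect * treat
        + rng.normal(scale=10.0, size=n)
    )
    post = pre - y
    return pd.DataFrame({"x1": x1, "x2": x2, "z": z, "treat": treat, "pre": pre, "post": post, "y": y})
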