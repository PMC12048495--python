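"""End-to-end orchestration: simulate (or load) → match → estimate →
sensitivity → network → pathways → report bundle.

One global seed is split deterministically into per-stage seeds, so a single
integer reproduces the entire run; all tabular outputs are TSV with headers
and all structured outputs JSON, so runs diff cleanly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import estimators, matching, network, pathways
from .catalog import EXCLUDED_NODES, MILESTONES, default_catalog
from .simulate import Cohort, CohortSpec, generate_cohort

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline"]

log = logging.getLogger("suipath")

#: The four matching covariates: age, bladder neck descent, duration of
#: training, weekly training days.
DEFAULT_MATCH_COVARIATES = ["d", "b", "g", "f"]

#: Baseline covariate pool for the sensitivity resampler.
DEFAULT_SENSITIVITY_POOL = [
    "d", "b", "g", "f", "r", "ai", "an", "ah", "ak", "aa", "ag", "al", "z", "i", "ao",
]

#: Adjustment set for the regression / VIF stage: treatment, testosterone,
#: PFMT frequency, core training, T-cho.
DEFAULT_ADJUSTMENT_SET = ["aq", "ai", "an", "l", "ak"]


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateSettings(_Model):
    n_treat: int = 41
    n_ctrl: int = 41
    treatment_effect_pad: float = 42.154
    treatment_effect_iciq: float = 10.78
    treatment_effect_logodds: float = 3.2


class MatchingSettings(_Model):
    covariates: list[str] = Field(default_factory=lambda: list(DEFAULT_MATCH_COVARIATES))
    caliper_sd: float = 0.2


class SensitivitySettings(_Model):
    enabled: bool = True
    n_sets: int = 50
    set_size: int = 4
    pool: list[str] = Field(default_factory=lambda: list(DEFAULT_SENSITIVITY_POOL))


class EstimatorSettings(_Model):
    adjustment_set: list[str] = Field(default_factory=lambda: list(DEFAULT_ADJUSTMENT_SET))
    binary_outcome: str = "bi"
    pad_pre: str = "ao"
    pad_post: str = "n"
    instrument: Optional[str] = None   # no catalog code is an instrument; opt-in only


class NetworkSettings(_Model):
    enabled: bool = True
    min_abs_r: float = 0.05
    prune: str = "explicit"            # explicit | threshold | none
    distance_cutoff: Optional[float] = None


class PathwaySettings(_Model):
    milestones: list[str] = Field(default_factory=lambda: list(MILESTONES))
    severity_variable: str = "b"       # bladder neck descent
    severity_insert_node: str = "af"
    cure_code: str = "bi"


class PipelineConfig(_Model):
    cohort_csv: Optional[str] = None   # load instead of simulate when set
    simulate: SimulateSettings = Field(default_factory=SimulateSettings)
    matching: MatchingSettings = Field(default_factory=MatchingSettings)
    sensitivity: SensitivitySettings = Field(default_factory=SensitivitySettings)
    estimators: EstimatorSettings = Field(default_factory=EstimatorSettings)
    network: NetworkSettings = Field(default_factory=NetworkSettings)
    pathways: PathwaySettings = Field(default_factory=PathwaySettings)
    outdir: str = "suipath_out"
    seed: int = 0


@dataclass
class ReportBundle:
    outdir: Path
    files: dict[str, Path] = field(default_factory=dict)
    cohort: Cohort | None = None
    balance: matching.BalanceReport | None = None
    match: matching.MatchResult | None = None
    effects: list[estimators.EffectReport] = field(default_factory=list)
    sensitivity: matching.SensitivityDistribution | None = None
    net: network.VarNetwork | None = None
    strata: list[pathways.StratumReport] = field(default_factory=list)
    natural_cure: pathways.NaturalCureEstimate | None = None
    metadata: dict = field(default_factory=dict)

    def check_files(self) -> None:
        missing = [str(p) for p in self.files.values() if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"bundle references missing files: {missing}")


def _stage_seeds(seed: int, k: int = 8) -> list[int]:
    children = np.random.SeedSequence(seed).spawn(k)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute all configured stages in dependency order.

    Any stage failure aborts with the stage name attached; identical
    (config, seed) produce byte-identical TSV outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(outdir=outdir)
    catalog = default_catalog()
    seeds = _stage_seeds(config.seed)

    stage = "simulate"
    try:
        if config.cohort_csv is not None:
            path = Path(config.cohort_csv)
            if not path.exists():
                raise FileNotFoundError(f"cohort file not found: {path}")
            cohort = Cohort.from_csv(path, catalog)
        else:
            spec = CohortSpec(
                n_treat=config.simulate.n_treat,
                n_ctrl=config.simulate.n_ctrl,
                treatment_effect_pad=config.simulate.treatment_effect_pad,
                treatment_effect_iciq=config.simulate.treatment_effect_iciq,
                treatment_effect_logodds=config.simulate.treatment_effect_logodds,
                seed=seeds[0],
            )
            cohort = generate_cohort(spec, catalog)
        bundle.cohort = cohort
        cohort_path = outdir / "cohort.csv"
        cohort.to_csv(cohort_path)
        bundle.files["cohort"] = cohort_path
        log.info("simulate: %d patients, %d constant columns", len(cohort.df), len(cohort.constant_columns))

        stage = "match"
        pm = matching.fit_propensity(cohort, config.matching.covariates)
        match = matching.match_caliper(pm, caliper_sd=config.matching.caliper_sd)
        bundle.match = match
        match.to_frame().to_csv(outdir / "matches.tsv", sep="\t", index=False)
        bundle.files["matches"] = outdir / "matches.tsv"
        balance = matching.balance_report(cohort, match, config.matching.covariates)
        bundle.balance = balance
        balance.table.to_csv(outdir / "balance.tsv", sep="\t")
        bundle.files["balance"] = outdir / "balance.tsv"
        log.info("match: %d pairs (caliper %.4f)", len(match.pairs), match.caliper_width)

        stage = "sensitivity"
        if config.sensitivity.enabled:
            sens = matching.covariate_set_sensitivity(
                cohort,
                pool=config.sensitivity.pool,
                n_sets=config.sensitivity.n_sets,
                set_size=config.sensitivity.set_size,
                seed=seeds[1],
                caliper_sd=config.matching.caliper_sd,
            )
            bundle.sensitivity = sens
            pd.DataFrame({"effect": sens.effects}).to_csv(
                outdir / "sensitivity_effects.tsv", sep="\t", index=False
            )
            bundle.files["sensitivity_effects"] = outdir / "sensitivity_effects.tsv"
            (outdir / "sensitivity.json").write_text(
                json.dumps(
                    {"mean": sens.mean, "sd": sens.sd, "n_sets": sens.n_sets,
                     "set_size": sens.set_size, "n_failed": sens.n_failed, "seed": sens.seed},
                    indent=2,
                )
            )
            bundle.files["sensitivity"] = outdir / "sensitivity.json"

        stage = "estimate"
        es = config.estimators
        effects: list[estimators.EffectReport] = []
        effects.append(estimators.naive_effect(cohort, es.binary_outcome))
        md = matching.matched_difference(cohort, match, es.binary_outcome)
        effects.append(
            estimators.EffectReport(
                method="matched", estimate=md, se=float("nan"),
                outcome=es.binary_outcome, n_used=2 * len(match.pairs),
            )
        )
        reg = estimators.fit_logistic(cohort, es.binary_outcome, es.adjustment_set)
        effects.append(
            estimators.EffectReport(
                method="regression", estimate=reg.coef("aq") if "aq" in reg.names else float("nan"),
                se=reg.se_of("aq") if "aq" in reg.names else float("nan"),
                outcome=es.binary_outcome, n_used=reg.n,
            )
        )
        effects.append(estimators.iptw_effect(cohort, pm, es.binary_outcome, truncate=True))
        effects.append(estimators.did_effect(cohort, pre=es.pad_pre, post=es.pad_post))
        if es.instrument is not None:
            effects.append(
                estimators.iv_2sls(cohort, (es.pad_pre, es.pad_post), "aq", es.instrument)
            )
        bundle.effects = effects
        eff_df = pd.DataFrame([e.as_dict() for e in effects])
        eff_df.to_csv(outdir / "effects.tsv", sep="\t", index=False)
        bundle.files["effects"] = outdir / "effects.tsv"
        vif = estimators.compute_vif(cohort, es.adjustment_set)
        vif.table.to_csv(outdir / "vif.tsv", sep="\t")
        bundle.files["vif"] = outdir / "vif.tsv"

        stage = "network"
        if config.network.enabled:
            corr = network.correlation_matrix(cohort)
            net = network.build_network(
                corr, catalog, vifs=vif, min_abs_r=config.network.min_abs_r,
            )
            if config.network.prune == "explicit":
                net = network.prune_nodes(net, mode="explicit", exclusion_list=list(EXCLUDED_NODES))
            elif config.network.prune == "threshold":
                net = network.prune_nodes(
                    net, mode="threshold", distance_cutoff=config.network.distance_cutoff,
                )
            elif config.network.prune != "none":
                raise ValueError(f"unknown prune mode {config.network.prune!r}")
            bundle.net = net
            pos = network.layout(net, seed=seeds[2])
            pos_df = pd.DataFrame(
                [(k, float(v[0]), float(v[1])) for k, v in sorted(pos.items())],
                columns=["code", "x", "y"],
            )
            pos_df.to_csv(outdir / "layout.tsv", sep="\t", index=False)
            bundle.files["layout"] = outdir / "layout.tsv"
            bundle.files["network_graphml"] = network.export_graphml(net, outdir / "network.graphml")
            bundle.files["network_edges"] = network.export_edge_tsv(net, outdir / "edges.tsv")

        stage = "pathways"
        if config.pathways is not None:
            if bundle.net is None:
                raise RuntimeError("network required: enable the network stage to run pathways")
            pw = config.pathways
            rules = [
                pathways.BranchRule(
                    variable=pw.severity_variable, op="gt_mean", insert_node=pw.severity_insert_node,
                )
            ]
            strata = pathways.assign_paths(
                cohort, bundle.net, milestones=tuple(pw.milestones),
                branch_rules=rules, cure_code=pw.cure_code,
            )
            bundle.strata = strata
            pd.DataFrame(
                [
                    {"path": s.path_label, "n": s.n, "proportion": s.proportion,
                     "cure_rate": s.cure_rate}
                    for s in strata
                ]
            ).to_csv(outdir / "strata.tsv", sep="\t", index=False)
            bundle.files["strata"] = outdir / "strata.tsv"

            df = cohort.df
            severe = df[pw.severity_variable] > df[pw.severity_variable].mean()
            treated = df["aq"] == 1
            control = ~treated
            natural_rate = float(df.loc[control, pw.cure_code].mean())
            n_mild_treated = int((treated & ~severe).sum())
            nce = pathways.natural_cure_estimate(natural_rate, max(n_mild_treated, 1))
            bundle.natural_cure = nce
            mild = ~severe
            k_t_m = int(df.loc[treated & mild, pw.cure_code].sum())
            n_t_m = int((treated & mild).sum())
            k_c_m = int(df.loc[control & mild, pw.cure_code].sum())
            n_c_m = int((control & mild).sum())
            cure_tests = {}
            if min(n_t_m, n_c_m) > 0:
                z, pe, pn = pathways.compare_cure_rates(k_t_m, n_t_m, k_c_m, n_c_m)
                cure_tests["mild"] = {"z": z, "p_exact": pe, "p_normal": pn,
                                      "k_treat": k_t_m, "n_treat": n_t_m,
                                      "k_ctrl": k_c_m, "n_ctrl": n_c_m}
            k_t_s = int(df.loc[treated & severe, pw.cure_code].sum())
            n_t_s = int((treated & severe).sum())
            k_c_s = int(df.loc[control & severe, pw.cure_code].sum())
            n_c_s = int((control & severe).sum())
            if min(n_t_s, n_c_s) > 0:
                z, pe, pn = pathways.compare_cure_rates(k_t_s, n_t_s, k_c_s, n_c_s)
                cure_tests["severe"] = {"z": z, "p_exact": pe, "p_normal": pn,
                                        "k_treat": k_t_s, "n_treat": n_t_s,
                                        "k_ctrl": k_c_s, "n_ctrl": n_c_s}
            (outdir / "natural_cure.json").write_text(
                json.dumps(
                    {
                        "natural_rate": nce.natural_rate, "n_group": nce.n_group,
                        "expected_cures": nce.expected_cures, "proportion_pct": nce.proportion_pct,
                        "cure_rate_tests": cure_tests,
                    },
                    indent=2,
                )
            )
            bundle.files["natural_cure"] = outdir / "natural_cure.json"

        stage = "report"
        bundle.metadata = {
            "seed": config.seed,
            "stage_seeds": seeds,
            "config": config.model_dump(),
        }
        (outdir / "metadata.json").write_text(json.dumps(bundle.metadata, indent=2, default=str))
        bundle.files["metadata"] = outdir / "metadata.json"
        bundle.check_files()
        return bundle
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
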