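"""End-to-end orchestration: config, per-analysis runs, report bundle.

``run_analysis`` wires the stages together: (synthetic) registry bundle →
eligibility screening and strategy assignment → covariate categorization →
per-protocol censor events → person-month expansion → IP weights →
weighted pooled logistic risk curves → bootstrap CIs → balance table,
flowchart and manifest. Every stage is also usable on its own; the
orchestration is deliberately nothing more than their composition.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from tte.adherence import adherence_curve, censor_events_for_cohort
from tte.cohort_builder import (EligibilitySpec, assign_strategy,
                                categorize_covariates, default_categorization,
                                screen_eligibility)
from tte.estimation import (OutcomeModelSpec, WeightSpec, baseline_ip_weights,
                            censoring_weights, combine_weights,
                            estimate_risk_curves, expand_person_months, km_curve)
from tte.exceptions import ConfigError
from tte.reporting import EffectEstimate, balance_table, bootstrap_effects
from tte.synthetic_registry import RegistryBundle, SyntheticConfig, generate_registry

logger = logging.getLogger(__name__)

DEFAULT_WEIGHT_COVARIATES = ("age_cat", "female", "nstemi", "sbp_cat",
                             "egfr_cat", "ldl_cat")


@dataclass(frozen=True)
class SubgroupFilter:
    name: str
    column: str
    op: Literal["eq", "lt", "ge"]
    value: object

    def mask(self, cohort: pd.DataFrame) -> pd.Series:
        col = cohort[self.column]
        if self.op == "eq":
            return col == self.value
        if self.op == "lt":
            return col < self.value
        if self.op == "ge":
            return col >= self.value
        raise ConfigError(f"unknown subgroup op {self.op!r}")


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything needed to reproduce one analysis run."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    eligibility: EligibilitySpec = field(default_factory=EligibilitySpec)
    estimands: tuple[str, ...] = ("itt", "pp")
    outcomes: tuple[str, ...] = ("composite",)
    adjustment: Literal["ipw", "covariates", "age_sex", "none"] = "ipw"
    weight_covariates: tuple[str, ...] = DEFAULT_WEIGHT_COVARIATES
    categorization: dict = field(default_factory=default_categorization)
    truncation_percentile: float | None = None
    grace_days: int = 90
    adherence_mode: Literal["pill_count", "fixed_90"] = "pill_count"
    horizon: int = 60
    knots: tuple[float, ...] = (6.0, 12.0, 24.0, 48.0)
    risk_estimator: Literal["pooled_logistic", "km"] = "pooled_logistic"
    #: post-baseline diagnosis code prefixes turned into time-varying 0/1
    #: covariates (per-protocol censoring models only)
    tv_covariate_codes: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {"hypertension": ("I10",)})
    n_bootstrap: int = 0
    seed: int = 0
    subgroups: tuple[SubgroupFilter, ...] = ()
    end_of_study: str | None = None

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            return obj
        return enc(self)

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        from tte.synthetic_registry import CovariateSpec
        kwargs = dict(raw)
        if "synthetic" in kwargs and isinstance(kwargs["synthetic"], dict):
            syn = dict(kwargs["synthetic"])
            if "covariate_spec" in syn:
                syn["covariate_spec"] = [
                    CovariateSpec(**c) if isinstance(c, dict) else c
                    for c in syn["covariate_spec"]]
            for key in ("treatment_coefs", "hazard_coefs", "adherence_stop_coefs",
                        "crossover_start_coefs", "missing_rate",
                        "noneligible_fraction"):
                if key in syn and syn[key] is None:
                    syn[key] = {}
            if "time_trend" in syn and syn["time_trend"] is not None:
                syn["time_trend"] = tuple(syn["time_trend"])
            kwargs["synthetic"] = SyntheticConfig(**syn)
        if "eligibility" in kwargs and isinstance(kwargs["eligibility"], dict):
            elig = {k: tuple(v) if isinstance(v, list) else v
                    for k, v in kwargs["eligibility"].items()}
            kwargs["eligibility"] = EligibilitySpec(**elig)
        if "subgroups" in kwargs:
            kwargs["subgroups"] = tuple(
                SubgroupFilter(**s) if isinstance(s, dict) else s
                for s in kwargs["subgroups"])
        for key in ("estimands", "outcomes", "weight_covariates", "knots"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        if "tv_covariate_codes" in kwargs and kwargs["tv_covariate_codes"]:
            kwargs["tv_covariate_codes"] = {
                k: tuple(v) for k, v in kwargs["tv_covariate_codes"].items()}
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def build_cohort(bundle: RegistryBundle, config: AnalysisConfig):
    """Screen, assign, and categorize; returns (cohort, tally)."""
    candidates, tally = screen_eligibility(bundle, config.eligibility)
    cohort = assign_strategy(candidates, bundle.dispensations,
                             config.eligibility, tally)
    cohort = categorize_covariates(cohort, config.categorization)
    return cohort, tally


def _tv_events_from_diagnoses(cohort: pd.DataFrame, diagnoses: pd.DataFrame,
                              code_map: dict[str, tuple[str, ...]]
                              ) -> pd.DataFrame | None:
    """Post-baseline diagnoses mapped to named time-varying covariates."""
    if not code_map or not len(diagnoses):
        return None
    dx = diagnoses.merge(cohort[["person_id", "time_zero"]], on="person_id")
    dx["day"] = (dx["date"] - dx["time_zero"]).dt.days
    dx = dx[dx["day"] > 0]
    pieces = []
    for name, prefixes in code_map.items():
        hit = dx.loc[dx["code"].astype(str).str.startswith(tuple(prefixes)),
                     ["person_id", "day"]].copy()
        hit["name"] = name
        pieces.append(hit)
    out = pd.concat(pieces, ignore_index=True) if pieces else None
    return out if out is not None and len(out) else None


def _outcome_variant(outcome: str) -> str:
    # heart failure is an additional qualifying indication only for the
    # death and MI outcomes; for the composite (and HF) it is an outcome
    return "death_or_mi" if outcome in ("death", "mi") else "composite"


def _model_spec(config: AnalysisConfig, outcome: str) -> OutcomeModelSpec:
    adjustment = {"ipw": "ipw", "covariates": "covariates_in_model",
                  "age_sex": "age_sex_only", "none": "unadjusted"}[config.adjustment]
    covs: tuple[str, ...] = ()
    if adjustment == "covariates_in_model":
        covs = config.weight_covariates
    elif adjustment == "age_sex_only":
        covs = ("age_cat", "female")
    return OutcomeModelSpec(knots=config.knots, adjustment=adjustment,
                            outcome=outcome, covariates=covs,
                            horizon=config.horizon)


def estimate_effect(tables: dict[str, pd.DataFrame], config: AnalysisConfig,
                    *, estimand: str, outcome: str,
                    return_curve: bool = False):
    """One full point estimate from linked person-level tables.

    ``tables`` holds the assigned, categorized cohort plus the raw child
    tables; all weight models are (re-)estimated inside, which makes this
    function the unit the bootstrap resamples around.
    """
    cohort = tables["cohort"]
    spec = _model_spec(config, outcome)

    censor_events = None
    tv_events = None
    if estimand == "pp":
        censor_events = censor_events_for_cohort(
            cohort, tables["dispensations"], tables["diagnoses"],
            acei_arb_atc_prefixes=config.eligibility.acei_arb_atc_prefixes,
            outcome_variant=_outcome_variant(outcome),
            grace_days=config.grace_days, mode=config.adherence_mode,
            horizon_months=config.horizon)
        tv_events = _tv_events_from_diagnoses(cohort, tables["diagnoses"],
                                              config.tv_covariate_codes)
    pm = expand_person_months(
        cohort, tables["outcomes"], tables["deaths"], censor_events,
        horizon=config.horizon, estimand=estimand, outcome=outcome,
        tv_events=tv_events, end_of_study=config.end_of_study)

    baseline = None
    cens = None
    if config.adjustment == "ipw":
        baseline, _ = baseline_ip_weights(
            cohort, WeightSpec(kind="baseline_treatment",
                               covariates=config.weight_covariates))
    if estimand == "pp":
        tv_cols = tuple(c for c in pm.columns if c.startswith("tv_"))
        cens = censoring_weights(
            pm, WeightSpec(kind="censoring",
                           covariates=config.weight_covariates + tv_cols,
                           knots=config.knots))
    w = combine_weights(pm, baseline, cens,
                        truncation_percentile=config.truncation_percentile)
    if estimand == "pp":
        # deviation-month rows feed the censoring model only; the outcome
        # model sees person-months uncensored at the start of the interval
        keep = pm["pp_censor"].to_numpy() == 0
        pm, w = pm.loc[keep].reset_index(drop=True), w[keep]
    if config.risk_estimator == "km":
        curve = km_curve(pm, w, horizon=config.horizon)
    else:
        curve = estimate_risk_curves(pm, spec, w, cohort=cohort)
    h = config.horizon
    result = {"risk_1": curve.risk(1, h), "risk_0": curve.risk(0, h),
              "rd": curve.rd(h), "rr": curve.rr(h)}
    if return_curve:
        return result, curve, pm, w, baseline, censor_events
    return result


def run_analysis(config: AnalysisConfig,
                 bundle: RegistryBundle | None = None) -> dict:
    """Run the configured analyses end to end and return the report bundle.

    Returns a dict with the cohort, flowchart tally, balance table,
    per-analysis effect estimates and risk curves, per-protocol adherence
    curves, and a run manifest (seed, config hash, package versions).
    Empty subgroups are skipped with a warning. Intention-to-treat results
    do not depend on any adherence-engine setting.
    """
    if bundle is None:
        bundle = generate_registry(config.synthetic)
    cohort, tally = build_cohort(bundle, config)
    tables = {"cohort": cohort, "dispensations": bundle.dispensations,
              "diagnoses": bundle.diagnoses, "deaths": bundle.deaths,
              "outcomes": bundle.outcomes}

    baseline_w = None
    if config.adjustment == "ipw":
        baseline_w, _ = baseline_ip_weights(
            cohort, WeightSpec(covariates=config.weight_covariates))
    balance = balance_table(cohort, baseline_w, list(config.weight_covariates))

    effects: list[EffectEstimate] = []
    curves = []
    adherence = None
    groups: list[tuple[str, pd.DataFrame]] = [("all", cohort)]
    for sg in config.subgroups:
        sub = cohort.loc[sg.mask(cohort)]
        if len(sub) == 0:
            logger.warning("subgroup %s is empty; skipped", sg.name)
            continue
        groups.append((sg.name, sub.reset_index(drop=True)))

    for group_name, group_cohort in groups:
        gtables = dict(tables, cohort=group_cohort)
        for estimand in config.estimands:
            for outcome in config.outcomes:
                res, curve, pm, w, _, censor_events = estimate_effect(
                    gtables, config, estimand=estimand, outcome=outcome,
                    return_curve=True)
                if config.n_bootstrap > 0:
                    def fn(tbls, _e=estimand, _o=outcome):
                        return estimate_effect(tbls, config, estimand=_e, outcome=_o)
                    est = bootstrap_effects(
                        fn, gtables, n_reps=config.n_bootstrap, seed=config.seed,
                        outcome=outcome, estimand=estimand, horizon=config.horizon)
                else:
                    est = EffectEstimate(outcome=outcome, estimand=estimand,
                                         horizon=config.horizon, point=res,
                                         seed=config.seed)
                row = est.to_row()
                row["subgroup"] = group_name
                row["n"] = len(group_cohort)
                effects.append(row)
                cf = curve.frame.copy()
                cf.insert(0, "subgroup", group_name)
                cf.insert(1, "estimand", estimand)
                cf.insert(2, "outcome", outcome)
                curves.append(cf)
                if (estimand == "pp" and outcome == "composite"
                        and group_name == "all" and censor_events is not None):
                    adherence = adherence_curve(group_cohort, censor_events,
                                                config.horizon)

    import tte
    config_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
    manifest = {
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "package_version": tte.__version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    return {
        "cohort": cohort,
        "flowchart": tally,
        "balance": balance,
        "effects": pd.DataFrame(effects),
        "curves": pd.concat(curves, ignore_index=True) if curves else pd.DataFrame(),
        "adherence": adherence,
        "manifest": manifest,
    }
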