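"""Synthetic registry generator with a fully known data-generating process.

Emulates the linked tables of a national-registry study of a secondary
prevention drug strategy after myocardial infarction with preserved
ejection fraction: one admissions table (index hospitalization with
baseline covariates), a pharmacy dispensations table, inpatient/outpatient
diagnoses, deaths, and non-fatal outcome events (re-infarction, heart
failure).

The generator exposes every knob of the data-generating process —
confounded treatment assignment, a discrete-time (monthly) outcome hazard
with a configurable treatment effect, geometric stopping/crossover
adherence processes, post-baseline indication and contraindication events,
and MCAR missingness — and records per-person ground-truth labels
(assignment, stop/crossover months, deviation day, event month) in a
``truth`` table, so that every downstream pipeline stage can be checked
against generator bookkeeping, and counterfactual risks can be computed
exactly by Monte Carlo (:func:`true_marginal_risk`).

Time is discretized in 30-day blocks ("months") counted from each
person's time zero, which is set 30 days after admission (the end of the
treatment-assignment window). Month ``t`` covers relative days
``(30*(t-1), 30*t]``.

Randomness is split per person: person ``i`` owns an independent
substream seeded by ``(seed, i)``, so enlarging the cohort never perturbs
the draws of existing persons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from tte.exceptions import ConfigError

DAYS_PER_MONTH = 30
ASSIGNMENT_WINDOW_DAYS = 30

# ATC / ICD-10-style codes used by the generator (reduced code sets).
ACEI_ATC = "C09AA02"
STATIN_ATC = "C10AA05"
ANTITHROMBOTIC_ATC = "B01AC06"
HYPERTENSION_CODE = "I10"
HEART_FAILURE_CODE = "I50"
HYPOTENSION_CODE = "I95"
DEMENTIA_CODE = "F03"
METASTATIC_CANCER_CODE = "C78"

#: recognized eligibility-violation labels for ``noneligible_fraction``
VIOLATION_LABELS = (
    "age",
    "low_lvef",
    "low_egfr",
    "prior_indication",
    "prior_acei_arb",
    "not_standard_care",
    "unemployed",
    "dementia",
    "metastatic_cancer",
)

_EVENT_TYPES = ("death", "mi", "hf")
_EVENT_TYPE_PROBS = (0.45, 0.30, 0.25)


@dataclass(frozen=True)
class CovariateSpec:
    """One baseline covariate of the admissions table.

    Parameters
    ----------
    name : str
        Column name in the admissions table.
    kind : {"binary", "continuous", "categorical"}
    params : dict
        ``binary``: ``{"p": ...}``; ``continuous``: ``{"dist": "normal",
        "mean": ..., "sd": ...}`` or ``{"dist": "uniform", "low": ...,
        "high": ...}``; ``categorical``: ``{"levels": [...], "probs": [...]}``.
    """

    name: str
    kind: Literal["binary", "continuous", "categorical"]
    params: dict

    def validate(self) -> None:
        if self.kind == "binary":
            p = self.params.get("p")
            if p is None or not (0.0 <= p <= 1.0):
                raise ConfigError(f"covariate_spec[{self.name}]: binary p must be in [0, 1]")
        elif self.kind == "continuous":
            dist = self.params.get("dist", "normal")
            if dist == "normal":
                if self.params.get("sd", -1.0) <= 0:
                    raise ConfigError(f"covariate_spec[{self.name}]: normal sd must be > 0")
            elif dist == "uniform":
                if not self.params.get("low", 0.0) < self.params.get("high", 0.0):
                    raise ConfigError(f"covariate_spec[{self.name}]: uniform needs low < high")
            else:
                raise ConfigError(f"covariate_spec[{self.name}]: unknown dist {dist!r}")
        elif self.kind == "categorical":
            levels = self.params.get("levels")
            probs = self.params.get("probs")
            if not levels or probs is None or len(levels) != len(probs):
                raise ConfigError(f"covariate_spec[{self.name}]: levels/probs mismatch")
            if abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ConfigError(f"covariate_spec[{self.name}]: probs must sum to 1")
        else:
            raise ConfigError(f"covariate_spec[{self.name}]: unknown kind {self.kind!r}")

    def standardize(self, values: np.ndarray) -> np.ndarray:
        """Map raw values to the scale linear predictors act on.

        Binary covariates enter as 0/1; continuous covariates are z-scored
        by their configured distribution moments, so a coefficient is a
        log-odds change per SD.
        """
        if self.kind == "binary":
            return values.astype(float)
        if self.kind == "continuous":
            if self.params.get("dist", "normal") == "normal":
                mu, sd = self.params["mean"], self.params["sd"]
            else:
                lo, hi = self.params["low"], self.params["high"]
                mu, sd = (lo + hi) / 2.0, (hi - lo) / np.sqrt(12.0)
            return (values.astype(float) - mu) / sd
        raise ConfigError(
            f"covariate {self.name!r}: categorical covariates need level-keyed "
            f"coefficients ('name=level'), not a single coefficient"
        )


def default_covariates() -> list[CovariateSpec]:
    """Baseline covariates loosely matching a post-MI registry population."""
    return [
        CovariateSpec("age", "continuous", {"dist": "uniform", "low": 40.0, "high": 74.99}),
        CovariateSpec("female", "binary", {"p": 0.21}),
        CovariateSpec("nstemi", "binary", {"p": 0.60}),
        CovariateSpec("sbp", "continuous", {"dist": "normal", "mean": 148.0, "sd": 22.0}),
        CovariateSpec("egfr", "continuous", {"dist": "normal", "mean": 89.0, "sd": 14.0}),
        CovariateSpec("ldl", "continuous", {"dist": "normal", "mean": 3.5, "sd": 1.0}),
    ]


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of the synthetic data-generating process.

    The linear predictors below act on standardized covariates (see
    :meth:`CovariateSpec.standardize`); all rate parameters are monthly
    probabilities; all ``*_logit`` parameters are monthly log-odds.

    The adherence defaults are calibrated so that about 46% of the treated
    arm is still adherent at 5 years and about 79% of the untreated arm
    has never crossed over, the orders of magnitude seen in dispensation
    registries for this drug class.
    """

    n_individuals: int = 1000
    seed: int = 0
    covariate_spec: list[CovariateSpec] = field(default_factory=default_covariates)
    treatment_intercept: float = 0.8
    treatment_coefs: dict[str, float] = field(
        default_factory=lambda: {"nstemi": -0.7, "sbp": 0.35, "age": 0.15}
    )
    hazard_intercept: float = -6.5
    treatment_effect: float = 0.0
    hazard_coefs: dict[str, float] = field(
        default_factory=lambda: {"age": 0.5, "nstemi": 0.15}
    )
    time_trend: tuple[float, ...] = ()
    adherence_stop_logit: float = -4.33
    adherence_stop_coefs: dict[str, float] = field(default_factory=dict)
    crossover_start_logit: float = -5.55
    crossover_start_coefs: dict[str, float] = field(default_factory=dict)
    indication_rate: float = 0.003
    contraindication_rate: float = 0.001
    missing_rate: dict[str, float] = field(
        default_factory=lambda: {"ldl": 0.11, "egfr": 0.023}
    )
    horizon_months: int = 60
    dispensation_supply_days: int = 100
    grace_days: int = 90
    noneligible_fraction: dict[str, float] = field(default_factory=dict)
    recruitment_start: str = "2010-09-01"
    recruitment_end: str = "2016-12-31"

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ConfigError("n_individuals must be >= 1")
        if self.horizon_months < 1:
            raise ConfigError("horizon_months must be >= 1")
        if self.dispensation_supply_days < 1:
            raise ConfigError("dispensation_supply_days must be >= 1")
        for name, rate in [
            ("indication_rate", self.indication_rate),
            ("contraindication_rate", self.contraindication_rate),
        ]:
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        for cov, rate in self.missing_rate.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"missing_rate[{cov}] must be in [0, 1]")
        names = [c.name for c in self.covariate_spec]
        if len(set(names)) != len(names):
            raise ConfigError("covariate_spec: duplicate covariate names")
        for c in self.covariate_spec:
            c.validate()
        for label, frac in self.noneligible_fraction.items():
            if label not in VIOLATION_LABELS:
                raise ConfigError(f"noneligible_fraction: unknown rule {label!r}")
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"noneligible_fraction[{label}] must be in [0, 1]")
        if sum(self.noneligible_fraction.values()) > 1.0:
            raise ConfigError("noneligible_fraction: fractions sum to more than 1")
        for coef_field in ("treatment_coefs", "hazard_coefs", "adherence_stop_coefs",
                           "crossover_start_coefs"):
            for key in getattr(self, coef_field):
                base = key.split("=", 1)[0]
                if base not in names:
                    raise ConfigError(f"{coef_field}: unknown covariate {key!r}")

    def with_(self, **kwargs) -> "SyntheticConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def covariate(self, name: str) -> CovariateSpec:
        for c in self.covariate_spec:
            if c.name == name:
                return c
        raise ConfigError(f"unknown covariate {name!r}")


@dataclass
class RegistryBundle:
    """The five linked registry-style tables, plus generator truth labels.

    ``truth`` is populated only by :func:`generate_registry`; bundles read
    from disk may carry ``truth=None``. It is a per-person table of the
    latent labels of the data-generating process and exists purely so that
    tests can compare pipeline output against generator bookkeeping.
    """

    admissions: pd.DataFrame
    dispensations: pd.DataFrame
    diagnoses: pd.DataFrame
    deaths: pd.DataFrame
    outcomes: pd.DataFrame
    truth: pd.DataFrame | None = None

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "admissions": self.admissions,
            "dispensations": self.dispensations,
            "diagnoses": self.diagnoses,
            "deaths": self.deaths,
            "outcomes": self.outcomes,
        }


def _eta(config: SyntheticConfig, values: dict[str, np.ndarray],
         coefs: dict[str, float]) -> np.ndarray:
    """Linear predictor from standardized covariates and a coefficient dict."""
    n = len(next(iter(values.values())))
    out = np.zeros(n)
    for key, beta in coefs.items():
        if "=" in key:
            name, level = key.split("=", 1)
            out += beta * (values[name] == level).astype(float)
        else:
            out += beta * config.covariate(key).standardize(values[key])
    return out


def _time_trend(config: SyntheticConfig, t: np.ndarray | float) -> np.ndarray | float:
    """Polynomial baseline time trend in scaled time s = t / horizon."""
    if not config.time_trend:
        return 0.0
    s = np.asarray(t, dtype=float) / config.horizon_months
    out = 0.0
    for j, c in enumerate(config.time_trend, start=1):
        out = out + c * s**j
    return out


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _draw_covariates(spec: list[CovariateSpec], rng: np.random.Generator,
                     n: int) -> dict[str, np.ndarray]:
    values: dict[str, np.ndarray] = {}
    for cov in spec:
        if cov.kind == "binary":
            values[cov.name] = (rng.random(n) < cov.params["p"]).astype(int)
        elif cov.kind == "continuous":
            if cov.params.get("dist", "normal") == "normal":
                values[cov.name] = rng.normal(cov.params["mean"], cov.params["sd"], n)
            else:
                values[cov.name] = rng.uniform(cov.params["low"], cov.params["high"], n)
        else:
            values[cov.name] = rng.choice(
                cov.params["levels"], size=n, p=cov.params["probs"]
            )
    return values


def _person_draws(config: SyntheticConfig, person_id: int) -> dict:
    """All random draws for one person, from that person's own substream."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, person_id]))
    H = config.horizon_months
    cov = _draw_covariates(config.covariate_spec, rng, 1)
    return {
        "cov": {k: v[0] for k, v in cov.items()},
        "u_admission": rng.random(),
        "u_violation": rng.random(),
        "u_violation_value": rng.random(),
        "u_assign": rng.random(),
        "first_dispense_offset": int(rng.integers(0, ASSIGNMENT_WINDOW_DAYS)),
        "u_employment": rng.random(),
        "u_event_type": rng.random(),
        "u_dx_setting": rng.random(2),
        "u_dx_position": rng.random(2),
        "u_event": rng.random(H),
        "u_transition": rng.random(H),
        "u_indication": rng.random(H),
        "u_contraindication": rng.random(H),
    }


def _first_success_month(u: np.ndarray, p: np.ndarray) -> np.ndarray:
    """First month t (1-based) with u[:, t-1] < p[:, t-1], else 0."""
    hits = u < p
    any_hit = hits.any(axis=1)
    first = hits.argmax(axis=1) + 1
    return np.where(any_hit, first, 0)


def generate_registry(config: SyntheticConfig) -> RegistryBundle:
    """Simulate a linked registry bundle under the configured process.

    Returns a :class:`RegistryBundle` whose ``truth`` table records, per
    person: the eligibility-violation label (empty string if none), the
    latent treatment assignment, stop / crossover months, effective
    indication and contraindication months, the implied per-protocol
    deviation day, and the outcome event month and type.

    Deterministic: the same config (including seed) yields byte-identical
    tables across process invocations.
    """
    n = config.n_individuals
    H = config.horizon_months
    supply = config.dispensation_supply_days
    draws = [_person_draws(config, i + 1) for i in range(n)]
    person_ids = np.arange(1, n + 1)

    cov_values = {
        c.name: np.array([d["cov"][c.name] for d in draws])
        for c in config.covariate_spec
    }

    # --- eligibility violations ------------------------------------------
    labels = list(config.noneligible_fraction)
    cuts = np.cumsum([config.noneligible_fraction[k] for k in labels])
    u_viol = np.array([d["u_violation"] for d in draws])
    violation = np.full(n, "", dtype=object)
    prev = 0.0
    for label, hi in zip(labels, cuts):
        violation[(u_viol >= prev) & (u_viol < hi)] = label
        prev = hi
    u_vv = np.array([d["u_violation_value"] for d in draws])
    # violators get the violating feature injected into their record
    age = cov_values["age"].astype(float).copy() if "age" in cov_values else np.full(n, 60.0)
    age[violation == "age"] = 75.0 + 14.0 * u_vv[violation == "age"]
    lvef = 50.0 + 20.0 * u_vv  # eligible range by default
    lvef[violation == "low_lvef"] = 25.0 + 24.0 * u_vv[violation == "low_lvef"]
    if "egfr" in cov_values:
        egfr = np.maximum(cov_values["egfr"].astype(float), 20.0)
        egfr[violation == "low_egfr"] = 5.0 + 9.0 * u_vv[violation == "low_egfr"]
        cov_values["egfr"] = egfr

    # --- admission dates and employment ----------------------------------
    start = pd.Timestamp(config.recruitment_start)
    end = pd.Timestamp(config.recruitment_end)
    window = (end - start).days
    u_adm = np.array([d["u_admission"] for d in draws])
    admission_day = np.floor(u_adm * (window + 1)).astype(int)
    admission_date = start + pd.to_timedelta(admission_day, unit="D")
    discharge_date = admission_date + pd.Timedelta(days=5)
    u_emp = np.array([d["u_employment"] for d in draws])
    employment = np.where(u_emp < 0.63, "working",
                          np.where(u_emp < 0.98, "retired", "student")).astype(object)
    employment[violation == "unemployed"] = "unemployed"

    # --- treatment assignment (confounded) --------------------------------
    eta_treat = config.treatment_intercept + _eta(config, cov_values, config.treatment_coefs)
    u_assign = np.array([d["u_assign"] for d in draws])
    assigned = (u_assign < _expit(eta_treat)).astype(int)

    # --- adherence processes (geometric with covariate links) -------------
    p_stop = _expit(config.adherence_stop_logit
                    + _eta(config, cov_values, config.adherence_stop_coefs))
    p_cross = _expit(config.crossover_start_logit
                     + _eta(config, cov_values, config.crossover_start_coefs))
    u_trans = np.stack([d["u_transition"] for d in draws])
    stop_month = _first_success_month(u_trans, p_stop[:, None])      # treated arm
    cross_month = _first_success_month(u_trans, p_cross[:, None])    # untreated arm
    stop_month = np.where(assigned == 1, stop_month, 0)
    cross_month = np.where(assigned == 0, cross_month, 0)

    # --- post-baseline indication / contraindication events ---------------
    u_ind = np.stack([d["u_indication"] for d in draws])
    u_contra = np.stack([d["u_contraindication"] for d in draws])
    ind_month = _first_success_month(u_ind, np.full((n, 1), config.indication_rate))
    contra_month = _first_success_month(u_contra, np.full((n, 1), config.contraindication_rate))

    # --- monthly outcome process ------------------------------------------
    # A treated stopper's exposure runs until the deviation day (coverage
    # end + grace): dispensed pills are consumed past the last refill, and
    # the strategy is only provably abandoned when the gap closes. This
    # keeps the exposure switch aligned with per-protocol censoring, so
    # censoring happens when exposure changes.
    supply = config.dispensation_supply_days
    first_offset = np.array([d["first_dispense_offset"] for d in draws])
    f_day = first_offset - ASSIGNMENT_WINDOW_DAYS
    boundary = DAYS_PER_MONTH * (np.maximum(stop_month, 1) - 1)
    n_fills = np.maximum(1, np.ceil((boundary - f_day) / supply)).astype(int)
    dev_day_uncapped = f_day + supply * n_fills - 1 + config.grace_days
    exposure_end_month = np.where(
        (assigned == 1) & (stop_month > 0),
        np.ceil(dev_day_uncapped / DAYS_PER_MONTH), np.inf)

    eta_haz = config.hazard_intercept + _eta(config, cov_values, config.hazard_coefs)
    u_event = np.stack([d["u_event"] for d in draws])
    event_month = np.zeros(n, dtype=int)
    for t in range(1, H + 1):
        on_rx = np.where(
            assigned == 1,
            t <= exposure_end_month,
            (cross_month != 0) & (t >= cross_month),
        )
        h_t = _expit(eta_haz + config.treatment_effect * on_rx + _time_trend(config, t))
        new_event = (event_month == 0) & (u_event[:, t - 1] < h_t)
        event_month[new_event] = t

    u_etype = np.array([d["u_event_type"] for d in draws])
    etype_idx = np.searchsorted(np.cumsum(_EVENT_TYPE_PROBS), u_etype, side="right")
    event_type = np.where(
        event_month > 0, np.array(_EVENT_TYPES, dtype=object)[np.minimum(etype_idx, 2)], ""
    ).astype(object)
    event_day = np.where(event_month > 0, DAYS_PER_MONTH * (event_month - 1) + 15, 0)

    # diagnoses only materialize while the person is alive
    def _effective(month: np.ndarray, day_in_month: int) -> np.ndarray:
        day = DAYS_PER_MONTH * (month - 1) + day_in_month
        ok = (month > 0) & ((event_month == 0) | (day <= event_day))
        return np.where(ok, month, 0)

    ind_month = _effective(ind_month, 10)
    contra_month = _effective(contra_month, 10)
    ind_day = np.where(ind_month > 0, DAYS_PER_MONTH * (ind_month - 1) + 10, 0)
    contra_day = np.where(contra_month > 0, DAYS_PER_MONTH * (contra_month - 1) + 10, 0)

    # --- dispensation streams ---------------------------------------------
    horizon_day = DAYS_PER_MONTH * H
    disp_person: list[int] = []
    disp_code: list[str] = []
    disp_day: list[int] = []      # relative to time zero
    disp_pills: list[int] = []
    deviation_day = np.full(n, -1, dtype=int)  # -1: follows strategy through horizon
    deviation_reason = np.full(n, "", dtype=object)

    for i in range(n):
        cap = event_day[i] if event_month[i] > 0 else horizon_day
        if assigned[i] == 1:
            # adherent through the end of month (stop_month - 1)
            boundary = (DAYS_PER_MONTH * (stop_month[i] - 1)
                        if stop_month[i] > 0 else horizon_day)
            refill_cap = min(boundary, cap)
            day = first_offset[i] - ASSIGNMENT_WINDOW_DAYS
            disp_person.append(person_ids[i]); disp_code.append(ACEI_ATC)
            disp_day.append(day); disp_pills.append(supply)
            cov_end = day + supply
            while cov_end < refill_cap:
                disp_person.append(person_ids[i]); disp_code.append(ACEI_ATC)
                disp_day.append(cov_end); disp_pills.append(supply)
                cov_end += supply
            lapse = (cov_end - 1) + config.grace_days
            if lapse <= horizon_day:
                if contra_day[i] > 0 and contra_day[i] <= lapse:
                    deviation_day[i] = -1  # contraindication excuses stopping
                else:
                    deviation_day[i] = lapse
                    deviation_reason[i] = "stopped_treatment"
        else:
            if cross_month[i] > 0:
                day = DAYS_PER_MONTH * (cross_month[i] - 1) + 7
                if day <= cap:
                    cov_end = day
                    while cov_end <= cap and cov_end < horizon_day:
                        disp_person.append(person_ids[i]); disp_code.append(ACEI_ATC)
                        disp_day.append(cov_end if cov_end > day else day)
                        disp_pills.append(supply)
                        cov_end = (cov_end if cov_end > day else day) + supply
                    if ind_day[i] > 0 and ind_day[i] <= day:
                        deviation_day[i] = -1  # new indication excuses initiation
                    else:
                        deviation_day[i] = day
                        deviation_reason[i] = "initiated_treatment"

    time_zero = admission_date + pd.Timedelta(days=ASSIGNMENT_WINDOW_DAYS)

    # standard-care dispensations (statin + antithrombotic) in the window
    std_mask = violation != "not_standard_care"
    std_ids = person_ids[std_mask]
    std_dates = admission_date[std_mask] + pd.Timedelta(days=1)
    dispensations = pd.DataFrame({
        "person_id": np.concatenate([
            np.asarray(disp_person, dtype=int), std_ids, std_ids,
            person_ids[violation == "prior_acei_arb"],
        ]),
        "atc_code": (list(disp_code) + [STATIN_ATC] * len(std_ids)
                     + [ANTITHROMBOTIC_ATC] * len(std_ids)
                     + [ACEI_ATC] * int((violation == "prior_acei_arb").sum())),
        "dispense_date": pd.DatetimeIndex(np.concatenate([
            (time_zero[np.asarray(disp_person, dtype=int) - 1]
             + pd.to_timedelta(disp_day, unit="D")).values,
            std_dates.values, std_dates.values,
            (admission_date[violation == "prior_acei_arb"]
             - pd.Timedelta(days=100)).values,
        ])),
        "pill_count": (list(disp_pills) + [100] * (2 * len(std_ids))
                       + [100] * int((violation == "prior_acei_arb").sum())),
    }).sort_values(["person_id", "dispense_date"], kind="stable").reset_index(drop=True)

    # --- diagnoses ---------------------------------------------------------
    u_set = np.stack([d["u_dx_setting"] for d in draws])
    u_pos = np.stack([d["u_dx_position"] for d in draws])
    dx_rows = []
    for i in np.flatnonzero(ind_month > 0):
        dx_rows.append((person_ids[i], HYPERTENSION_CODE,
                        time_zero[i] + pd.Timedelta(days=int(ind_day[i])),
                        "inpatient" if u_set[i, 0] < 0.5 else "outpatient",
                        "primary" if u_pos[i, 0] < 0.5 else "secondary"))
    for i in np.flatnonzero(contra_month > 0):
        dx_rows.append((person_ids[i], HYPOTENSION_CODE,
                        time_zero[i] + pd.Timedelta(days=int(contra_day[i])),
                        "inpatient" if u_set[i, 1] < 0.5 else "outpatient",
                        "primary" if u_pos[i, 1] < 0.5 else "secondary"))
    lookback_codes = {"prior_indication": HYPERTENSION_CODE, "dementia": DEMENTIA_CODE,
                      "metastatic_cancer": METASTATIC_CANCER_CODE}
    for label, code in lookback_codes.items():
        for i in np.flatnonzero(violation == label):
            dx_rows.append((person_ids[i], code,
                            admission_date[i] - pd.Timedelta(days=200),
                            "outpatient", "primary"))
    diagnoses = pd.DataFrame(
        dx_rows, columns=["person_id", "code", "date", "setting", "position"]
    ).sort_values(["person_id", "date"], kind="stable").reset_index(drop=True)

    # --- deaths and outcome events ----------------------------------------
    has_event = event_month > 0
    event_date_all = time_zero + pd.to_timedelta(event_day, unit="D")
    is_death = has_event & (event_type == "death")
    deaths = pd.DataFrame({
        "person_id": person_ids[is_death],
        "death_date": pd.DatetimeIndex(event_date_all[is_death]),
    }).reset_index(drop=True)
    is_nonfatal = has_event & ~is_death
    outcomes = pd.DataFrame({
        "person_id": person_ids[is_nonfatal],
        "event_type": event_type[is_nonfatal],
        "event_date": pd.DatetimeIndex(event_date_all[is_nonfatal]),
    }).reset_index(drop=True)

    admissions = pd.DataFrame({
        "person_id": person_ids,
        "admission_date": admission_date,
        "discharge_date": discharge_date,
        "age": age,
        "lvef_percent": lvef,
        "mi_type": np.where(cov_values.get("nstemi", np.zeros(n)) == 1,
                            "nstemi", "stemi"),
        "angiography": True,
        "employment_status": employment,
    })
    for c in config.covariate_spec:
        if c.name == "age":
            continue
        admissions[c.name] = cov_values[c.name]

    truth = pd.DataFrame({
        "person_id": person_ids,
        "violation": violation,
        "assigned": assigned,
        "first_dispense_day": np.where(assigned == 1,
                                       first_offset - ASSIGNMENT_WINDOW_DAYS, 0),
        "stop_month": stop_month,
        "crossover_month": cross_month,
        "indication_month": ind_month,
        "contraindication_month": contra_month,
        "event_month": event_month,
        "event_type": event_type,
        "event_day": np.where(has_event, event_day, -1),
        "deviation_day": deviation_day,
        "deviation_reason": deviation_reason,
    })

    return RegistryBundle(admissions, dispensations, diagnoses, deaths, outcomes, truth)


def inject_missingness(bundle: RegistryBundle, config: SyntheticConfig) -> RegistryBundle:
    """Set baseline covariates missing completely at random (MCAR).

    Each covariate named in ``config.missing_rate`` is independently
    blanked (NaN) in the admissions table at its configured rate. All
    other fields, and all other tables, are untouched. Draws come from a
    dedicated substream, so missingness does not perturb the generation
    stream.
    """
    admissions = bundle.admissions.copy()
    for j, (name, rate) in enumerate(sorted(config.missing_rate.items())):
        if name not in admissions.columns:
            raise ConfigError(f"missing_rate: covariate {name!r} not in admissions")
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 2_000_000_000 + j]))
        mask = rng.random(len(admissions)) < rate
        col = admissions[name].astype(float) if admissions[name].dtype != object \
            else admissions[name].astype(object)
        col[mask] = np.nan
        admissions[name] = col
    return RegistryBundle(admissions, bundle.dispensations, bundle.diagnoses,
                          bundle.deaths, bundle.outcomes, bundle.truth)


def true_marginal_risk(config: SyntheticConfig, arm: str, horizon: int,
                       n_mc: int = 100_000, oracle_seed: int = 12345) -> float:
    """Counterfactual cumulative incidence under sustained assignment.

    Monte-Carlo estimate of the marginal risk at ``horizon`` months if
    everyone followed ``arm`` with full adherence. Covariates are drawn
    ``n_mc`` times; given covariates the risk is computed exactly as
    ``1 - prod_t (1 - h_t)``, so the only MC noise is over the covariate
    distribution (SE well below ``sqrt(0.25 / n_mc)``).
    """
    if arm not in ("treated", "untreated"):
        raise ConfigError(f"arm must be 'treated' or 'untreated', got {arm!r}")
    if n_mc < 1:
        raise ConfigError("n_mc must be >= 1")
    if horizon > config.horizon_months:
        raise ValueError(
            f"horizon {horizon} exceeds config.horizon_months {config.horizon_months}")
    rng = np.random.default_rng(np.random.SeedSequence([oracle_seed]))
    cov = _draw_covariates(config.covariate_spec, rng, n_mc)
    eta = config.hazard_intercept + _eta(config, cov, config.hazard_coefs)
    if arm == "treated":
        eta = eta + config.treatment_effect
    t = np.arange(1, horizon + 1)
    h = _expit(eta[:, None] + np.broadcast_to(_time_trend(config, t), (1, horizon)))
    surv = np.prod(1.0 - h, axis=1)
    return float(np.mean(1.0 - surv))
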