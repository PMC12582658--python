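"""Eligibility screening, strategy assignment, and the exclusion flowchart.

Screens a registry bundle against trial-style eligibility criteria
(age, index-event window, preserved ejection fraction, standard MI care,
occupational status, no contraindication, no existing indication or prior
use of the study drugs, no dementia or metastatic cancer in a 3-year
lookback), assigns each eligible person to a treatment strategy from
dispensations in the 30-day assignment window, and tallies exclusions in
the order the criteria are declared, counting each person only under the
first criterion they fail.

Time zero defaults to a fixed day-30 landmark (admission date plus the
assignment window) for both arms, so that eligibility, assignment and the
start of follow-up coincide and neither arm accrues immortal time. An
alternative convention — time zero at the assignment date in the treated
arm — is available via ``EligibilitySpec.time_zero_mode``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from tte.exceptions import ConfigError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EligibilitySpec:
    """Eligibility criteria and code sets.

    Code sets are ICD-10-style / ATC prefixes matched by ``startswith``;
    they are deliberately small configurable stand-ins for full registry
    dictionaries.
    """

    age_min: int = 18
    age_max_exclusive: int = 75
    assignment_window_days: int = 30
    lvef_min_percent: float = 50.0
    egfr_min: float = 15.0
    lookback_years: int = 3
    recruitment_start: str = "2010-09-01"
    recruitment_end: str = "2021-06-30"
    indication_codes: tuple[str, ...] = ("I10", "I50", "E10", "E11", "N18")
    contraindication_codes: tuple[str, ...] = ("I95", "I70.1")
    exclusion_codes: tuple[str, ...] = ("C77", "C78", "C79", "F00", "F01", "F02", "F03")
    acei_arb_atc_prefixes: tuple[str, ...] = ("C09A", "C09B", "C09C", "C09D")
    statin_atc_prefixes: tuple[str, ...] = ("C10A",)
    antithrombotic_atc_prefixes: tuple[str, ...] = ("B01A",)
    employment_required: bool = True
    eligible_employment: tuple[str, ...] = ("working", "retired", "student")
    time_zero_mode: Literal["landmark", "assignment"] = "landmark"

    def __post_init__(self) -> None:
        if self.age_min >= self.age_max_exclusive:
            raise ConfigError("age_min must be < age_max_exclusive")
        if self.assignment_window_days <= 0 or self.lookback_years <= 0:
            raise ConfigError("windows must be positive")
        if not self.acei_arb_atc_prefixes:
            raise ConfigError("acei_arb_atc_prefixes must be non-empty")


@dataclass
class FlowchartTally:
    """Ordered exclusion counts for the selection flowchart."""

    n_input: int
    steps: list[tuple[str, int]] = field(default_factory=list)
    n_eligible: int = 0
    n_treated: int | None = None
    n_untreated: int | None = None

    def validate(self) -> None:
        excluded = sum(n for _, n in self.steps)
        if self.n_input - excluded != self.n_eligible:
            raise AssertionError(
                f"flowchart not conserved: {self.n_input} - {excluded} != {self.n_eligible}")
        if self.n_treated is not None and self.n_untreated is not None:
            if self.n_treated + self.n_untreated != self.n_eligible:
                raise AssertionError("per-arm counts do not sum to n_eligible")

    def set_arm_counts(self, n_treated: int, n_untreated: int) -> None:
        self.n_treated = int(n_treated)
        self.n_untreated = int(n_untreated)
        self.validate()

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "exclusions": [{"criterion": c, "n_excluded": int(n)} for c, n in self.steps],
            "n_eligible": self.n_eligible,
            "n_treated": self.n_treated,
            "n_untreated": self.n_untreated,
        }


def _startswith_any(series: pd.Series, prefixes: tuple[str, ...]) -> pd.Series:
    return series.astype(str).str.startswith(tuple(prefixes))


def _require_datetime(df: pd.DataFrame, col: str, table: str) -> None:
    if not pd.api.types.is_datetime64_any_dtype(df[col]):
        raise ValueError(f"{table}.{col} must be datetime; parse dates on read")


def _lookback_flags(admissions: pd.DataFrame, events: pd.DataFrame,
                    date_col: str, match: pd.Series, lookback_years: int,
                    include_admission_day: bool) -> pd.Series:
    """Per-person flag: any matching event in the pre-admission lookback."""
    flagged = events.loc[match, ["person_id", date_col]].merge(
        admissions[["person_id", "admission_date"]], on="person_id")
    lo = flagged["admission_date"] - pd.DateOffset(years=lookback_years)
    if include_admission_day:
        hit = (flagged[date_col] > lo) & (flagged[date_col] <= flagged["admission_date"])
    else:
        # dispensations on/after admission belong to the assignment window,
        # not to history
        hit = (flagged[date_col] > lo) & (flagged[date_col] < flagged["admission_date"])
    ids = flagged.loc[hit, "person_id"].unique()
    return admissions["person_id"].isin(ids)


def screen_eligibility(bundle, spec: EligibilitySpec
                       ) -> tuple[pd.DataFrame, FlowchartTally]:
    """Apply the eligibility criteria in declared order.

    Returns the candidate table (one row per eligible person, time zero
    not yet assigned) and the exclusion flowchart. A person failing
    several criteria is counted only under the first failed one.

    Overlapping admissions for one person are resolved to the earliest
    qualifying admission, with a warning.
    """
    admissions = bundle.admissions
    _require_datetime(admissions, "admission_date", "admissions")

    if admissions["person_id"].duplicated().any():
        n_dup = int(admissions["person_id"].duplicated().sum())
        logger.warning("admissions: %d duplicate person rows; keeping earliest", n_dup)
        admissions = (admissions.sort_values("admission_date", kind="stable")
                      .drop_duplicates("person_id", keep="first"))
    admissions = admissions.reset_index(drop=True)

    disp = bundle.dispensations
    diag = bundle.diagnoses
    window_end = admissions["admission_date"] + pd.Timedelta(days=spec.assignment_window_days)

    # in-window standard-care dispensations
    def window_flag(prefixes: tuple[str, ...]) -> pd.Series:
        rows = disp.loc[_startswith_any(disp["atc_code"], prefixes),
                        ["person_id", "dispense_date"]].merge(
            pd.DataFrame({"person_id": admissions["person_id"],
                          "admission_date": admissions["admission_date"],
                          "window_end": window_end}), on="person_id")
        hit = ((rows["dispense_date"] >= rows["admission_date"])
               & (rows["dispense_date"] <= rows["window_end"]))
        return admissions["person_id"].isin(rows.loc[hit, "person_id"].unique())

    lb = spec.lookback_years
    fails: list[tuple[str, pd.Series]] = []
    in_window = ((admissions["admission_date"] >= pd.Timestamp(spec.recruitment_start))
                 & (admissions["admission_date"] <= pd.Timestamp(spec.recruitment_end)))
    fails.append(("admission outside recruitment period", ~in_window))
    age_ok = (admissions["age"] >= spec.age_min) & (admissions["age"] < spec.age_max_exclusive)
    fails.append((f"age outside [{spec.age_min}, {spec.age_max_exclusive})", ~age_ok))
    fails.append((f"LVEF below {spec.lvef_min_percent:g}%",
                  ~(admissions["lvef_percent"] >= spec.lvef_min_percent)))
    std_care = (admissions.get("angiography", pd.Series(True, index=admissions.index))
                & window_flag(spec.statin_atc_prefixes)
                & window_flag(spec.antithrombotic_atc_prefixes))
    fails.append(("no standard MI care (angiography, statin, antithrombotic)", ~std_care))
    if spec.employment_required:
        emp_ok = admissions["employment_status"].isin(spec.eligible_employment)
        fails.append(("not working, retired or studying", ~emp_ok))
    contra = (
        (admissions["egfr"] < spec.egfr_min)
        | _lookback_flags(admissions, diag, "date",
                          _startswith_any(diag["code"], spec.contraindication_codes),
                          lb, include_admission_day=True)
    )
    fails.append(("contraindication (low eGFR, hypotension, renal artery stenosis)",
                  contra))
    prior_use = _lookback_flags(admissions, disp, "dispense_date",
                                _startswith_any(disp["atc_code"], spec.acei_arb_atc_prefixes),
                                lb, include_admission_day=False)
    prior_ind = _lookback_flags(admissions, diag, "date",
                                _startswith_any(diag["code"], spec.indication_codes),
                                lb, include_admission_day=True)
    fails.append(("existing indication or prior ACEi/ARB use", prior_use | prior_ind))
    excl = _lookback_flags(admissions, diag, "date",
                           _startswith_any(diag["code"], spec.exclusion_codes),
                           lb, include_admission_day=True)
    fails.append(("dementia or metastatic cancer", excl))

    tally = FlowchartTally(n_input=len(admissions))
    remaining = pd.Series(True, index=admissions.index)
    for label, fail in fails:
        newly = remaining & fail.to_numpy()
        tally.steps.append((label, int(newly.sum())))
        remaining &= ~newly
    candidates = admissions.loc[remaining].reset_index(drop=True)
    tally.n_eligible = len(candidates)
    tally.validate()
    return candidates, tally


def assign_strategy(candidates: pd.DataFrame, dispensations: pd.DataFrame,
                    spec: EligibilitySpec,
                    tally: FlowchartTally | None = None) -> pd.DataFrame:
    """Assign each candidate to a strategy from assignment-window dispensations.

    Arm is ``acei_arb`` iff any dispensation with a matching ATC prefix is
    dated within ``assignment_window_days`` of admission (inclusive);
    otherwise ``none``. Time zero is the day-30 landmark in ``landmark``
    mode, or the first qualifying dispensation date for the treated arm in
    ``assignment`` mode. Dispensations with unrecognized ATC codes are
    ignored.
    """
    cohort = candidates.copy()
    window_days = spec.assignment_window_days
    rows = dispensations.loc[
        _startswith_any(dispensations["atc_code"], spec.acei_arb_atc_prefixes),
        ["person_id", "dispense_date"]].merge(
        cohort[["person_id", "admission_date"]], on="person_id")
    in_window = ((rows["dispense_date"] >= rows["admission_date"])
                 & (rows["dispense_date"] <= rows["admission_date"]
                    + pd.Timedelta(days=window_days)))
    first = (rows.loc[in_window].groupby("person_id")["dispense_date"].min())
    cohort["assignment_date"] = cohort["person_id"].map(first)
    cohort["arm"] = np.where(cohort["assignment_date"].notna(), "acei_arb", "none")
    landmark = cohort["admission_date"] + pd.Timedelta(days=window_days)
    if spec.time_zero_mode == "landmark":
        cohort["time_zero"] = landmark
    elif spec.time_zero_mode == "assignment":
        cohort["time_zero"] = cohort["assignment_date"].fillna(landmark)
    else:
        raise ConfigError(f"unknown time_zero_mode {spec.time_zero_mode!r}")
    if tally is not None:
        tally.set_arm_counts(int((cohort["arm"] == "acei_arb").sum()),
                             int((cohort["arm"] == "none").sum()))
    return cohort


def _labels_from_cuts(cuts: list[float]) -> list[str]:
    labels = [f"<{cuts[0]:g}"]
    labels += [f"{lo:g}-{hi:g}" for lo, hi in zip(cuts[:-1], cuts[1:])]
    labels.append(f">={cuts[-1]:g}")
    return labels


def categorize_covariates(cohort: pd.DataFrame,
                          scheme: dict[str, list[float] | None]) -> pd.DataFrame:
    """Categorize covariates, carrying an explicit ``missing`` level.

    ``scheme`` maps a covariate name to its cut points (continuous) or to
    ``None`` (categorical/binary: pass levels through). The categorized
    column is written as ``<name>_cat``; raw values are preserved.
    """
    out = cohort.copy()
    for name, cuts in scheme.items():
        if name not in out.columns:
            raise ConfigError(f"categorization scheme names unknown covariate {name!r}")
        col = out[name]
        if cuts is None:
            cat = col.astype(object).where(col.notna(), "missing").astype(str)
        else:
            edges = [-np.inf, *cuts, np.inf]
            cat = pd.cut(col.astype(float), bins=edges, right=False,
                         labels=_labels_from_cuts(list(cuts))).astype(object)
            cat = pd.Series(cat, index=out.index).where(col.notna(), "missing")
        out[f"{name}_cat"] = cat.astype(str)
    return out


def default_categorization() -> dict[str, list[float] | None]:
    """Cut points for the default synthetic covariates."""
    return {
        "age": [50.0, 60.0, 67.0],
        "sbp": [130.0, 150.0, 170.0],
        "egfr": [60.0, 90.0],
        "ldl": [2.8, 3.5, 4.2],
    }
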