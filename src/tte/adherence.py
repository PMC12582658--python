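"""Dispensation-based treatment episodes and per-protocol deviation times.

A dispensation of ``n`` pills at one-pill-per-day covers ``n`` days from
the dispense date. Successive dispensations are merged into one
continuous-treatment episode when the gap between the end of coverage and
the next dispense date is strictly less than the grace period (90 days by
default); overlapping dispensations stockpile, extending coverage from
the end of the previous supply.

Per-protocol deviation is established:

* in the treated arm, on the first day a treatment lapse is confirmed —
  coverage end plus the grace period — unless a contraindication
  (hypotension, renal artery stenosis) was diagnosed on or before that
  day;
* in the untreated arm, on the day of the first study-drug dispensation
  after time zero, unless it was preceded by a qualifying new indication
  (hypertension; additionally heart failure for the death and
  myocardial-infarction outcomes).

Switching between drug classes within the study-drug ATC prefixes is
adherence-neutral: episodes pool all matching dispensations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from tte.exceptions import ConfigError

DAYS_PER_MONTH = 30


@dataclass(frozen=True)
class TreatmentEpisode:
    """One continuous-coverage interval, in days since time zero (inclusive)."""

    person_id: int
    start_day: int
    end_day: int
    covered_days: int


@dataclass(frozen=True)
class CensorEvent:
    """Per-protocol deviation for one person."""

    person_id: int
    censor_day: int
    reason: Literal["stopped_treatment", "initiated_treatment"]


def month_of_day(day: float) -> int:
    """Map a relative day to its 30-day month (month t covers (30(t-1), 30t])."""
    return max(1, math.ceil(day / DAYS_PER_MONTH))


def build_episodes(dispensations: pd.DataFrame, *, pills_per_day: int = 1,
                   grace_days: int = 90,
                   mode: Literal["pill_count", "fixed_90"] = "pill_count",
                   ) -> list[TreatmentEpisode]:
    """Merge a dispensation stream into continuous-treatment episodes.

    Parameters
    ----------
    dispensations : DataFrame
        Columns ``person_id``, ``day`` (days since time zero; may be
        negative for assignment-window dispensations) and ``pill_count``.
        Dispensations that precede the assignment window should already
        have been dropped — they speak to eligibility, not adherence.
    pills_per_day : int
        Fixed daily dose assumption; each dispensation covers
        ``pill_count // pills_per_day`` days.
    grace_days : int
        Strict merge threshold: a gap of exactly ``grace_days`` starts a
        new episode.
    mode : {"pill_count", "fixed_90"}
        ``fixed_90`` assigns every dispensation 90 days of coverage
        regardless of pill count (a sensitivity variant).
    """
    if mode not in ("pill_count", "fixed_90"):
        raise ConfigError(f"unknown episode mode {mode!r}")
    if pills_per_day < 1:
        raise ConfigError("pills_per_day must be >= 1")
    episodes: list[TreatmentEpisode] = []
    df = dispensations.sort_values(["person_id", "day"], kind="stable")
    for pid, grp in df.groupby("person_id", sort=True):
        ep_start = None
        cov_end = 0  # exclusive end of coverage
        covered = 0
        for day, pills in zip(grp["day"].to_numpy(), grp["pill_count"].to_numpy()):
            supply = 90 if mode == "fixed_90" else int(pills) // pills_per_day
            if supply < 1:
                raise ConfigError(f"person {pid}: dispensation with pill_count < "
                                  f"pills_per_day gives zero coverage")
            if ep_start is None:
                ep_start, cov_end, covered = int(day), int(day) + supply, supply
            elif day < cov_end:  # overlap: stockpile
                cov_end += supply
                covered += supply
            elif day - cov_end < grace_days:  # bridgeable gap, same episode
                cov_end = int(day) + supply
                covered += supply
            else:
                episodes.append(TreatmentEpisode(int(pid), ep_start, cov_end - 1, covered))
                ep_start, cov_end, covered = int(day), int(day) + supply, supply
        if ep_start is not None:
            episodes.append(TreatmentEpisode(int(pid), ep_start, cov_end - 1, covered))
    return episodes


def episodes_frame(episodes: list[TreatmentEpisode]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.person_id, e.start_day, e.end_day, e.covered_days) for e in episodes],
        columns=["person_id", "start_day", "end_day", "covered_days"],
    )


def pp_censor_time(person_id: int, arm: str,
                   episodes: list[TreatmentEpisode],
                   initiation_days: list[int],
                   indication_days: list[int],
                   contraindication_days: list[int],
                   *, grace_days: int = 90,
                   horizon_days: int = 60 * DAYS_PER_MONTH) -> CensorEvent | None:
    """Per-protocol deviation time for one person, or None if none occurs.

    ``initiation_days`` are post-time-zero study-drug dispense days (used
    for the untreated arm); ``indication_days`` / ``contraindication_days``
    are post-baseline diagnosis days of the qualifying code sets.
    """
    if arm == "acei_arb":
        lapse = episodes[0].end_day + grace_days if episodes else grace_days
        if lapse > horizon_days:
            return None
        if any(d <= lapse for d in contraindication_days):
            return None  # contraindication excuses discontinuation
        return CensorEvent(person_id, max(0, lapse), "stopped_treatment")
    if arm == "none":
        post = [d for d in initiation_days if d > 0]
        if not post:
            return None
        first = min(post)
        if first > horizon_days:
            return None
        if any(d <= first for d in indication_days):
            return None  # new indication excuses initiation
        return CensorEvent(person_id, first, "initiated_treatment")
    raise ConfigError(f"unknown arm {arm!r}")


def _relative_days(dates: pd.Series, time_zero: pd.Series) -> pd.Series:
    return (dates - time_zero).dt.days


def censor_events_for_cohort(cohort: pd.DataFrame, dispensations: pd.DataFrame,
                             diagnoses: pd.DataFrame, *,
                             acei_arb_atc_prefixes: tuple[str, ...] = ("C09A", "C09B",
                                                                       "C09C", "C09D"),
                             indication_codes: tuple[str, ...] = ("I10",),
                             hf_codes: tuple[str, ...] = ("I50",),
                             contraindication_codes: tuple[str, ...] = ("I95", "I70.1"),
                             outcome_variant: Literal["composite", "death_or_mi"]
                             = "composite",
                             grace_days: int = 90,
                             mode: Literal["pill_count", "fixed_90"] = "pill_count",
                             horizon_months: int = 60) -> pd.DataFrame:
    """Determine every cohort member's per-protocol deviation, if any.

    Expects ``cohort`` with ``person_id``, ``arm``, ``admission_date`` and
    ``time_zero``. Returns a frame with columns ``person_id``,
    ``censor_day``, ``censor_month`` and ``reason`` (one row per deviating
    person). For ``outcome_variant="death_or_mi"`` a new heart-failure
    diagnosis also counts as an indication excusing initiation.
    """
    if outcome_variant not in ("composite", "death_or_mi"):
        raise ConfigError(f"unknown outcome_variant {outcome_variant!r}")
    horizon_days = horizon_months * DAYS_PER_MONTH
    cohort = cohort.reset_index(drop=True)

    drug = dispensations.loc[
        dispensations["atc_code"].astype(str).str.startswith(tuple(acei_arb_atc_prefixes)),
        ["person_id", "dispense_date", "pill_count"]].merge(
        cohort[["person_id", "admission_date", "time_zero"]], on="person_id")
    drug = drug[drug["dispense_date"] >= drug["admission_date"]]
    drug["day"] = _relative_days(drug["dispense_date"], drug["time_zero"])

    ind_codes = tuple(indication_codes) + (tuple(hf_codes)
                                           if outcome_variant == "death_or_mi" else ())
    dx = diagnoses.merge(cohort[["person_id", "time_zero"]], on="person_id")
    dx["day"] = _relative_days(dx["date"], dx["time_zero"])
    dx = dx[dx["day"] > 0]  # post-baseline only
    code = dx["code"].astype(str)
    ind_days = dx.loc[code.str.startswith(ind_codes), ["person_id", "day"]] \
        if ind_codes else dx.iloc[0:0][["person_id", "day"]]
    contra_days = dx.loc[code.str.startswith(tuple(contraindication_codes)),
                         ["person_id", "day"]]

    episodes = build_episodes(drug[["person_id", "day", "pill_count"]],
                              grace_days=grace_days, mode=mode)
    eps_by_person: dict[int, list[TreatmentEpisode]] = {}
    for e in episodes:
        eps_by_person.setdefault(e.person_id, []).append(e)
    init_by_person = drug.groupby("person_id")["day"].apply(list).to_dict()
    ind_by_person = ind_days.groupby("person_id")["day"].apply(list).to_dict()
    contra_by_person = contra_days.groupby("person_id")["day"].apply(list).to_dict()

    rows = []
    for pid, arm in zip(cohort["person_id"], cohort["arm"]):
        ev = pp_censor_time(
            pid, arm,
            eps_by_person.get(pid, []),
            init_by_person.get(pid, []),
            ind_by_person.get(pid, []),
            contra_by_person.get(pid, []),
            grace_days=grace_days, horizon_days=horizon_days)
        if ev is not None:
            rows.append((ev.person_id, ev.censor_day, month_of_day(ev.censor_day),
                         ev.reason))
    return pd.DataFrame(rows, columns=["person_id", "censor_day", "censor_month",
                                       "reason"])


def adherence_curve(cohort: pd.DataFrame, censor_events: pd.DataFrame,
                    horizon_months: int = 60,
                    end_months: pd.Series | None = None) -> pd.DataFrame:
    """Per-arm proportion still following the assigned strategy, by month.

    A Kaplan–Meier-style curve with strategy deviation as the event;
    death, outcome and administrative end of follow-up (``end_months``,
    a person-indexed Series, default: full horizon) act as non-informative
    censoring. Deviations beyond the horizon count as adherent at horizon.
    """
    dev = cohort["person_id"].map(
        censor_events.set_index("person_id")["censor_month"]
        if len(censor_events) else pd.Series(dtype=float))
    dev = dev.fillna(np.inf).to_numpy()
    if end_months is None:
        end = np.full(len(cohort), horizon_months)
    else:
        end = cohort["person_id"].map(end_months).fillna(horizon_months).to_numpy()
    out = []
    for arm, mask in [(a, (cohort["arm"] == a).to_numpy())
                      for a in ("acei_arb", "none")]:
        d, e = dev[mask], end[mask]
        surv = 1.0
        for t in range(1, horizon_months + 1):
            at_risk = ((d >= t) & (e >= t)).sum()
            deviated = ((d == t) & (e >= t)).sum()
            if at_risk > 0:
                surv *= 1.0 - deviated / at_risk
            out.append((arm, t, surv))
    return pd.DataFrame(out, columns=["arm", "month", "adherent"])
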