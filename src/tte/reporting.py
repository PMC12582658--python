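"""Balance diagnostics, bootstrap inference, and effect summaries.

Standardized mean differences use the standard pooled-variance
definitions: for a binary covariate with proportions ``p1, p2``,

    SMD = |p1 - p2| / sqrt((p1 (1-p1) + p2 (1-p2)) / 2)

and for a continuous covariate with moments ``(m1, s1), (m2, s2)``,

    SMD = |m1 - m2| / sqrt((s1^2 + s2^2) / 2).

Weighted SMDs use the same formulas with weighted means, proportions and
variances. Multi-level categorical covariates are summarized by the
maximum over level-wise binary SMDs (a declared convention).

Confidence intervals are nonparametric bootstrap percentile intervals:
individuals are resampled with replacement and the full estimator —
including re-estimation of all weight models — is re-run in every
replicate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# standardized mean differences
# --------------------------------------------------------------------------

def _smd_from_props(p1: float, p2: float) -> float:
    v = (p1 * (1.0 - p1) + p2 * (1.0 - p2)) / 2.0
    if v == 0.0:
        if p1 == p2:
            return 0.0
        warnings.warn("binary SMD: both groups degenerate with unequal "
                      "proportions; SMD is infinite")
        return float("inf")
    return abs(p1 - p2) / np.sqrt(v)


def smd_binary(group1: tuple[int, int], group2: tuple[int, int]) -> float:
    """Absolute standardized mean difference from (positives, n) counts."""
    for pos, n in (group1, group2):
        if n < 1:
            raise ValueError("smd_binary: group size must be >= 1")
        if not 0 <= pos <= n:
            raise ValueError("smd_binary: positives must be in [0, n]")
    p1 = group1[0] / group1[1]
    p2 = group2[0] / group2[1]
    return _smd_from_props(p1, p2)


def smd_continuous(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """Absolute standardized mean difference from group moments."""
    if sd1 < 0 or sd2 < 0:
        raise ValueError("smd_continuous: sd must be >= 0")
    v = (sd1**2 + sd2**2) / 2.0
    if v == 0.0:
        if mean1 == mean2:
            return 0.0
        warnings.warn("continuous SMD: zero variance in both groups with "
                      "unequal means; SMD is infinite")
        return float("inf")
    return abs(mean1 - mean2) / np.sqrt(v)


def _wmoments(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    ok = ~np.isnan(x)
    x, w = x[ok], w[ok]
    m = float(np.average(x, weights=w))
    s = float(np.sqrt(np.average((x - m) ** 2, weights=w)))
    return m, s


@dataclass
class BalanceRow:
    covariate: str
    summary_treated: str
    summary_untreated: str
    smd: float
    smd_weighted: float


def balance_table(cohort: pd.DataFrame, weights: pd.Series | np.ndarray | None,
                  covariates: list[str]) -> pd.DataFrame:
    """Covariate balance before and after IP weighting, one row per covariate.

    ``weights`` is person-aligned (same order as ``cohort`` or indexed by
    person_id); ``None`` means unweighted in both columns.
    """
    a = (cohort["arm"] == "acei_arb").to_numpy()
    if weights is None:
        w = np.ones(len(cohort))
    elif isinstance(weights, pd.Series):
        w = cohort["person_id"].map(weights).to_numpy(float)
    else:
        w = np.asarray(weights, dtype=float)
    ones = np.ones(len(cohort))
    rows: list[BalanceRow] = []
    for name in covariates:
        if name not in cohort.columns:
            raise KeyError(f"balance_table: covariate {name!r} not in cohort")
        col = cohort[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(pd.unique(col.astype(str)))
            def max_level_smd(wt: np.ndarray) -> float:
                out = 0.0
                for lev in levels:
                    x = (col.astype(str) == lev).to_numpy(float)
                    p1 = np.average(x[a], weights=wt[a])
                    p2 = np.average(x[~a], weights=wt[~a])
                    out = max(out, _smd_from_props(p1, p2))
                return out
            p1_mode = col[a].astype(str).mode().iat[0] if a.any() else ""
            p2_mode = col[~a].astype(str).mode().iat[0] if (~a).any() else ""
            rows.append(BalanceRow(name, f"mode={p1_mode}", f"mode={p2_mode}",
                                   max_level_smd(ones), max_level_smd(w)))
        else:
            x = col.to_numpy(float)
            m1, s1 = _wmoments(x[a], ones[a])
            m2, s2 = _wmoments(x[~a], ones[~a])
            mw1, sw1 = _wmoments(x[a], w[a])
            mw2, sw2 = _wmoments(x[~a], w[~a])
            rows.append(BalanceRow(
                name, f"{m1:.2f} ({s1:.2f})", f"{m2:.2f} ({s2:.2f})",
                smd_continuous(m1, s1, m2, s2),
                smd_continuous(mw1, sw1, mw2, sw2)))
    return pd.DataFrame([r.__dict__ for r in rows])


# --------------------------------------------------------------------------
# bootstrap
# --------------------------------------------------------------------------

@dataclass
class EffectEstimate:
    """Point estimates and bootstrap percentile CIs at the horizon month."""

    outcome: str
    estimand: str
    horizon: int
    point: dict[str, float]
    ci_lower: dict[str, float] = field(default_factory=dict)
    ci_upper: dict[str, float] = field(default_factory=dict)
    n_reps: int = 0
    n_failed: int = 0
    seed: int | None = None

    def to_row(self) -> dict:
        row: dict = {"outcome": self.outcome, "estimand": self.estimand,
                     "horizon": self.horizon, "n_reps": self.n_reps,
                     "n_failed": self.n_failed}
        for key, val in self.point.items():
            row[key] = val
            if key in self.ci_lower:
                row[f"{key}_lo"] = self.ci_lower[key]
                row[f"{key}_hi"] = self.ci_upper[key]
        return row


def resample_individuals(tables: dict[str, pd.DataFrame],
                         rng: np.random.Generator,
                         unit_table: str = "cohort") -> dict[str, pd.DataFrame]:
    """Resample individuals with replacement across linked tables.

    Each draw of a person gets a fresh person_id so that duplicated
    individuals remain distinct follow-up units in every downstream stage.
    """
    base = tables[unit_table]
    ids = base["person_id"].to_numpy()
    picked = rng.choice(ids, size=len(ids), replace=True)
    mapper = pd.DataFrame({"person_id": picked,
                           "__new_id": np.arange(1, len(ids) + 1)})
    out = {}
    for name, tbl in tables.items():
        merged = mapper.merge(tbl, on="person_id", how="inner")
        merged = merged.drop(columns="person_id").rename(
            columns={"__new_id": "person_id"})
        out[name] = merged.sort_values("person_id", kind="stable").reset_index(drop=True)
    return out


def bootstrap_effects(pipeline_fn: Callable[[dict[str, pd.DataFrame]], dict[str, float]],
                      tables: dict[str, pd.DataFrame], *,
                      n_reps: int = 500, seed: int = 0, alpha: float = 0.05,
                      outcome: str = "composite", estimand: str = "itt",
                      horizon: int = 60,
                      max_failure_fraction: float = 0.10) -> EffectEstimate:
    """Nonparametric bootstrap percentile CIs for the full estimator.

    ``pipeline_fn`` maps a dict of linked person-level tables to a dict of
    scalar estimates (e.g. ``risk_1``, ``risk_0``, ``rd``, ``rr``) and is
    re-run — weight estimation included — on every resampled replicate.
    Replicates that fail (e.g. non-convergence) are dropped and counted;
    more than ``max_failure_fraction`` failures is a hard error.
    Deterministic for a fixed seed.
    """
    point = pipeline_fn(tables)
    rng = np.random.default_rng(seed)
    reps: dict[str, list[float]] = {k: [] for k in point}
    n_failed = 0
    for _ in range(n_reps):
        resampled = resample_individuals(tables, rng)
        try:
            est = pipeline_fn(resampled)
        except Exception as exc:  # noqa: BLE001 - replicate failures are data
            n_failed += 1
            logger.warning("bootstrap replicate failed: %s", exc)
            continue
        for k in reps:
            reps[k].append(est[k])
    if n_reps > 0 and n_failed > max_failure_fraction * n_reps:
        raise RuntimeError(
            f"bootstrap unstable: {n_failed}/{n_reps} replicates failed")
    lo, hi = {}, {}
    for k, vals in reps.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[~np.isnan(arr)]
        if len(arr):
            lo[k] = float(np.percentile(arr, 100 * alpha / 2))
            hi[k] = float(np.percentile(arr, 100 * (1 - alpha / 2)))
    return EffectEstimate(outcome=outcome, estimand=estimand, horizon=horizon,
                          point={k: float(v) for k, v in point.items()},
                          ci_lower=lo, ci_upper=hi,
                          n_reps=n_reps, n_failed=n_failed, seed=seed)
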