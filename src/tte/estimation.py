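"""Person-month expansion, IP weights, pooled logistic hazards, risk curves.

The discrete-time hazard model is a pooled logistic regression on
person-month rows: for person ``i`` in month ``t``,

    logit P(Y_it = 1 | at risk) = beta_0 + beta_A A_i + f(t) + A_i * f(t) [+ L_i gamma]

where ``f`` is a restricted cubic spline in month with knots at 6, 12,
24 and 48 months by default. Cumulative incidence is the product-limit
transform ``R_a(t) = 1 - prod_{k<=t} (1 - h_a(k))``.

Confounding adjustment is by unstabilized inverse-probability-of-
treatment weights estimated from baseline covariates; the per-protocol
analysis additionally censors at strategy deviation and applies
time-varying inverse-probability-of-censoring weights, the cumulative
product within person of ``1 / P(uncensored at k | L_0, L_k, k)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from tte._logit import LogitFit, expit, newton_logistic
from tte.exceptions import ConfigError, ConvergenceError, PositivityError

logger = logging.getLogger(__name__)

DAYS_PER_MONTH = 30


# --------------------------------------------------------------------------
# restricted cubic spline basis
# --------------------------------------------------------------------------

def rcs_basis(t, knots=(6.0, 12.0, 24.0, 48.0)) -> np.ndarray:
    """Restricted (natural) cubic spline basis: linear term + K-2 nonlinear.

    With knots ``k_1 < ... < k_K`` the j-th nonlinear term (j = 1..K-2) is

        [(t-k_j)+^3 - (t-k_{K-1})+^3 (k_K-k_j)/(k_K-k_{K-1})
                    + (t-k_K)+^3 (k_{K-1}-k_j)/(k_K-k_{K-1})] / (k_K-k_1)^2

    which is linear beyond the boundary knots. The ``(k_K-k_1)^2``
    normalization keeps the nonlinear terms on roughly the scale of ``t``.
    """
    knots = np.asarray(knots, dtype=float)
    if knots.ndim != 1 or len(knots) < 3 or np.any(np.diff(knots) <= 0):
        raise ConfigError("knots must be >= 3 strictly increasing values")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    K = len(knots)
    kK, kK1, k1 = knots[-1], knots[-2], knots[0]
    norm = (kK - k1) ** 2
    cols = [t]
    for j in range(K - 2):
        kj = knots[j]
        term = (np.clip(t - kj, 0, None) ** 3
                - np.clip(t - kK1, 0, None) ** 3 * (kK - kj) / (kK - kK1)
                + np.clip(t - kK, 0, None) ** 3 * (kK1 - kj) / (kK - kK1))
        cols.append(term / norm)
    return np.column_stack(cols)


# --------------------------------------------------------------------------
# person-month expansion
# --------------------------------------------------------------------------

def _event_day_for(cohort: pd.DataFrame, outcomes: pd.DataFrame,
                   deaths: pd.DataFrame,
                   outcome: Literal["composite", "death", "mi", "hf"]) -> pd.Series:
    """First qualifying outcome day (relative to time zero) per person; NaN if none."""
    tz = cohort.set_index("person_id")["time_zero"]
    pieces = []
    if outcome in ("composite", "death") and len(deaths):
        d = deaths.merge(tz.rename("time_zero"), left_on="person_id", right_index=True)
        d["day"] = (d["death_date"] - d["time_zero"]).dt.days
        pieces.append(d[["person_id", "day"]])
    if outcome in ("composite", "mi", "hf") and len(outcomes):
        want = ("mi", "hf") if outcome == "composite" else (outcome,)
        o = outcomes[outcomes["event_type"].isin(want)].merge(
            tz.rename("time_zero"), left_on="person_id", right_index=True)
        o["day"] = (o["event_date"] - o["time_zero"]).dt.days
        pieces.append(o[["person_id", "day"]])
    if not pieces:
        return pd.Series(np.nan, index=cohort["person_id"])
    days = pd.concat(pieces)
    days = days[days["day"] > 0]  # events before/at time zero are not follow-up events
    first = days.groupby("person_id")["day"].min()
    return cohort["person_id"].map(first)


def expand_person_months(cohort: pd.DataFrame, outcomes: pd.DataFrame,
                         deaths: pd.DataFrame,
                         censor_events: pd.DataFrame | None = None,
                         *, horizon: int = 60,
                         estimand: Literal["itt", "pp"] = "itt",
                         outcome: Literal["composite", "death", "mi", "hf"] = "composite",
                         tv_events: pd.DataFrame | None = None,
                         end_of_study: str | pd.Timestamp | None = None
                         ) -> pd.DataFrame:
    """Expand the cohort to one row per person-month at risk.

    Months are numbered from 1. A person's series ends at the month of
    first event (``event = 1`` on the final row), the per-protocol
    deviation month (``pp_censor = 1``, only when ``estimand="pp"``), the
    administrative end of study, or ``horizon``, whichever is first. An
    event and a deviation in the same month resolve to the event: the
    outcome occurred while still on protocol at the start of the month.

    ``tv_events`` (optional) has columns ``person_id``, ``name``, ``day``;
    each distinct name becomes a time-varying 0/1 column ``tv_<name>``
    that switches on the month *after* the event month (covariate history
    is measured at the start of each month).
    """
    cohort = cohort.reset_index(drop=True)
    n = len(cohort)
    event_day = _event_day_for(cohort, outcomes, deaths, outcome).to_numpy(float)
    event_month = np.where(np.isnan(event_day), np.inf,
                           np.maximum(1, np.ceil(event_day / DAYS_PER_MONTH)))

    admin_month = np.full(n, float(horizon))
    if end_of_study is not None:
        avail = (pd.Timestamp(end_of_study) - cohort["time_zero"]).dt.days.to_numpy() \
            // DAYS_PER_MONTH
        admin_month = np.minimum(admin_month, np.maximum(avail, 0))

    censor_month = np.full(n, np.inf)
    if estimand == "pp":
        if censor_events is None:
            raise ConfigError("per-protocol expansion requires censor_events")
        if len(censor_events):
            cm = cohort["person_id"].map(
                censor_events.set_index("person_id")["censor_month"])
            censor_month = cm.fillna(np.inf).to_numpy(float)
    elif estimand != "itt":
        raise ConfigError(f"unknown estimand {estimand!r}")

    T = np.minimum.reduce([event_month, censor_month, admin_month]).astype(int)
    keep = T >= 1
    cohort, T = cohort.loc[keep].reset_index(drop=True), T[keep]
    event_month, censor_month = event_month[keep], censor_month[keep]

    idx = np.repeat(np.arange(len(cohort)), T)
    month = np.concatenate([np.arange(1, ti + 1) for ti in T]) if len(T) else np.array([], int)
    last = np.concatenate([np.r_[np.zeros(ti - 1, bool), True] for ti in T]) \
        if len(T) else np.array([], bool)
    ev_final = (event_month[idx] == T[idx]) & (event_month[idx] <= censor_month[idx])
    pm = cohort.iloc[idx].reset_index(drop=True)
    pm["month"] = month
    pm["event"] = (last & ev_final).astype(int)
    pm["pp_censor"] = (last & ~ev_final & (censor_month[idx] == T[idx])).astype(int)
    pm["treated"] = (pm["arm"] == "acei_arb").astype(int)

    if tv_events is not None and len(tv_events):
        first_day = tv_events.groupby(["person_id", "name"])["day"].min().unstack()
        for name in first_day.columns:
            d = pm["person_id"].map(first_day[name]).to_numpy(float)
            ev_month = np.where(np.isnan(d), np.inf,
                                np.maximum(1, np.ceil(d / DAYS_PER_MONTH)))
            pm[f"tv_{name}"] = (pm["month"].to_numpy() > ev_month).astype(int)
    return pm


# --------------------------------------------------------------------------
# model specification and design matrices
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OutcomeModelSpec:
    """Specification of the pooled logistic outcome model."""

    knots: tuple[float, ...] = (6.0, 12.0, 24.0, 48.0)
    include_treatment: bool = True
    include_interaction: bool = True
    adjustment: Literal["ipw", "covariates_in_model", "age_sex_only",
                        "unadjusted"] = "ipw"
    outcome: Literal["composite", "death", "mi", "hf"] = "composite"
    time_spec: Literal["rcs", "saturated"] = "rcs"
    covariates: tuple[str, ...] = ()
    horizon: int = 60

    def __post_init__(self) -> None:
        if self.time_spec == "rcs":
            k = np.asarray(self.knots, float)
            if len(k) < 3 or np.any(np.diff(k) <= 0):
                raise ConfigError("knots must be >= 3 strictly increasing values")
            if self.horizon < k[-1]:
                raise ConfigError("horizon must be >= last knot")


@dataclass(frozen=True)
class WeightSpec:
    """Specification of an inverse-probability weight model."""

    kind: Literal["baseline_treatment", "censoring"] = "baseline_treatment"
    covariates: tuple[str, ...] = ()
    truncation_percentile: float | None = None
    knots: tuple[float, ...] = (6.0, 12.0, 24.0, 48.0)

    def __post_init__(self) -> None:
        if self.truncation_percentile is not None and not (
                50.0 < self.truncation_percentile <= 100.0):
            raise ConfigError("truncation_percentile must be in (50, 100]")


def _covariate_design(df: pd.DataFrame, covariates: tuple[str, ...]
                      ) -> tuple[np.ndarray, list[str]]:
    """Dummy-code object columns (dropping the first level), keep numerics."""
    cols, names = [], []
    for name in covariates:
        if name not in df.columns:
            raise ConfigError(f"covariate {name!r} not in table")
        col = df[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(pd.unique(col.astype(str)))
            for lev in levels[1:]:
                cols.append((col.astype(str) == lev).to_numpy(float))
                names.append(f"{name}[{lev}]")
        else:
            vals = col.to_numpy(float)
            if np.isnan(vals).any():
                raise ConfigError(
                    f"covariate {name!r} has missing values; categorize it "
                    f"with a missing level (e.g. '{name}_cat') before modelling")
            cols.append(vals)
            names.append(name)
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return X, names


def _outcome_design(pm: pd.DataFrame, spec: OutcomeModelSpec
                    ) -> tuple[np.ndarray, list[str]]:
    t = pm["month"].to_numpy(float)
    a = pm["treated"].to_numpy(float)
    if spec.time_spec == "saturated":
        # indicator per (arm, month) cell; intercept-free
        months = np.arange(1, spec.horizon + 1)
        cols, names = [], []
        for arm in (0, 1):
            for m in months:
                cols.append(((a == arm) & (t == m)).astype(float))
                names.append(f"cell[a={arm},t={m}]")
        X = np.column_stack(cols)
        keep = X.any(axis=0)
        return X[:, keep], [n for n, k in zip(names, keep) if k]
    S = rcs_basis(t, spec.knots)
    cols = [np.ones(len(pm))]
    names = ["intercept"]
    if spec.include_treatment:
        cols.append(a)
        names.append("treated")
    for j in range(S.shape[1]):
        cols.append(S[:, j])
        names.append(f"time_s{j}")
    if spec.include_treatment and spec.include_interaction:
        for j in range(S.shape[1]):
            cols.append(a * S[:, j])
            names.append(f"treated:time_s{j}")
    if spec.adjustment in ("covariates_in_model", "age_sex_only"):
        Xc, cnames = _covariate_design(pm, spec.covariates)
        cols.extend(Xc.T)
        names.extend(cnames)
    return np.column_stack(cols), names


@dataclass
class PooledLogisticFit:
    """Fitted pooled logistic model with its design-column ledger."""

    spec: OutcomeModelSpec
    coef: pd.Series
    converged: bool
    n_iter: int
    max_score: float
    n_rows: int
    n_events: float
    arm_zero_events: tuple[int, ...] = ()
    zero_event_cells: tuple[str, ...] = ()

    def diagnostics(self) -> dict:
        return {
            "converged": self.converged,
            "n_iter": self.n_iter,
            "max_score": self.max_score,
            "n_rows": self.n_rows,
            "n_events": self.n_events,
            "arm_zero_events": list(self.arm_zero_events),
        }


def fit_pooled_logistic(pm: pd.DataFrame, spec: OutcomeModelSpec,
                        weights: np.ndarray | pd.Series | None = None,
                        *, tol: float = 1e-8, max_iter: int = 100
                        ) -> PooledLogisticFit:
    """Fit the weighted pooled logistic discrete-time hazard model.

    Raises :class:`ConvergenceError` on non-convergence (possible
    separation) rather than returning a silently bad fit. If one arm has
    zero events, arm terms are dropped and the hazard for that arm comes
    from the intercept and spline alone (with a warning).

    For the saturated time specification, (arm, month) cells with zero
    events are excluded from the design — their maximum-likelihood hazard
    is exactly zero, which the logistic parametrization can only reach in
    the limit — and recorded in the fit object.
    """
    y = pm["event"].to_numpy(float)
    if y.sum() == 0:
        raise ConfigError("no events in the person-month table")
    w = None if weights is None else np.asarray(weights, dtype=float)
    spec_used = spec
    arm_zero: tuple[int, ...] = ()
    for arm in (0, 1):
        mask = pm["treated"].to_numpy() == arm
        if mask.any() and y[mask].sum() == 0:
            arm_zero = arm_zero + (arm,)
    if arm_zero and spec.time_spec == "rcs" and spec.include_treatment:
        warnings.warn(f"arm(s) {arm_zero} have zero events; dropping treatment "
                      f"terms, hazard from intercept/spline only")
        spec_used = OutcomeModelSpec(
            knots=spec.knots, include_treatment=False, include_interaction=False,
            adjustment=spec.adjustment, outcome=spec.outcome,
            time_spec=spec.time_spec, covariates=spec.covariates,
            horizon=spec.horizon)
    X, names = _outcome_design(pm, spec_used)

    zero_cells: tuple[str, ...] = ()
    if spec_used.time_spec == "saturated":
        wy = y if w is None else w * y
        has_event = (X * wy[:, None]).sum(axis=0) > 0
        zero_cells = tuple(n for n, h in zip(names, has_event) if not h)
        X = X[:, has_event]
        names = [n for n, h in zip(names, has_event) if h]
        # the saturated design is orthogonal (disjoint indicators), so the
        # weighted MLE is exact in closed form: per-cell event fraction
        ww = np.ones(len(y)) if w is None else w
        d_cell = X.T @ (ww * y)
        n_cell = X.T @ ww
        p_cell = d_cell / n_cell
        if np.any(p_cell >= 1.0):
            raise ConvergenceError("saturated fit: a cell has event "
                                   "fraction 1 (hazard on the boundary)")
        coef = np.log(p_cell / (1.0 - p_cell))
        return PooledLogisticFit(
            spec=spec_used, coef=pd.Series(coef, index=names),
            converged=True, n_iter=0, max_score=0.0,
            n_rows=len(pm), n_events=float((ww * y).sum()),
            arm_zero_events=arm_zero, zero_event_cells=zero_cells)

    fit = newton_logistic(X, y, w, tol=tol, max_iter=max_iter)
    if not fit.converged:
        raise ConvergenceError(
            f"pooled logistic did not converge (max|score|={fit.max_score:.3g}, "
            f"{fit.n_iter} iterations"
            + ("; separation suspected)" if fit.separation_suspected else ")"))
    return PooledLogisticFit(
        spec=spec_used, coef=pd.Series(fit.coef, index=names),
        converged=fit.converged, n_iter=fit.n_iter, max_score=fit.max_score,
        n_rows=len(pm), n_events=float(y.sum() if w is None else (w * y).sum()),
        arm_zero_events=arm_zero, zero_event_cells=zero_cells)


# --------------------------------------------------------------------------
# inverse probability weights
# --------------------------------------------------------------------------

def _truncate(wts: np.ndarray, percentile: float | None) -> np.ndarray:
    if percentile is None:
        return wts
    # order-statistic cap: strictly fewer than (100 - percentile)% of
    # weights can exceed it, which an interpolated percentile cannot promise
    cap = np.percentile(wts, percentile, method="higher")
    return np.minimum(wts, cap)


def baseline_ip_weights(cohort: pd.DataFrame, spec: WeightSpec,
                        *, tol: float = 1e-8) -> tuple[pd.Series, LogitFit]:
    """Unstabilized inverse-probability-of-treatment weights.

    Fits arm ~ covariates by logistic regression; the weight is
    ``1 / p_hat`` for the treated and ``1 / (1 - p_hat)`` for the
    untreated. Optional truncation caps the pooled weight distribution at
    the configured percentile.
    """
    a = (cohort["arm"] == "acei_arb").to_numpy(float)
    Xc, names = _covariate_design(cohort, spec.covariates)
    X = np.column_stack([np.ones(len(cohort)), Xc])
    fit = newton_logistic(X, a, tol=tol)
    if not fit.converged:
        raise ConvergenceError("treatment model did not converge"
                               + (" (separation suspected)"
                                  if fit.separation_suspected else ""))
    p = fit.predict(X)
    bad = (p < 1e-10) | (p > 1 - 1e-10)
    if bad.any():
        i = int(np.argmax(bad))
        raise PositivityError(
            f"estimated treatment probability numerically 0/1 for person "
            f"{cohort['person_id'].iloc[i]}",
            pattern=cohort[list(spec.covariates)].iloc[i].to_dict())
    wts = np.where(a == 1, 1.0 / p, 1.0 / (1.0 - p))
    wts = _truncate(wts, spec.truncation_percentile)
    return pd.Series(wts, index=cohort["person_id"].to_numpy(),
                     name="baseline_weight"), fit


def censoring_weights(pm: pd.DataFrame, spec: WeightSpec,
                      *, tol: float = 1e-8) -> pd.Series:
    """Time-varying inverse-probability-of-censoring weights, per row.

    Within each arm, fits a pooled logistic model for remaining
    *uncensored* at month ``t`` given baseline (and time-varying)
    covariates and a spline in time, and returns the within-person
    cumulative product of ``1 / P(uncensored)``. Arms with no deviation
    events get weight 1. Unstabilized.
    """
    if "pp_censor" not in pm.columns:
        raise ConfigError("censoring_weights requires a per-protocol expansion")
    out = np.ones(len(pm))
    for arm in (0, 1):
        mask = (pm["treated"] == arm).to_numpy()
        sub = pm.loc[mask]
        if len(sub) == 0 or sub["pp_censor"].sum() == 0:
            continue
        uncens = 1.0 - sub["pp_censor"].to_numpy(float)
        S = rcs_basis(sub["month"].to_numpy(float), spec.knots)
        Xc, _ = _covariate_design(sub, spec.covariates)
        X = np.column_stack([np.ones(len(sub)), S, Xc])
        fit = newton_logistic(X, uncens, tol=tol)
        if not fit.converged:
            raise ConvergenceError(f"censoring model (arm={arm}) did not converge")
        p = fit.predict(X)
        if np.any(p < 1e-10):
            t_bad = int(sub["month"].to_numpy()[np.argmin(p)])
            raise PositivityError(
                f"P(uncensored) numerically 0 in arm {arm} at month {t_bad}",
                pattern={"arm": arm, "month": t_bad})
        contrib = np.ones(len(sub))
        contrib[:] = 1.0 / p
        cum = (pd.Series(np.log(contrib), index=sub.index)
               .groupby(sub["person_id"].to_numpy()).cumsum())
        out[mask] = np.exp(cum.to_numpy())
    return pd.Series(out, index=pm.index, name="censoring_weight")


def combine_weights(pm: pd.DataFrame, baseline: pd.Series | None,
                    censoring: pd.Series | None,
                    truncation_percentile: float | None = None) -> np.ndarray:
    """Final analysis weight: baseline x censoring, optionally truncated."""
    w = np.ones(len(pm))
    if baseline is not None:
        w = w * pm["person_id"].map(baseline).to_numpy(float)
    if censoring is not None:
        w = w * np.asarray(censoring, dtype=float)
    return _truncate(w, truncation_percentile)


# --------------------------------------------------------------------------
# risk curves
# --------------------------------------------------------------------------

@dataclass
class RiskCurve:
    """Per-arm monthly hazards and cumulative incidence, with RD and RR."""

    frame: pd.DataFrame  # month, hazard_1, hazard_0, risk_1, risk_0, rd, rr
    method: str = "pooled_logistic"

    @classmethod
    def from_hazards(cls, months: np.ndarray, h1: np.ndarray, h0: np.ndarray,
                     method: str) -> "RiskCurve":
        r1 = 1.0 - np.cumprod(1.0 - h1)
        r0 = 1.0 - np.cumprod(1.0 - h0)
        with np.errstate(divide="ignore", invalid="ignore"):
            rr = np.where(r0 > 0, r1 / r0, np.nan)
        frame = pd.DataFrame({
            "month": months, "hazard_1": h1, "hazard_0": h0,
            "risk_1": r1, "risk_0": r0, "rd": r1 - r0, "rr": rr,
        })
        return cls(frame, method)

    def at(self, month: int) -> pd.Series:
        return self.frame.set_index("month").loc[month]

    def risk(self, arm: int, month: int) -> float:
        return float(self.at(month)[f"risk_{arm}"])

    def rd(self, month: int) -> float:
        return float(self.at(month)["rd"])

    def rr(self, month: int) -> float:
        return float(self.at(month)["rr"])


def _predict_hazard(fit: PooledLogisticFit, arm: int, months: np.ndarray,
                    cov_row: pd.Series | None = None) -> np.ndarray:
    spec = fit.spec
    if spec.time_spec == "saturated":
        h = np.zeros(len(months))
        for i, m in enumerate(months):
            name = f"cell[a={arm},t={int(m)}]"
            h[i] = expit(np.array([fit.coef[name]]))[0] if name in fit.coef.index else 0.0
        return h
    S = rcs_basis(months.astype(float), spec.knots)
    eta = np.zeros(len(months))
    for name, beta in fit.coef.items():
        if name == "intercept":
            eta += beta
        elif name == "treated":
            eta += beta * arm
        elif name.startswith("treated:time_s"):
            j = int(name.rsplit("s", 1)[1])
            eta += beta * arm * S[:, j]
        elif name.startswith("time_s"):
            j = int(name.rsplit("s", 1)[1])
            eta += beta * S[:, j]
        else:
            if cov_row is None:
                raise ConfigError(
                    f"model term {name!r} needs covariate values; risks under "
                    f"covariates_in_model must be standardized over the cohort")
            eta += beta * cov_row[name]
    return expit(eta)


def estimate_risk_curves(pm: pd.DataFrame, spec: OutcomeModelSpec,
                         weights: np.ndarray | pd.Series | None = None,
                         *, fit: PooledLogisticFit | None = None,
                         cohort: pd.DataFrame | None = None,
                         tol: float | None = None) -> RiskCurve:
    """Fit the outcome model (unless given) and produce the risk curve.

    Under IP weighting the weighted population is exchangeable, so the
    marginal hazards are read directly off the arm + time model. In
    ``covariates_in_model`` mode risks are standardized: predicted
    per-person cumulative incidences under each counterfactual arm are
    averaged over the cohort's covariate distribution (g-computation).
    """
    if fit is None:
        if tol is None:
            # the saturated design is orthogonal, so Newton's final
            # polishing step squares the score-implied error: a 1e-9
            # score tolerance leaves hazards exact to machine precision
            tol = 1e-9 if spec.time_spec == "saturated" else 1e-8
        fit = fit_pooled_logistic(pm, spec, weights, tol=tol)
    months = np.arange(1, spec.horizon + 1)
    if fit.spec.adjustment in ("covariates_in_model", "age_sex_only") \
            and fit.spec.covariates:
        if cohort is None:
            cohort = pm.drop_duplicates("person_id")
        Xc, cnames = _covariate_design(cohort, fit.spec.covariates)
        cov_coef = np.array([fit.coef.get(n, 0.0) for n in cnames])
        eta_cov = Xc @ cov_coef
        S = rcs_basis(months.astype(float), fit.spec.knots)
        base = np.full(len(months), fit.coef.get("intercept", 0.0))
        for name, beta in fit.coef.items():
            if name.startswith("time_s") and ":" not in name:
                base += beta * S[:, int(name.rsplit("s", 1)[1])]
        curves = {}
        for arm in (0, 1):
            eta_t = base.copy()
            if "treated" in fit.coef.index:
                eta_t = eta_t + fit.coef["treated"] * arm
            for name, beta in fit.coef.items():
                if name.startswith("treated:time_s"):
                    eta_t = eta_t + beta * arm * S[:, int(name.rsplit("s", 1)[1])]
            # person x month hazards, survival product over months
            h = expit(eta_cov[:, None] + eta_t[None, :])
            risks = 1.0 - np.cumprod(1.0 - h, axis=1)
            curves[arm] = risks.mean(axis=0)
        r1, r0 = curves[1], curves[0]
        h1 = np.empty_like(r1)
        h0 = np.empty_like(r0)
        h1[0], h0[0] = r1[0], r0[0]
        h1[1:] = 1 - (1 - r1[1:]) / (1 - r1[:-1])
        h0[1:] = 1 - (1 - r0[1:]) / (1 - r0[:-1])
        return RiskCurve.from_hazards(months, h1, h0, "pooled_logistic_standardized")
    h1 = _predict_hazard(fit, 1, months)
    h0 = _predict_hazard(fit, 0, months)
    return RiskCurve.from_hazards(months, h1, h0, "pooled_logistic")


def km_curve(pm: pd.DataFrame, weights: np.ndarray | pd.Series | None = None,
             *, horizon: int = 60) -> RiskCurve:
    """Discrete product-limit (Kaplan-Meier) estimator on the monthly grid.

    Supports weights via weighted risk-set and event sums. Raises if an
    arm has no person-months.
    """
    w = np.ones(len(pm)) if weights is None else np.asarray(weights, dtype=float)
    months = np.arange(1, horizon + 1)
    hz = {}
    for arm in (0, 1):
        mask = (pm["treated"] == arm).to_numpy()
        if not mask.any():
            raise ValueError(f"km_curve: no person-months in arm {arm}")
        sub_m = pm.loc[mask, "month"].to_numpy()
        sub_y = pm.loc[mask, "event"].to_numpy(float)
        sub_w = w[mask]
        n_t = np.bincount(sub_m, weights=sub_w, minlength=horizon + 1)[1:horizon + 1]
        d_t = np.bincount(sub_m, weights=sub_w * sub_y, minlength=horizon + 1)[1:horizon + 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(n_t > 0, d_t / np.where(n_t > 0, n_t, 1.0), 0.0)
        hz[arm] = h
    return RiskCurve.from_hazards(months, hz[1], hz[0], "kaplan_meier")
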