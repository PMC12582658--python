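"""Spline basis, person-month expansion, pooled logistic fits, IP weights,
and risk-curve estimators, each checked against an independent oracle."""

import numpy as np
import pandas as pd
import pytest

from tte.estimation import (
    OutcomeModelSpec,
    WeightSpec,
    baseline_ip_weights,
    censoring_weights,
    combine_weights,
    estimate_risk_curves,
    expand_person_months,
    fit_pooled_logistic,
    km_curve,
    rcs_basis,
)
from tte.exceptions import ConfigError
from tte.adherence import censor_events_for_cohort
from tte.reporting import balance_table


class TestSplineBasis:
    def test_below_first_knot_only_linear_term(self):
        basis = rcs_basis([3.0], knots=(6, 12, 24, 48))
        assert basis.tolist() == [[3.0, 0.0, 0.0]]

    def test_hand_evaluated_value_at_24(self):
        # (24-6)^3 / (48-6)^2 = 5832/1764
        basis = rcs_basis([24.0], knots=(6, 12, 24, 48))
        assert basis[0, 1] == pytest.approx(5832 / 1764, rel=1e-12)
        assert basis[0, 2] == pytest.approx((24 - 12) ** 3 / 1764, rel=1e-12)

    def test_linearity_beyond_last_knot(self):
        b = rcs_basis([50.0, 55.0, 60.0], knots=(6, 12, 24, 48))
        for j in range(1, b.shape[1]):
            assert b[1, j] == pytest.approx((b[0, j] + b[2, j]) / 2, rel=1e-10)

    def test_nonincreasing_knots_rejected(self):
        with pytest.raises(ConfigError, match="knots"):
            rcs_basis([1.0], knots=(6, 6, 24))


def _one_person_cohort(event_day=None):
    cohort = pd.DataFrame({
        "person_id": [1], "arm": ["acei_arb"],
        "time_zero": [pd.Timestamp("2015-01-31")],
    })
    deaths = pd.DataFrame({
        "person_id": [1],
        "death_date": [cohort["time_zero"][0] + pd.Timedelta(days=event_day)],
    }) if event_day is not None else pd.DataFrame(columns=["person_id", "death_date"])
    outcomes = pd.DataFrame(columns=["person_id", "event_type", "event_date"])
    return cohort, outcomes, deaths


class TestExpansion:
    def test_event_at_day_40_gives_two_rows(self):
        cohort, outcomes, deaths = _one_person_cohort(event_day=40)
        pm = expand_person_months(cohort, outcomes, deaths)
        assert len(pm) == 2
        assert pm["event"].tolist() == [0, 1]
        assert pm["month"].tolist() == [1, 2]

    def test_full_follow_up_gives_60_event_free_rows(self):
        cohort, outcomes, deaths = _one_person_cohort()
        pm = expand_person_months(cohort, outcomes, deaths)
        assert len(pm) == 60
        assert pm["event"].sum() == 0

    def test_event_and_deviation_in_same_month_resolves_to_event(self):
        cohort, outcomes, deaths = _one_person_cohort(event_day=40)
        ce = pd.DataFrame({"person_id": [1], "censor_day": [55],
                           "censor_month": [2], "reason": ["stopped_treatment"]})
        pm = expand_person_months(cohort, outcomes, deaths, ce, estimand="pp")
        assert pm["event"].tolist() == [0, 1]
        assert pm["pp_censor"].sum() == 0

    def test_total_person_months_match_direct_scan(self, small_bundle,
                                                   small_cohort):
        cohort, _ = small_cohort
        ce = censor_events_for_cohort(cohort, small_bundle.dispensations,
                                      small_bundle.diagnoses)
        pm = expand_person_months(cohort, small_bundle.outcomes,
                                  small_bundle.deaths, ce, estimand="pp")
        # independent per-person scan over the raw tables
        truth = small_bundle.truth.set_index("person_id")
        cm = ce.set_index("person_id")["censor_month"]
        total = 0
        for pid in cohort["person_id"]:
            e = truth.loc[pid, "event_month"]
            e = 61 if e == 0 else e
            c = int(cm.get(pid, 61))
            total += min(e, c if c < e else e, 60) if False else min(e, c, 60)
        assert len(pm) == total

    def test_tv_flag_switches_on_after_event_month(self):
        cohort, outcomes, deaths = _one_person_cohort()
        tv = pd.DataFrame({"person_id": [1], "name": ["renal"], "day": [100]})
        pm = expand_person_months(cohort, outcomes, deaths, tv_events=tv)
        # day 100 falls in month 4; history flag is on from month 5
        assert pm.loc[pm["month"] <= 4, "tv_renal"].sum() == 0
        assert (pm.loc[pm["month"] >= 5, "tv_renal"] == 1).all()


def _toy_pm(n=200, seed=0, p_event=0.2):
    rng = np.random.default_rng(seed)
    pm = pd.DataFrame({
        "person_id": np.arange(n),
        "month": rng.integers(1, 61, size=n).astype(float),
        "treated": rng.integers(0, 2, size=n),
        "x": rng.normal(size=n),
        "event": rng.binomial(1, p_event, size=n),
    })
    pm["arm"] = np.where(pm["treated"] == 1, "acei_arb", "none")
    return pm


class TestPooledLogistic:
    def test_intercept_only_mle_is_logit_of_event_rate(self):
        pm = _toy_pm(400, seed=1)
        spec = OutcomeModelSpec(include_treatment=False, include_interaction=False)
        # strip time terms by fitting on a constant-month table
        pm["month"] = 1.0
        fit = fit_pooled_logistic(pm, spec)
        e, N = pm["event"].sum(), len(pm)
        # intercept + spline(1)-terms at t=1: only the linear term is
        # nonzero, so intercept + coef*1 = logit(e/N)
        eta = fit.coef["intercept"] + fit.coef["time_s0"] * 1.0
        assert eta == pytest.approx(np.log(e / (N - e)), abs=1e-6)

    def test_duplicating_rows_leaves_coefficients_unchanged(self):
        pm = _toy_pm(300, seed=2)
        spec = OutcomeModelSpec()
        f1 = fit_pooled_logistic(pm, spec)
        f2 = fit_pooled_logistic(pd.concat([pm, pm], ignore_index=True), spec)
        assert np.allclose(f1.coef.to_numpy(), f2.coef.to_numpy(), atol=1e-8)

    def test_weighted_fit_matches_statsmodels(self):
        import statsmodels.api as sm
        pm = _toy_pm(200, seed=3)
        w = np.random.default_rng(4).uniform(0.5, 3.0, size=len(pm))
        spec = OutcomeModelSpec()
        fit = fit_pooled_logistic(pm, spec, w)
        from tte.estimation import _outcome_design
        X, names = _outcome_design(pm, spec)
        ref = sm.GLM(pm["event"].to_numpy(), X,
                     family=sm.families.Binomial(), freq_weights=w).fit()
        assert np.allclose(fit.coef.to_numpy(), ref.params, atol=1e-6)

    def test_zero_event_arm_drops_treatment_terms_with_warning(self):
        pm = _toy_pm(300, seed=5)
        pm.loc[pm["treated"] == 1, "event"] = 0
        pm.loc[pm["treated"] == 0, "event"] = np.random.default_rng(0).binomial(
            1, 0.3, size=(pm["treated"] == 0).sum())
        with pytest.warns(UserWarning, match="zero events"):
            fit = fit_pooled_logistic(pm, OutcomeModelSpec())
        assert "treated" not in fit.coef.index


class TestBaselineWeights:
    def test_saturated_model_satisfies_horvitz_thompson_identity(self):
        rng = np.random.default_rng(6)
        n = 1000
        x = rng.integers(0, 2, size=n)
        p = np.where(x == 1, 0.7, 0.4)
        arm = np.where(rng.random(n) < p, "acei_arb", "none")
        cohort = pd.DataFrame({"person_id": np.arange(n), "arm": arm,
                               "x": x.astype(float)})
        w, _ = baseline_ip_weights(cohort, WeightSpec(covariates=("x",)))
        treated = cohort["arm"].to_numpy() == "acei_arb"
        assert w.to_numpy()[treated].sum() == pytest.approx(n, rel=1e-6)
        assert w.to_numpy()[~treated].sum() == pytest.approx(n, rel=1e-6)

    def test_randomized_assignment_gives_weights_near_two(self):
        rng = np.random.default_rng(7)
        n = 4000
        cohort = pd.DataFrame({
            "person_id": np.arange(n),
            "arm": np.where(rng.random(n) < 0.5, "acei_arb", "none"),
            "x": rng.normal(size=n)})
        w, _ = baseline_ip_weights(cohort, WeightSpec(covariates=("x",)))
        assert np.abs(w.to_numpy() - 2.0).max() < 0.4

    def test_truncation_alters_at_most_one_percent_of_weights(self, small_cohort):
        cohort, _ = small_cohort
        covs = ("age", "female", "nstemi", "sbp", "egfr", "ldl")
        w_raw, _ = baseline_ip_weights(cohort, WeightSpec(covariates=covs))
        w_tr, _ = baseline_ip_weights(
            cohort, WeightSpec(covariates=covs, truncation_percentile=99.0))
        changed = (w_raw.to_numpy() != w_tr.to_numpy()).mean()
        assert changed <= 0.01 + 1e-12
        assert (w_tr > 0).all()


class TestCensoringWeights:
    def test_no_deviations_give_unit_weights(self):
        pm = _toy_pm(100, seed=8)
        pm["pp_censor"] = 0
        w = censoring_weights(pm, WeightSpec(kind="censoring"))
        assert (w == 1.0).all()

    def test_constant_censoring_hazard_gives_geometric_weights(self):
        # 10% monthly censoring, independent of covariates: weight at
        # month t approx (1/0.9)^t
        rng = np.random.default_rng(9)
        n = 4000
        cm = rng.geometric(0.10, size=n)
        rows = []
        for pid, c in enumerate(cm):
            last = min(c, 24)
            for t in range(1, last + 1):
                rows.append((pid, t, 1, int(t == c)))
        pm = pd.DataFrame(rows, columns=["person_id", "month", "treated",
                                         "pp_censor"])
        pm["event"] = 0
        w = censoring_weights(pm, WeightSpec(kind="censoring",
                                             knots=(3.0, 8.0, 16.0)))
        for t in (1, 6, 12, 24):
            rows_t = (pm["month"] == t) & (pm["pp_censor"] == 0)
            got = w[rows_t].mean()
            assert got == pytest.approx((1 / 0.9) ** t, rel=0.06)


class TestRiskCurves:
    def test_hand_product_limit(self):
        # 4 persons: events in months 1 and 3 -> R(3) = 1 - (3/4)(2/3) = 1/2
        rows = []
        rows += [(1, 1, 1, 1)]
        rows += [(2, t, 1, 1 if t == 3 else 0) for t in (1, 2, 3)]
        for pid in (3, 4):
            rows += [(pid, t, 1, 0) for t in range(1, 61)]
        pm = pd.DataFrame(rows, columns=["person_id", "month", "treated", "event"])
        pm0 = pm.copy()
        pm0["treated"] = 0
        curve = km_curve(pd.concat([pm, pm0]), horizon=60)
        assert curve.risk(1, 3) == pytest.approx(0.5, abs=1e-12)

    def test_no_events_give_zero_risk(self):
        pm = pd.DataFrame({"person_id": [1, 2], "month": [1, 1],
                           "treated": [1, 0], "event": [0, 0]})
        curve = km_curve(pm, horizon=1)
        assert curve.risk(1, 1) == 0.0 and curve.risk(0, 1) == 0.0

    def test_km_matches_lifelines(self, small_bundle, small_cohort):
        from lifelines import KaplanMeierFitter
        cohort, _ = small_cohort
        pm = expand_person_months(cohort, small_bundle.outcomes,
                                  small_bundle.deaths)
        curve = km_curve(pm)
        last = pm.groupby("person_id").tail(1)
        for arm in (0, 1):
            sub = last[last["treated"] == arm]
            kmf = KaplanMeierFitter().fit(sub["month"], sub["event"])
            for t in (6, 24, 60):
                ours = 1.0 - curve.risk(arm, t)
                ref = float(kmf.survival_function_at_times(t).iloc[0])
                assert ours == pytest.approx(ref, abs=1e-10)

    def test_saturated_pooled_logistic_equals_km(self, small_bundle, small_cohort):
        cohort, _ = small_cohort
        pm = expand_person_months(cohort, small_bundle.outcomes,
                                  small_bundle.deaths)
        km = km_curve(pm)
        sat = estimate_risk_curves(pm, OutcomeModelSpec(time_spec="saturated"))
        diff = np.abs(sat.frame[["risk_1", "risk_0"]].to_numpy()
                      - km.frame[["risk_1", "risk_0"]].to_numpy())
        assert diff.max() < 1e-12

    def test_risk_curves_are_monotone_and_bounded(self, small_bundle,
                                                  small_cohort):
        cohort, _ = small_cohort
        pm = expand_person_months(cohort, small_bundle.outcomes,
                                  small_bundle.deaths)
        covs = ("age", "female", "nstemi", "sbp", "egfr", "ldl")
        w, _ = baseline_ip_weights(cohort, WeightSpec(covariates=covs))
        curve = estimate_risk_curves(pm, OutcomeModelSpec(),
                                     combine_weights(pm, w, None))
        for col in ("risk_1", "risk_0"):
            r = curve.frame[col].to_numpy()
            assert (np.diff(r) >= -1e-15).all()
            assert ((r >= 0) & (r <= 1)).all()

    def test_fitted_log_hazard_linear_beyond_last_knot(self, small_bundle,
                                                       small_cohort):
        cohort, _ = small_cohort
        pm = expand_person_months(cohort, small_bundle.outcomes,
                                  small_bundle.deaths)
        curve = estimate_risk_curves(pm, OutcomeModelSpec())
        h = curve.frame.query("month >= 49")["hazard_0"].to_numpy()
        logit_h = np.log(h / (1 - h))
        second_diff = np.diff(logit_h, n=2)
        assert np.abs(second_diff).max() < 1e-8

    def test_standardized_risks_under_covariates_in_model(self, small_bundle,
                                                          small_cohort):
        cohort, _ = small_cohort
        pm = expand_person_months(cohort, small_bundle.outcomes,
                                  small_bundle.deaths)
        spec = OutcomeModelSpec(adjustment="covariates_in_model",
                                covariates=("age", "nstemi"))
        curve = estimate_risk_curves(pm, spec, cohort=cohort)
        r = curve.frame
        assert ((r["risk_1"] >= 0) & (r["risk_1"] <= 1)).all()
        assert (np.diff(r["risk_1"]) >= -1e-15).all()


class TestBalanceProperty:
    def test_ipw_balances_generator_confounders(self, small_cohort):
        cohort, _ = small_cohort
        covs = ("age", "female", "nstemi", "sbp", "egfr", "ldl")
        bal_un = balance_table(cohort, None, list(covs))
        w, _ = baseline_ip_weights(cohort, WeightSpec(covariates=covs))
        bal_w = balance_table(cohort, w, list(covs))
        un = bal_un.set_index("covariate")["smd"]
        wt = bal_w.set_index("covariate")["smd_weighted"]
        assert (un[["nstemi", "sbp"]] > 0.2).all()  # confounded by design
        assert (wt[list(covs)] < 0.1).all()
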