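# Methods

## Design

The pipeline emulates a two-arm pragmatic trial from linked
registry-style tables. Eligibility, strategy assignment and the start of
follow-up are aligned at a single time zero — admission date plus the
30-day assignment window — for both arms, so neither arm accrues
immortal time while prescriptions are being filled. An alternative
convention (time zero at the assignment date for the treated arm) is
available via `EligibilitySpec(time_zero_mode="assignment")` for
sensitivity analyses of this choice; the landmark is the default because
a common anchor is the only convention that is symmetric across arms.

Follow-up time is discretized in 30-day blocks ("months"), month `t`
covering days `(30(t−1), 30t]` after time zero. Sixty months cover the
5-year horizon and put the hazard-spline knots (6, 12, 24, 48) on a
round grid. Follow-up ends at the first of: outcome, per-protocol
deviation (per-protocol analysis only), an optional administrative
end-of-study date, or the horizon.

## Eligibility and assignment

Criteria are applied in their declared order (recruitment window; age 18
to <75; LVEF ≥ 50%; standard MI care — angiography plus statin and
antithrombotic dispensations in the assignment window; working, retired
or studying; no contraindication — eGFR < 15, hypotension, renal artery
stenosis; no existing indication — hypertension, heart failure, diabetes,
chronic kidney disease — and no prior study-drug use; no dementia or
metastatic cancer), each person counted under the first criterion they
fail. Permuting the order moves persons between flowchart rows but can
never change the final eligible set, which the tests assert via the
generator's violation labels.

Diagnosis lookback is `(admission − 3 years, admission]` in any setting
and any diagnosis position. The dispensation lookback for prior use is
`[admission − 3 years, admission)`, exclusive of the admission day:
study-drug dispensations from the admission day onward constitute
treatment assignment, not history, and must not disqualify the person
they assign.

Arm is `acei_arb` iff any dispensation with an ATC prefix in
C09A/C09B/C09C/C09D falls within 30 days of admission (inclusive).

## Adherence episodes and per-protocol censoring

Each dispensation covers `pill_count` days at one pill per day (dosage
is not observed; a fixed-90-day variant is available as
`mode="fixed_90"`). Overlapping supplies stockpile: coverage extends
from the end of the previous supply. Coverage windows merge into one
continuous-treatment episode when the gap from coverage end to the next
dispensation is strictly less than the grace period (90 days; 180 as a
sensitivity variant), so total covered days always equal total pills.

Per-protocol deviation is placed at the first day non-adherence is
*established*: coverage end + grace in the treated arm (within the grace
window the person could still have redeemed the strategy), the first
post-baseline study-drug dispensation in the untreated arm. A
contraindication diagnosis (hypotension, renal artery stenosis) on or
before the lapse excuses discontinuation; a new indication
(hypertension; additionally heart failure when the outcome is death or
MI) excuses initiation. Switching between ACEi and ARB is
adherence-neutral. Whether continued treatment after a contraindication
should itself count as deviation is left configurable downstream; here
it is protocol-consistent.

## Estimation

The outcome model is a weighted pooled logistic regression on
person-month rows: intercept, assigned-strategy indicator, restricted
cubic spline in month, and strategy × spline product terms. The spline
basis uses the standard truncated-power natural-spline construction with
a `(k_K − k_1)²` normalization; any full-rank basis yields identical
fitted hazards, so this is a reproducibility convention only. Fitting is
by Newton-Raphson on the weighted Bernoulli likelihood with unit-RMS
column scaling, step-halving, a convergence criterion of max |score|
< 1e-8 and one polishing step past the tolerance; non-convergence raises
rather than returning silently. With the saturated (indicator-per-month)
time specification the design is orthogonal and the weighted MLE is
computed in its exact closed form (per-cell weighted event fraction);
cells with zero events have their hazard exactly at the boundary value 0
and are reported in the fit diagnostics. This makes the saturated fit
agree with the weighted product-limit (Kaplan–Meier) estimator to
machine precision, which the tests assert at 1e-12.

Treatment weights are unstabilized `1/P(A = a | L)` from a logistic
model on baseline covariates; estimated probabilities numerically at 0
or 1 raise a positivity error carrying the offending covariate pattern.
Censoring weights are fitted per arm: a pooled logistic model of
remaining uncensored on the spline of month plus baseline (and any
time-varying) covariates, cumulated within person as
`Π_{k≤t} 1/P(uncensored at k)`. The deviation-month row feeds the
censoring model only; the outcome model sees person-months uncensored at
the start of the interval. The final analysis weight is the product of
the two, optionally truncated at a percentile of the pooled distribution
(the cap is an order statistic, so a 99th-percentile truncation can
never alter more than 1% of weights). Administrative censoring is
treated as non-informative and receives no weights.

Under IP weighting the marginal risks are read directly off the
arm + time model — the weighted population is exchangeable, so no
further standardization is needed. In `covariates_in_model` mode
(a sensitivity analysis replacing weights with covariates in the outcome
model) risks are standardized by g-computation: per-person cumulative
incidences are predicted under both counterfactual arms and averaged
over the cohort's covariate distribution. Risk ratios are reported only
at months where the reference risk is positive.

Missing baseline covariates are handled by categorization with an
explicit `missing` level (continuous covariates are cut at configurable
points and keep their raw values alongside); design construction refuses
raw covariates containing NaN rather than guessing.

Bootstrap confidence intervals are percentile intervals over
`n_reps = 500` resamples of individuals (each draw receives a fresh id,
so duplicated persons remain distinct follow-up units); every weight
model is re-estimated inside each replicate. Replicates that fail — for
example separation in a resampled weight model — are dropped and
counted; more than 10% failures aborts the estimate as unstable.

## The synthetic registry

The generator emulates the structure the analysis assumes, not any
particular population: baseline covariates (age, sex, infarction type,
systolic blood pressure, eGFR, LDL by default) with configurable
distributions; treatment assignment by a logistic model on standardized
covariates (default intercept 0.8 with coefficients on infarction type,
blood pressure and age, giving a ~69/31 split and unweighted SMDs around
0.15–0.32 on the confounders); a monthly outcome logit of −6.5 at the
covariate means (≈9% 5-year risk) with covariate effects and an optional
polynomial time trend; a default treatment effect of 0 on the monthly
log-odds (the estimated effect in this clinical setting is null — tests
set nonzero values explicitly); geometric stopping and crossover with
monthly logits −4.33 and −5.55, calibrated so that roughly 46% of the
treated arm is adherent and 79% of the untreated arm has never crossed
over at 5 years; independent monthly indication (0.003) and
contraindication (0.001) processes; MCAR missingness defaulting to 11%
of LDL and 2.3% of eGFR values; and optional per-rule fractions of
persons constructed to violate eligibility, recorded in the truth table
for flowchart tests.

Randomness is split per person (`SeedSequence([seed, person_id])`), a
stronger guarantee than per-table streams: enlarging the cohort never
perturbs existing persons' draws, and the truth table makes every latent
label (assignment, stop/crossover month, deviation day, event month)
available to tests.

One modelling choice matters for what the per-protocol estimator can
recover. A treated stopper's outcome-hazard exposure runs until the
per-protocol deviation day (coverage end + grace), not until the last
refill: dispensed pills continue to be consumed after the final refill,
and the strategy is only provably abandoned when the 90-day gap closes.
This aligns the exposure switch with the censoring time, which is
exactly the condition under which inverse-probability-of-censoring
weighting identifies the full-adherence counterfactual risk. Had
exposure ended at the refill boundary, the uncensored grace months would
carry off-treatment hazard that no censoring weight can correct, and the
per-protocol estimand would be systematically unattainable — a property
of the convention, not of the estimator.

`true_marginal_risk` computes counterfactual risks by Monte Carlo over
the covariate distribution only; given covariates the risk is the exact
product `1 − Π(1 − h_t)`, so its standard error is bounded by
`sqrt(0.25/n_mc)` and in practice far smaller.

What the generator does **not** emulate: realistic code dictionaries
(reduced to single representative ICD-10/ATC codes per concept),
clinically calibrated covariate joint distributions, informative (MNAR)
missingness, hazard-linked indication processes, or dose titration.
Passing tests therefore demonstrate the estimators' statistical
correctness under a known process, not the clinical validity of any
particular registry analysis.

## Test and validation scales

The statistical acceptance checks run at sizes chosen to keep the full
suite under a few minutes while leaving each question answerable:
confounding-recovery at n = 20 000 (unadjusted bias > 3 SE, IPW estimate
within 3 SE of zero, with SE computed from the Kish effective sample
size of the baseline weights); per-protocol recovery at n = 20 000 with
stopping strongly linked to a strong hazard covariate (logit −4.6 + 1.6
× NSTEMI), a scenario chosen to make selection bias large relative to
its SE while preserving positivity — about 6% of the high-stopping
stratum remains uncensored at 5 years; and bootstrap coverage with 200
replicates across 50 simulation seeds at n = 800 over a 24-month
horizon, compared with the nominal 95% within binomial error. The
"3 Monte-Carlo SE" yardstick uses the estimator's sampling SE via Kish
effective sample sizes plus the oracle's (negligible) MC SE.

## Known limitations

- The weighted product-limit and weighted pooled-logistic risk estimates
  carry finite-sample ratio bias under heavy cumulative censoring
  weights (observed ≈ +0.01 at n ≈ 12 000 in a strong-selection
  scenario, shrinking like 1/ESS); truncation trades this against
  residual confounding.
- Competing risks are not modelled: death both is part of the composite
  outcome and truncates the non-fatal outcomes; sensitivity analyses
  censoring at death are out of scope.
- The censoring model shares the outcome model's spline-of-time terms;
  a lumpy true censoring hazard (refill arithmetic) is only
  approximated, though a saturated-time check showed no material
  difference.
- Continuous-time (Cox) modelling, MNAR missingness and multiple-testing
  adjustment across subgroups are deliberately out of scope.
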