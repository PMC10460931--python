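# Methods

## Scope and model

The package externally validates published logistic prognostic scores for
pediatric in-hospital mortality. A score is a fixed equation
lp = β₀ + Σ βᵢXᵢ with published intercept and weights on the log-odds
scale; predicted risk is logistic(lp). Nothing is refit: validation asks how
well the frozen equation discriminates and how well its risks agree with
observed mortality in a new cohort. The built-in registry carries the four
published equations exactly as printed; weights labelled "odds ratios" in
the source table are stored as the additive log-odds coefficients the
equations actually use.

One unit choice deserves note: the MUAC weight (−0.03) in the two
MUAC-based infection models is interpreted per millimetre. Per centimetre
the baseline risk of a well-nourished child (MUAC ≈ 14.3 cm) would be
logistic(−0.523 − 0.03·14.3) ≈ 0.28 — clinically absurd — while per-mm
values give sensible risks across the observed 115–160 mm range. All MUAC
handling in the package is in mm.

## Cohort construction

General exclusions (burns, poisonings, trauma, strike-period admissions,
healthy children accompanying sick babies) are applied before any
model-specific rule. Eligibility then follows the derivation studies:

- pneumonia cohort: age 2–59 months, cough or difficulty breathing, and at
  least one danger sign (central cyanosis, grunting, chest indrawing,
  stridor, inability to drink, convulsion) or AVPU of P/U. A sensitivity
  mode replaces the danger-sign definition with the clinical pneumonia
  diagnosis.
- infection cohort: age 6–60 months with proven or suspected infection,
  excluding diagnosed malnutrition, readmissions, cancer, heart conditions
  and non-infectious illness.

Encoding thresholds: moderate hypoxemia 90 ≤ SpO2 ≤ 92, severe < 90;
moderate malnutrition 115 ≤ MUAC ≤ 135 mm (boundaries inclusive on the
moderate side), severe < 115 mm; unconscious = AVPU P or U; abnormal
Blantyre coma score < 5, with an optional AVPU = V proxy used where the coma
score is not collected. Convulsion counts as a danger sign (the inclusion
table lists it even though one prose passage omits it). Predictors derived
from a missing source field are reported as missing rather than silently
zero-filled.

Case-fatality percentages in cohort summaries are rounded to one decimal,
half away from zero, matching how such tables are printed.

## Discrimination and calibration

The c-statistic is computed from midranks in O(n log n), ties counting 1/2;
for n ≤ 200 it equals brute-force pair enumeration exactly (tested). Bands:
≥0.90 excellent, 0.80–0.89 good, 0.70–0.79 fair, <0.70 poor.

Calibration-in-the-large is the intercept of logit P(y=1) = a + lp with the
linear predictor entering as a fixed-slope offset. The estimating equation
for the published analyses is not stated in the source; the offset
formulation is the standard one and matches the reference-value semantics
(0 = calibrated, >0 = underestimation). The calibration slope is the free
slope b of logit P(y=1) = a + b·lp.

The flexible calibration curve fits logit P(y=1) = f(logit(risk)) with f a
restricted cubic spline: 5 knots at the 5/27.5/50/72.5/95th percentiles of
logit(risk), dropping to 3 knots (10/50/90) below 100 events. Risks are
clipped to [1e-12, 1 − 1e-12] before the logit so degenerate 0/1 inputs
stay finite. The spline basis is standardized before fitting; indicator-only
models produce few distinct risks and a nearly collinear basis whose raw
coefficients are legitimately large.

All three fits share one IRLS (damped Newton) engine with offset support:
convergence when the maximum absolute score falls below 1e-8 or the
relative deviance change below 1e-10, at most 100 iterations, with step
halving when a full Newton step would increase the deviance. Separation is
reported as non-convergence (with the iteration trace) when the fitted
log-odds diverge or the deviance vanishes — a perfect fit of binary
outcomes. A coefficient-magnitude cutoff was deliberately not used as the
separation test because collinear spline bases produce legitimately large
coefficients.

## Bootstrap

Percentile intervals from resampling patients with replacement at the
original size, default B = 1000. Resamples that lose an outcome class are
redrawn up to ten times, then skipped and counted. The percentile variant
was chosen as the simplest reproducible one; measured coverage for the
c-statistic in the binormal benchmark (n = 2000, B = 1000) is ≈95% at
nominal 95%, with the usual slight undercoverage of percentile intervals.
Hospital-clustered resampling is out of scope — the validation design
resamples patients.

## Multiple imputation

Imputation operates on the raw measurements (SpO2, MUAC, WAZ, coma score,
AVPU, wheeze, HIV), and threshold categories are re-derived afterwards, so
the published predictor definitions stay exact. Chained equations visit
incomplete fields in ascending missingness order. Continuous fields use
predictive mean matching with k = 5 donors and a proper Bayesian parameter
draw (residual variance from a scaled inverse-χ², coefficients from their
normal posterior); binary fields use logistic draws with a
normal-approximation coefficient draw; the AVPU category uses multinomial
plug-in draws (no parameter draw — a mild approximation that slightly
understates between-imputation variance for that field). The outcome is
included as an imputation-model predictor, standard practice for validation
studies (switchable). If a binary sub-model separates, the sampler falls
back to marginal Bernoulli draws.

Config defaults are m = 50 imputations and 100 iterations, mirroring the
validation study design this workflow supports. The package's own tests and
the acceptance script run m = 5–10 with 10 iterations: chained equations on
these data reach a stable imputed-mean level within a few sweeps, and the
recovery results below are unchanged — these are the package's chosen
problem sizes, with a chain-drift warning raised when the last sweeps still
move an imputed mean by more than a fifth of the field's observed spread.

Pooling is by Rubin's rules: Q̄ = mean of per-imputation estimates,
W = mean within variance (bootstrap variance within each completed
dataset), B = between variance, T = W + (1 + 1/m)B, df =
(m − 1)(1 + W/((1 + 1/m)B))², infinite when B = 0. AUC is pooled on the
identity scale. Calibration curves are evaluated on a common
predicted-risk grid and averaged pointwise across imputations.

## Synthetic cohorts

The generator emulates the structure of the pneumonia validation cohort:
marginal prevalences female 0.438, wheeze 0.132, unconscious 0.064, and
continuous SpO2/MUAC drawn from per-category component distributions
(truncated normals, uniform on the moderate bands) so the induced category
rates hit moderate/severe hypoxemia 0.076/0.177 and moderate/severe
malnutrition 0.172/0.060 exactly in expectation. Field-level missingness
defaults are SpO2 0.413, MUAC 0.498, wheeze 0.026, AVPU 0.030 — MCAR by
default, with a MAR option whose masking probability is logistic in
standardized dependence fields and whose intercept is calibrated by root
finding to hit the marginal rate.

Predictors are independent except one built-in dependence: severe hypoxemia
and unconsciousness share an odds ratio of 2 (configurable), split across
consciousness strata by root finding so the marginal severe rate is
preserved. Outcomes are Bernoulli with logit p = δ + γ·lp_true, where
lp_true is a chosen model's linear predictor on the complete record; δ > 0
makes true risks higher than the model's predictions (the model
underestimates), γ < 1 makes predictions too moderate relative to truth. A
hidden truth table retains the complete pre-masking values and true risks.

What the generator does not emulate: hospital-level clustering and temporal
trends; the left-skewed WAZ distribution of real admissions (WAZ is drawn
Normal(−0.5, 1.1), matching the printed median/IQR but not the printed
WAZ < −2 tail); the abnormal-coma-score rate (tied deterministically to
AVPU here); and any correlation structure beyond the one built-in
dependence. Passing recovery tests therefore demonstrate that the pipeline
measures what it claims on data of this structure — not that the published
real-data performance figures are reproduced, which would require the
restricted cohort itself.

## Measurement design in tests and the acceptance script

Parameter recovery is measured at n = 50,000 generated admissions
(≈34,000 eligible, ≈1,000 deaths at δ=0, γ=1) with m = 5 imputations under
the default missingness. At these sizes the Monte-Carlo SE of the pooled
calibration slope is ≈0.035, so single-cohort estimates scatter visibly
around the truth; the recovery quantities are therefore averaged over 5
independent replicate cohorts per (δ, γ) condition, and the pooled-vs-full
AUC comparison over 6 replicate cohorts of n = 20,000 — precision choices,
with per-cohort conditions unchanged. Bootstrap coverage uses 100 seeded
replications in the test suite and 200 in the acceptance script.

A residual attenuation of the pooled calibration slope of about −0.015 under
the default missingness is a real property of scalar-match predictive mean
matching on these data (the imputation model conditions on a linear score
while the outcome depends on threshold categories); it is visible in the
replicate averages and is well inside the recovery tolerances.

## Known limitations

- Imputation assumes MAR; MNAR sensitivity models are out of scope.
- The multinomial AVPU imputer omits the parameter draw (see above).
- Percentile bootstrap mildly undercovers at 95% nominal; BCa or
  studentized intervals are not implemented.
- The CSV dialect is strict (exact header, UTF-8, semicolon-joined sets);
  it does not parse raw hospital exports.
- Weight-for-age z-scores are consumed as given; computing them from raw
  weight and age against growth references is out of scope.
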