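# Methods

## Design overview

The package follows one analysis design end to end: classify annual
register-style person-year records into four mutually exclusive
labour-market states, select the cohort that was Jobless at baseline, form
person-period transition rows at unequally spaced measurement years, fit
three nested multinomial-logit Markov models, and convert coefficients into
stratified transition-probability tables.  Because the individual-level
registers such analyses run on are not redistributable, the package ships a
synthetic register generator with known ground truth; every claim the test
suite makes about estimation quality is a claim about data generated by
that module.

## Classification

Each person-year is first mapped to one of nine fine positions (plus death
and emigration) and then collapsed to a state.  The rule families are
evaluated in a fixed precedence order: vital status (death, then
emigration), the benefit-day rule, the income-share rule, the
earnings-threshold rule, and the minimal-income residual.  Decisions that
the underlying design leaves open, and how they are resolved here:

* **"Six months" of compensated days** is `long_term_days = 183` (half of
  366), configurable within [150, 200].  The rule triggers on the *sum* of
  days across the four programmes (unemployment, sickness, disability,
  parental leave); the person is assigned to the programme with the most
  days, ties broken disability > sickness > unemployment > parental.  This
  makes an ambiguous verbal rule deterministic; every record's triggering
  rule is reported in the output (`triggered_rule`).
* **Income shares** are evaluated per source (social assistance, student
  allowance, old-age pension) against a strict `> 0.5` cut of disposable
  income; with a cut ≥ 0.5 at most one source can qualify.  A record whose
  share rule must be evaluated but whose disposable income is missing or
  non-positive raises an error rather than silently dividing by zero.
* **Precedence of welfare/health rules over earnings** reflects that the
  employed position is the residual majority category in such registers;
  whether the earnings rule is applied before or after the share rules
  cannot be settled from the design, so the welfare-first order is the
  package default and the audit column makes the decision inspectable.
* **Old-age pension** is classified via the share rule but collapses to
  Censored, like death and emigration.  Censoring is absorbing: after a
  censored year every later year is forced to Censored even if records
  reappear (re-immigration does not re-enter the cohort).

## Panel construction

Measurement years default to 1995, 1997, 2001, 2005, 2008, 2010 (periods
p0…p5).  One row is emitted per person per period p ≥ 1 whose previous
state is not Censored.  Age group (20–25, 26–30, 31–35, 36–40; the first
group deliberately spans six years to match the published reference
categories) is fixed at baseline age.  Education is lagged: the value
recorded in the calendar year of period p−1.  Inpatient care for an outcome
at year t counts countable hospital days in t−1 and t−2 (excluded-care days
— the childbirth/perinatal/contact-observation analogue — never enter), and
is categorised 0 / ≤ median / > median with the median computed per period
over rows with any care.  Whether that median should instead be pooled over
all periods is not decidable from the design; per-period is the default and
the medians used are reported.  Rows with a missing covariate are dropped
and counted per reason, never silently.

## Estimation

The three models are nested: previous state only (Model 1); plus sex, age
group, lagged education, country of birth (Model 2); plus inpatient
category and period dummies (Model 3).  The three equations
(Self-sufficient, Disabled, Censored, each against Jobless) are estimated
jointly by maximising the multinomial likelihood with Newton–Raphson on the
analytic gradient and Hessian:

* initialisation at zero; convergence when the gradient max-norm is below
  `tol = 1e-8`; at most 100 iterations; step halving (up to 40 halvings)
  whenever a full Newton step would decrease the likelihood;
* the design matrix is checked for full column rank up front via
  column-pivoted QR, and a rank-deficiency error names the offending
  columns; a small configurable ridge is available (and logged) for
  near-separated problems;
* the covariance is the inverse observed information at the optimum; Wald
  intervals `exp(b ± z·se)` mirror the symmetric printed intervals of
  published tables (profile-likelihood intervals are out of scope);
* pseudo-R² is McFadden's `1 − LL/LL₀` with the intercept-only
  log-likelihood in closed form from the outcome frequencies;
* standard errors are *not* cluster-adjusted: under the first-order Markov
  assumption repeated rows within a person are conditionally independent,
  which is the estimand this design targets.

The saturated Model 1 identity — fitted probabilities equal to the pooled
origin-destination fractions, intercepts equal to count ratios — is used as
an exact internal oracle, and the whole fit path is cross-checked against an
established multinomial-logit implementation in the test suite only.

## Prediction

Probabilities come from the inverse multilogit link, stabilised by
max-subtraction, ordered (S, J, D, C) in tables.  Tables can be built from
fitted coefficients or from *published* point odds ratios (two-decimal
precision).  In the latter mode the coefficients are ln(OR), and the
2-decimal rounding propagates: the Disabled intercept printed as 0.02 spans
0.015–0.025, which alone moves some Disabled cells by ±0.7 pp, hence the
±1 percentage-point reproduction tolerance used in the acceptance checks.
Table percentages are rounded half-up to one decimal to mirror printed
tables; rounding happens after normalisation, so unrounded columns sum to
100 exactly.

## Synthetic registers

The generator's defaults are the study conditions, chosen once:

* covariate marginals at baseline: 52.6 % male, education
  24.9/58.9/16.2 % (lower/high school/higher), 74.7 % born in Sweden —
  the published 1995 margins of the emulated cohort.  Age-group shares
  (0.30/0.25/0.23/0.22) reproduce the published mean age of 29.5; only the
  mean is published, not the group shares.  Factors are drawn
  independently: the joint covariate distribution is not published.
* education upgrades one level with probability 0.017 per year, moving the
  higher-education share from ~16 % to ~31 % over 15 years, matching the
  published trend and making the lagged-education covariate genuinely
  time-varying.
* the state process starts from a population mix of 26 % Jobless, 71 %
  Self-sufficient, 3 % Disabled and evolves at the measurement years under
  a multinomial-logit kernel whose default coefficients are the published
  full-model odds ratios; the baseline-Jobless selection downstream then
  recovers the ~26 % study population.
* annual inpatient days are zero-inflated geometric: probability of any
  care 0.136 (Jobless; giving the published 86.4 % zero-care share),
  0.10 (Self-sufficient), 0.40 (Disabled); positive counts geometric with
  mean 5 days.  The kernel categorises the two-year care window with the
  theoretical median of that positive distribution (4 days) because the
  empirical per-period median does not exist until the population has been
  simulated; the panel builder recomputes empirical medians downstream,
  which land on the same value in large samples.
* a Censored kernel draw is realised as death, emigration or old-age
  pension (split from the configured rates death 0.002 / emigration 0.005
  per year plus a 1 % old-age share), with the event year uniform in the
  preceding gap.  The kernel is the *only* source of censoring — there is
  no additional independent annual hazard — so empirical one-step
  fractions converge exactly to the analytic kernel, which the tests rely
  on.
* currency is abstract: the earnings threshold is 1.0 and all monetary
  fields are scaled relative to it (the real statistical-office threshold
  varies by year and is not published).
* intended states are rendered through the nine fine positions, sampled
  with weights proportional to their published population counts so all
  classifier branches are exercised; rendering keeps each position inside
  its classification region for any `long_term_days` in [150, 200]
  (target-programme days 200–330, incidental days ≤ 20 each, incidental
  income shares ≤ 0.2).

What the generator does **not** emulate: within-year benefit spells,
correlated covariates, monetary detail of benefit rules (replacement rates,
caps), state changes between measurement years (states are held constant
across a gap), or morbidity beyond a binary excludable-care flag.  Passing
tests therefore demonstrate correctness of the machinery under the stated
Markov design, not robustness to real-register messiness.

## Problem sizes and numerical checks

The test suite runs cohorts of 2,000–100,000 persons where marginal
accuracy requires it; parameter recovery uses 50,000 five-period
trajectories and interval coverage 200 replicates of 2,500 persons —
sizes at which the asymptotic Wald theory the models rely on is
comfortably valid while the whole suite stays quick.  Monte-Carlo
comparisons use 3–4 binomial standard errors; exact identities
(normalisation, the saturated-model fractions) are asserted at 1e−7 to
1e−12; the cross-check against the reference implementation is at 1e−6 on
interior MLEs only (quasi-separated replicates, where the MLE is not
interior, are excluded for both implementations alike).

## Known limitations

* Printed odds ratios reproduce published probability cells only up to
  their rounding (±1 pp); exact unrounded coefficients are unrecoverable.
* The Wald machinery degrades under quasi-separation (rare
  origin-destination cells at small n); the fit reports an honest
  convergence flag and offers a logged ridge rather than hiding it.
* No delta-method intervals for predicted probabilities, no random
  effects, no continuous-time transition intensities, no robust/clustered
  variances — all outside the design this package implements.
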