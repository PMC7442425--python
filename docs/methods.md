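# Methods

This note documents the statistical models implemented in `pharmsignal`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data experiments do and do not demonstrate.

## The estimation problem

Observational safety comparisons of two drugs are confounded: patients
channelled to one drug differ systematically from those channelled to the
alternative. The pipeline addresses this with three complementary layers:

1. **design** — a new-user active-comparator cohort (both arms initiate
   treatment for the same indication, removing prevalent-user and
   confounding-by-indication biases);
2. **measured confounding** — a large-scale propensity score, stratified
   into quintiles, with covariate balance verified;
3. **unmeasured confounding** — empirical calibration against
   negative-control outcomes, plus a self-controlled (within-person)
   design as an independent check.

Per-database estimates are then pooled across databases only when they are
homogeneous enough to pool.

## Synthetic claims generator

The generator emulates administrative claims mapped to a minimal OMOP-like
schema. Time is integer days; day 0 is every person's observation start,
anchored at Jan 1 of `start_year` (365-day years) so ages and calendar
seasons are well defined. Each person has exactly one observation period
(multiple periods add no testing value). The data-generating model:

* binary baseline covariates `x` with configured prevalences (defaults
  chosen to resemble a rheumatoid-arthritis population: 78% female, 13%
  diabetes, 15% heart disease, 31% hyperlipidaemia, 13% depression, 4%
  COPD);
* treatment: `arm ~ Bernoulli(expit(α + x'β + γ_u·u))` where `u` is a
  latent binary factor never exposed downstream (the unmeasured
  confounding channel);
* exposures: an initial fill at the index day plus Poisson-distributed
  refills with Poisson gaps (defaults: 30 days supplied, mean 3 refills,
  mean 10-day gaps), truncated at observation end;
* outcomes: first-event times `T ~ Exponential(λ·exp(x'γ + θ·arm + δ·u))`
  clocked from the index, recorded at day `index + ceil(T)` when that does
  not exceed observation end (right-censoring by disenrollment). An event
  therefore lands in a 30-day window exactly when `T ≤ 30`, which gives
  the closed-form binomial checks used in tests. Negative-control
  outcomes have `θ = 0` enforced at construction; a nonzero `δ` on them
  injects genuine systematic error for calibration to absorb.

Random streams are split per stage (population / treatment / outcomes /
case series) so adding outcomes never perturbs the population draw.

For self-controlled designs, `simulate_sccs_cases` generates
recurrent-event histories from a piecewise-constant Poisson process —
rate `λ·f_p` off treatment and `λ·f_p·IRR` on treatment, with an optional
log-normal per-person frailty `f_p` — because the cohort generator's
first-event, post-index semantics are not a valid recurrent-event law.

**What passing tests show, and what they do not.** The generator
reproduces the *statistical structure* the pipeline must handle:
confounded assignment, censoring, era fragmentation, null controls with
injectable bias. It does not reproduce coding-system noise, outcome
misclassification, multiple observation periods, time-varying hazards, or
between-database coding heterogeneity, so parameter recovery here
demonstrates correctness of the estimators, not robustness of real-world
results to those artefacts.

## Drug eras and cohorts

Dispensing records for one person and drug are merged into an era when the
count of unexposed days between them (`next_start − previous_end − 1`) is
at most `max_gap_days` (default 90). The boundary is unit-tested on both
sides; an era ends at the last record's `start + days_supplied − 1`. Era
construction is idempotent.

New users: index = first era start of the person's own drug; persons ever
exposed to both study drugs are excluded entirely (the cleanest new-user
contrast), as are those younger than 18 at index, without the indication
on or before the index day, or with fewer than 365 observed days before
it. Follow-up starts the day after the index; an event on the index day
itself does not count, and the person remains in the cohort.
Intention-to-treat follow-up is capped 30 days after the index;
on-treatment follow-up runs to the end of the index drug era plus a
14-day washout. Intervals are closed `[start, end]`; person-time is kept
in integer days and divided by 365.25 only at reporting.

## Propensity scores and balance

The propensity model is L1-penalized logistic regression. The penalty is
selected by ten-fold cross-validation (seeded fold assignment, out-of-fold
log-likelihood as the objective — likelihood rather than AUC, since the
score is used as a probability) over a 20-point logarithmic grid. Scores
are cut at the 20/40/60/80 percentiles of the pooled distribution; ties
are broken by the quantile cut itself, and fully degenerate all-equal
scores collapse into a single stratum with a warning rather than an
error. Perfect separation falls back to the largest penalty with a
warning. No trimming of non-overlapping scores is applied; stratification
is the analytic design.

Balance is measured by the standardized mean difference
`(m_t − m_c)/sqrt((v_t + v_c)/2)`. The after-stratification SMD replaces
arm means with stratum-size-weighted within-stratum means (weights
proportional to combined stratum size) while keeping the unadjusted
variances in the denominator so before/after values share a scale. Any
covariate with |SMD| > 0.1 after stratification fails the analysis, and
the pipeline driver turns every outcome of that analysis into an
exclusion record.

## Outcome model

Hazard ratios come from a Cox model conditioned on the propensity strata —
a separate baseline hazard per stratum and a single treatment coefficient,
with Efron's approximation for tied event times (ties are guaranteed by
integer-day data). Wald CIs and p-values are reported. Analyses with zero
events in *either* arm are inestimable (the HR is unbounded) and are
returned as exclusion records; this resolves the zero-event rule in the
stricter of its two possible readings. The fitter is `lifelines`'
`CoxPHFitter`; tests verify it against brute-force partial-likelihood
maximization on small instances.

The minimum detectable rate ratio uses the two-sided normal approximation
with the event split taken under the null:
`log MDRR = (z_{1−α/2} + z_{power})·sqrt(1/E_t + 1/E_c)` — finite for any
positive event count, infinite at zero events, and within 5% of a
brute-force binomial power simulation at 100 events.

## Empirical calibration

The systematic-error model is `log HR_i ~ Normal(μ, τ² + se_i²)` across
negative controls — constant (μ, τ) independent of true effect size, the
simplest model consistent with negative-control calibration; this is the
key modelling assumption, and positive-control models in which error
scales with effect size are out of scope. The MLE is found by bounded
quasi-Newton on (μ, log τ) from three starts, with an exact check of the
τ = 0 boundary (where the MLE of μ is the precision-weighted mean).
Fewer than 5 usable controls (configurable) skips calibration with a
warning; zero-event controls never reach the fit because they are already
exclusion records.

Calibrated quantities: p-value = two-sided tail of
`Normal(μ, τ² + se²)` at the observed log HR; point estimate
`log HR − μ`; CI half-width `1.959964·sqrt(τ² + se²)`. With μ = 0 and
τ = 0 these reduce exactly to the uncalibrated values. Recovery of
(μ, τ) to within 0.03 is demonstrated at 100 controls with sampling
standard errors around 0.05; with much noisier controls (se ≈ 0.1 and
larger) τ of that size is weakly identified and the MLE can sit on the
τ = 0 boundary — a property of the likelihood, not of the optimizer.
Calibration is applied per database before pooling.

## Self-controlled case series

Conditioning on each person's total event count turns the Poisson
likelihood into a per-person multinomial over intervals with
probabilities ∝ `length·exp(x'β)`; any time-invariant multiplicative
person effect cancels exactly (verified algebraically in tests by scaling
each person's interval lengths). Observation time is cut at exposure-era
boundaries (the risk window is the era itself — no pre-exposure or
residual window), 5-year age-band birthdays, calendar-quarter boundaries,
and co-medication era boundaries; all granularities are configurable.
The exposure coefficient is never penalized; nuisance covariates carry an
L1 penalty selected by seeded ten-fold cross-validation over cases on
out-of-fold conditional log-likelihood, over a 10-point geometric grid
anchored at the score of the nuisance block at the exposure-only fit.
The exposure standard error comes from the inverse of the analytic
observed information at the solution. Correction for event-dependent
observation is not implemented; result tables carry a placeholder column
for that variant.

## Evidence synthesis

Heterogeneity: `Q = Σ w_i(θ_i − θ_fixed)²` with inverse-variance weights,
`I² = max(0, (Q − df)/Q)`, and the DerSimonian–Laird moment estimate
`τ² = max(0, (Q − df)/(Σw − Σw²/Σw))` — the construction in which
across-database variance is estimated by comparing each database-specific
result with the fixed-effects meta-analysis. Pooling uses weights
`1/(se_i² + τ²)`; with τ² = 0 it equals the fixed-effects estimate
exactly. No pooled estimate is produced when I² ≥ 0.4: `meta_analysis`
returns a gated record with the pooled fields withheld, and
`random_effects_pool` refuses gated input outright. The gate is applied
to the calibrated estimates, which are the quantities pooled in reports.
Databases are treated as independent; a variance-inflation hook exists
for known patient overlap (default factor 1).

Pooled count rows sum users and events and weight rates by person-time,
back-deriving person-time as `events/rate` when only printed rates are
available. Cell counts in [1, 5) display as `<5` (zero displays as `0`
because zero-event analyses are excluded upstream, making zero
structural); a rate computed from a masked count displays as the upper
bound implied by the masking threshold, e.g. `<3.54`.

## Problem sizes in the test-suite and acceptance runs

Parameter-recovery studies use 50 replicates of n = 20,000 confounded
cohorts (Cox) and 20 replicates of 500-case series (SCCS); calibration
restoration uses 20 replicates of 40 negative controls and a 100-control
null-recovery fit; CI-coverage and permutation-uniformity properties use
400–500 replicates at smaller n. These sizes give Monte-Carlo standard
errors comfortably inside the asserted tolerances (e.g. ±0.011 on the
mean log HR over 50 replicates against a 0.05 band).

## Known limitations

* No multiple observation periods, vocabulary handling, or ATLAS-style
  cohort-definition import; covariates are the binary indicators present
  in the table rather than features constructed from raw codes.
* The combination-therapy index rule (second drug starting within a
  configurable window of the first) is a documented assumption.
* SCCS event-dependent observation correction, spline age models, and
  effect-size-dependent calibration error models are out of scope.
* Real-data hazard ratios from proprietary multi-database networks are
  not reproducible here; the worked tables bundled in
  `pharmsignal.examples` exercise reporting arithmetic only.
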