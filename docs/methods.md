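# Methods

This note documents the model, the statistical procedures, the
synthetic-data generator, and the numerical and design choices behind
`woundcea`, in the spirit of a model technical appendix.

## Cohort model

Three states — unhealed SWHSI, healed, dead — with everyone starting
unhealed. Cycles are monthly (365.25/12 = 30.4375 days) over a default
horizon of 360 cycles (30 years), by which time the cohort (starting
age 62.9 under an SMR of 13.3) is essentially extinct.

**Transitions.** Within a cycle, death is resolved first and healing
second among survivors:

```
unhealed' = unhealed · (1 − p_die) · (1 − p_heal)
healed'   = healed · (1 − p_die) + unhealed · (1 − p_die) · p_heal
dead'     = dead + (unhealed + healed) · p_die
```

The alternative composition (healing first) differs only at O(p²); the
death-first ordering is conservative and order-stable. Occupancy is
conserved to 10⁻¹² per cycle by construction, and the test suite checks
the deterministic trace against a 10⁵-patient microsimulation that uses
the same per-cycle probabilities but independent Bernoulli transitions.

**Mortality.** `p_die(t)` is taken from a single-year-of-age life table
at the cohort's attained age (start age + elapsed years, indexed by
`floor(age)`), converted to a per-cycle probability under a
constant-within-year hazard, and multiplied by the SMR *on the hazard
scale*: `p* = 1 − exp(−SMR · h)` with `h = −ln(1 − p_cycle)`.
Probability-scale multiplication would exceed 1 for large SMRs and is
not hazard-proportional. Death probabilities are identical in the
unhealed and healed states: the excess mortality reflects the frailty
of the population, not the wound state.

**Healing.** The baseline per-cycle hazard `h₀(t)` may be a constant or
a per-cycle sequence (piecewise exponential). The published occupancy
trajectory this model family targets is internally consistent at 12
months with a constant hazard, but its 5-year tail (≈9% of survivors
still unhealed) is not: a constant hazard calibrated to 12 months
implies ≈1% unhealed among survivors at 5 years. Because the base-case
hazard form behind that tail is unreported, the package exposes
piecewise hazards but ships a constant-hazard base case calibrated by
bisection so the standard arm reaches 55% cumulative healed occupancy
at cycle 12 (tolerance 10⁻⁸; the healed fraction is strictly increasing
in the hazard, so the root is unique). A consequence is that absolute
healthcare costs — which accrue over unhealed person-time — are smaller
than under a long-tailed baseline; the incremental comparison between
arms is far less sensitive to this choice than the absolute levels.

**Accrual convention.** State membership is evaluated at cycle end, with
an optional half-cycle correction (averaging start- and end-of-cycle
occupancy) behind a config flag, off by default. QALYs accrue as
occupancy-weighted utility × (cycle length in years); healed utility is
the general-population prediction from a quadratic-in-age, sex-adjusted
regression (coefficients live in the config; the bundled ones are the
published UK values), unhealed utility subtracts the decrement δ.
Discounting is 3.5%/year for costs and QALYs — the UK reference-case
rate — applied as `(1 + r)^(−t·cycle_days/365.25)`.

**Intervention costs.** The NPWT arm pays the NPWT daily rate for the
first 46.6 days of unhealed time and the standard-dressings rate
afterwards, pro-rated inside the switch cycle (46.6 days ≈ 1.53
cycles); the standard arm pays its daily rate throughout unhealed time.
Healthcare costs while unhealed are Σ(monthly resource mean × unit
cost) + monthly medication cost; healed patients are assumed discharged
and cost-free (an assumption that understates total costs for both arms
equally).

## Evidence synthesis

Study-level log hazard ratios are pooled with the normal-normal
random-effects model, marginalizing the study effects analytically so
the posterior is two-dimensional (μ, τ). Priors: μ ~ N(0, 10²) on the
log scale, τ ~ Half-Normal(1) — standard vague choices, exposed in
`PriorSpec`. Sampling uses an affine-invariant ensemble (emcee) with 8
walkers; four independently seeded ensembles act as chains, 500
burn-in steps each, 2 500 retained draws per chain (10 000 total).
Convergence is monitored with split-chain R-hat on μ; values above 1.05
set `converged=False` on the result and emit a warning — never silently
discarded. Patient-level (IPD) studies enter as a derived
(log HR, se) pair — two-stage synthesis — using the closed-form
exponential person-time estimator `log((d₁/T₁)/(d₀/T₀))` with
`se = √(1/d₁ + 1/d₀)`; censoring by death or the administrative cutoff
enters through the person-time accounting. The tests cross-check this
estimator against a Cox partial-likelihood fit.

A single seeded 7-study recovery run (between-study sd 0.1, per-study
se in [0.15, 0.4]) has a pooled-posterior standard deviation of ≈0.1 on
the log scale, so individual recovery runs scatter around the truth by
about that much; the coverage property (95% credible interval covering
the generating mean ≈95% of the time over 200 replicates) is the
sharper guarantee and is tested directly.

## Trial-parameter estimation

- **Utility decrement.** Linear mixed model of the EQ-5D index on an
  unhealed indicator with a random intercept per patient, fitted by
  REML; the decrement is the negated coefficient (positive = unhealed
  worse). Conditioning is on healing status only. Degenerate
  (effectively noiseless) panels short-circuit to OLS, and mixed-model
  failures fall back to OLS with cluster-robust standard errors.
- **SMR.** Observed deaths over expected deaths, with expected deaths
  computed by integrating each patient's age-specific reference hazard
  (constant within year of age, day resolution) over their follow-up.
  Checked against a brute-force day-by-day summation oracle.
- **Resource use.** Per-patient monthly rates (counts over unhealed
  months), averaged across patients; per arm for the primary-care items
  that are treatment-dependent, pooled for the secondary-care items.
- **NPWT duration.** Mean and standard error of recorded days on NPWT
  in the NPWT arm.

## Synthetic-trial generator

The generator emulates the data streams the estimators consume, with
defaults equal to the documented point estimates (n = 680; age
62.9 (12.6); covariate prevalences 37.7/83.1/78.4/16.8%; 1:1
allocation; HR 1.07; SMR 13.3; δ = 0.0095; NPWT duration 46.6 (4.12)
days; the full monthly resource-mean table; 12-month administrative
censoring):

- healing times: (piecewise-)exponential with arm hazard
  `h₀·exp(logHR·arm)`; the default constant hazard implies a mean time
  to healing of ≈164 days in the standard arm, matching the reported
  mean time on standard dressings;
- death times: inverse-transform sampling from the life-table hazard ×
  SMR, piecewise constant within years of attained age;
- EQ-5D: observed at 0/3/6/12 months while alive, index =
  flat population utility (0.70, a trial-like mean) + patient random
  intercept (sd 0.1) − δ·unhealed + N(0, 0.15) noise, ceiling-clipped
  at 1. The flat surface keeps the healing-status-only regression
  correctly specified, and the ceiling binds for <5% of draws so the
  attenuation it causes is an order of magnitude below the Monte-Carlo
  error of the recovery studies;
- resource counts: patient-level gamma monthly rates (CV 1,
  over-dispersed as questionnaire count data are) driving Poisson
  counts over the unhealed days of each follow-up window;
- study sets: per-study se uniform on a range, log-HRs drawn from the
  marginal law N(truth, τ² + se²).

What the generator does **not** emulate: correlation between baseline
covariates (independence assumed; nothing downstream consumes the joint
law), wound-area dynamics, infection or readmission events, missing
questionnaires, or EQ-5D-5L→3L valuation (index scores are emitted
directly). Passing recovery tests therefore demonstrates estimator
correctness under the stated generating law, not robustness to
real-data complications such as informative missingness.

## PSA and decision analytics

Each iteration draws: HR by resampling the pooled posterior draws
(preserving skew — no parametric refit); SMR lognormal; utility
decrement and NPWT duration normal truncated at zero; daily dressing
costs, medication and resource means gamma. All families are
moment-matched to their mean/s.e. pairs and overridable; a zero s.e.
freezes the parameter. Draws are deterministic given (seed, iteration),
so runs are reproducible and extensible. Parameters are independent
across the draw (a correlation hook can be added via the families map);
the calibrated baseline hazard is held fixed across iterations, being
an internal calibration rather than an evidence-based parameter.

CEAC probabilities count iterations with incremental NMB > 0, ties at
exactly zero counting 0.5 (unbiased under symmetric noise). Interval
summaries use the inclusive linear-interpolation percentile definition
(numpy's default). The break-even analysis bisects the deterministic
incremental NMB over an HR bracket (default [1, 5], tolerance 10⁻⁶);
the incremental NMB is strictly increasing in HR there, and the result
reports both the hazard-ratio root and the equivalent multiplier on the
per-cycle healing probability, because a "% increase in the probability
of healing" can be read on either scale. An unachievable break-even
within the bracket is reported as a flagged result, not an exception.

## Problem sizes used in validation

Recovery studies use n = 680 patients × 20 replicates (decrement),
n = 20 000 (SMR), k = 7 studies (pooling), 200 replicates for interval
coverage, and 10⁵ patients for the microsimulation cross-check — sizes
at which Monte-Carlo error is small relative to the effects being
recovered while the full suite stays fast on a single CPU.

## Known limitations

- Absolute lifetime costs depend strongly on the unreported baseline
  hazard tail and on unit costs; the bundled base case is internally
  consistent but not a reproduction of any specific published cost
  level. Incremental comparisons are the robust output.
- No tunnel states: a healed wound cannot recur.
- No arm-specific mortality, by assumption.
- The meta-analysis does not model publication bias, covariate
  meta-regression or one-stage IPD synthesis.
- No EVPI/value-of-information analysis.
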