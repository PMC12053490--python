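# woundcea

Lifetime cost-utility modelling of **negative pressure wound therapy
(NPWT)** versus **standard dressings** for surgical wounds healing by
secondary intention (SWHSI) — open surgical wounds left to granulate
rather than being sutured closed.

The package is aimed at health economists and trial statisticians who
want a tested, reusable implementation of the full evidence-to-decision
pipeline for this comparison: evidence synthesis → trial-parameter
estimation → Markov cohort extrapolation → probabilistic sensitivity
analysis (PSA) → decision analytics. Because the underlying
patient-level trial data are not redistributable, the package ships a
synthetic-trial generator that emulates the data streams the analysis
consumes, so every estimator can be exercised and validated by
parameter recovery.

## The model

A three-state Markov cohort model (*unhealed* → *healed*, both →
*dead*) advances in monthly cycles over a 30-year horizon. Per cycle
*t*:

- healing: the standard arm heals with probability
  `p₀(t) = 1 − exp(−h₀(t))`; the NPWT arm with
  `p₁(t) = 1 − exp(−h₀(t)·HR)`, where `HR` is the pooled hazard ratio
  from a Bayesian random-effects meta-analysis
  (`yᵢ ~ N(θᵢ, seᵢ²)`, `θᵢ ~ N(μ, τ²)`, vague priors, sampled with an
  affine-invariant ensemble);
- death: age-indexed life-table probability with a standardized
  mortality ratio (SMR) applied on the hazard scale,
  `q* = 1 − (1 − q)^SMR` per cycle, identical in both living states;
- QALYs: healed patients accrue general-population utility `U(age)`
  (quadratic-in-age, sex-adjusted); unhealed patients accrue
  `U(age) − δ`, with `δ` the unhealed-state utility decrement;
- costs: healthcare costs (primary/secondary care resource use ×
  unit costs + medication) accrue only while unhealed; dressing costs
  accrue daily — the NPWT arm pays the pump rate for its first 46.6
  days of unhealed time and the standard rate thereafter;
- both streams are discounted at 3.5% per year.

Decision outputs are the net monetary benefit `NMB = λ·QALYs − cost`
per arm, the incremental NMB, the probability that NPWT is
cost-effective across PSA iterations, the cost-effectiveness
acceptability curve, and a break-even analysis solving for the HR at
which the incremental NMB crosses zero.

## Worked example

The bundled base case (`woundcea/data/base_case.yaml`) calibrates the
baseline healing hazard so that 55% of the standard-dressings cohort is
healed at 12 months, uses HR 1.07, SMR 13.3, δ = 0.0095 and the costs
listed in the config. From a shell:

```text
$ woundcea run
    npwt: QALYs 3.636  total £15,367 (healthcare £13,104 + intervention £2,263)
standard: QALYs 3.636  total £14,584 (healthcare £13,324 + intervention £1,260)

$ woundcea psa --n 500 --seed 1 --out psa.csv
λ=£20,000: iNMB £-864, P(CE)=26.0%
λ=£30,000: iNMB £-859, P(CE)=26.0%

$ woundcea threshold
required HR 1.1365 (per-cycle healing probability × 1.1303, i.e. +13.0%) at λ=£20,000
```

Reading: discounted lifetime QALYs are essentially identical across
arms (the HR of 1.07 is small and uncertain), NPWT costs about £780
more per patient — higher dressing costs, slightly lower healthcare
costs — so its incremental NMB is negative at conventional
willingness-to-pay values and its probability of being cost-effective
is about a quarter. NPWT would need to raise the per-cycle healing
probability by roughly 13% before it broke even. Absolute cost levels
scale directly with the unit costs and the extrapolated unhealed time
configured in the YAML; the comparison between arms, not the absolute
level, is the decision-relevant output.

The same pipeline is scriptable from Python (`woundcea.generate_cohort`,
`pool_effects`, `run_psa`, `ceac`, `threshold_effect`, ...); see the
module docstrings and `docs/methods.md`.

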