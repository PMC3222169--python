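# alccea

Population-level cost-effectiveness simulation of health-care systems for
alcohol use disorders.

`alccea` is aimed at health-economic modellers and public-health planners who
want to compare a *base-case* mix of clinical interventions for problem
drinking (brief interventions, CBT, detoxification, aftercare) with an
*alternative* mix — for example one augmented with eHealth services — at the
national level and over a 12-month horizon. It answers: what does each system
cost, how much disease burden does it avert, and is the difference worth
paying for?

## Model

The target population of problem drinkers is stratified by gender and by
bands of the AUDIT screening score (abstinent, moderate, heavy, hazardous,
harmful, dependence). For each scenario entry — a (disorder band,
intervention) pair with coverage rate *c* and adherence rate *a* — the model
computes:

- **Costs.** `N_band × c × unit cost` summed over entries; costs accrue to
  everyone covered, adherent or not. Nothing is discounted (12-month
  perspective).
- **Morbidity (YLD).** Instead of disorder-specific disability weights, the
  treatment effect size *d* (standardized mean difference) is converted into
  a disability-weight shift with an expert-panel conversion factor of
  0.18 (95% CI 0.16–0.20) per unit of *d*:
  `YLD = N_band × c × a × d × 0.18 × (1 − attenuation)`.
- **Mortality (YLL).** Gender-specific relative risk of all-cause death as a
  function of mean pure-ethanol intake *x* (g/day):
  `ln RR = b₁·ln(x+1) + b₂·x`, with (b₁, b₂) = (−0.1030, 0.0035) for men and
  (−0.0645, 0.0029) for women. Treatment lowers intake by 20%, the RR drop
  times the age-weighted background mortality gives deaths avoided in the
  present year, and each avoided death is credited with the remaining life
  expectancy at the age of death.
- **DALYs.** `DALY = YLD + YLL`, both damped by a conservative 20%
  attenuation factor (former heavy drinkers retain elevated risk).
- **Economics.** Incremental cost `ΔC = C₁ − C₀`, incremental effect
  `ΔE = E₁ − E₀` (DALYs averted), `ICER = ΔC/ΔE` with explicit CE-plane
  quadrant flags, benefit–cost ratios at a willingness-to-pay ceiling λ, and
  the cost-effectiveness acceptability curve
  `P(λ·ΔE − ΔC > 0)` over a grid of λ.

In stochastic mode, per-participant costs are drawn from moment-matched
gamma distributions (sd = range width / 3.92), effect sizes from normal
distributions on their 95% CIs, and the conversion factor from its CI; both
scenarios are evaluated on the *same* draws each iteration (common random
numbers), so shared interventions cancel exactly from every increment.

Band-level mean intakes are not observed; they are calibrated once by
inverting the dose-response curve against published band-level RRs and
shipped frozen in the fixtures. The packaged mortality table is synthetic
(a Gompertz fit anchored on Dutch 2009 period life-table values) and is
labelled as such.

## Worked example

The packaged Netherlands fixtures describe 1,254,000 problem drinkers
(987,000 men, 267,000 women), a seven-intervention catalog in 2009 euros,
and three scenarios: current care (`base_case`), current care plus eHealth
(`ehealth_added`), and 50% substitution of face-to-face care by eHealth
(`ehealth_substitution`).

```sh
$ alccea run --out results
base_case: cost €238.3M, 4748 DALYs averted
ehealth_added: cost €301.2M, 9627 DALYs averted
Δcost €62.9M, ΔDALY 4879, ICER Icer(12892 €/DALY), BCR 1.00 -> 1.60
wrote results/comparison.json
```

Adding eHealth costs an extra €62.9 million and averts an extra 4,879 DALYs:
about €12,900 per DALY, far below the customary Dutch ceilings of
€20,000–€80,000 per DALY, and the benefit–cost ratio at €50,000/DALY rises
from roughly break-even (1.00) to 1.60 — every euro spent returns €1.60 of
health-related value. Decision uncertainty:

```sh
$ alccea ceac --seed 1 --out results
P(cost-effective | λ=€20,000/DALY) = 73.6%
wrote results/ceac.csv
```

At λ = €0 the probability is 0% (the new system is never cheaper); it rises
steeply and reaches ~74% at €20,000/DALY. Running
`alccea run --alt ehealth_substitution` shows the substitution scenario is
*dominant*: €163.6M instead of €238.3M for virtually unchanged population
health (4,858 vs 4,748 DALYs averted).

`alccea psa --seed 1 --out results` writes the per-iteration vectors,
`alccea fixtures` exports the packaged fixture files, and
`alccea validate` checks a configuration. Coverage overrides support what-if
analyses, e.g. `--override harmful:online_therapist_led=0.20`.

## Documentation

See `docs/methods.md` for the model assumptions, parameter defaults,
numerical choices, what the synthetic fixtures do and do not emulate, and
known limitations.
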