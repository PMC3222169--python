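# Methods

## Scope and model structure

`alccea` estimates the 12-month incremental cost-effectiveness of one mix of
clinical interventions for alcohol use disorders against another, at
population scale. It is a steady-state, one-period model: no dynamics, no
discounting, no implementation costs, and only health-care-system costs (no
out-of-pocket, productivity, or justice-system costs). Outcomes are averted
disability-adjusted life years, `DALY = YLD + YLL`, and euros.

The computation runs in five stages, mirroring the module layout:

1. **population** — stratify the target group by gender and AUDIT band;
   attach a mean pure-ethanol intake (g/day) and a relative risk of
   all-cause death to each band; hold the age structure and the mortality /
   life-expectancy table.
2. **interventions** — the catalog of per-participant costs and effect
   sizes, with their sampling distributions, and the scenario definitions
   (coverage and adherence per disorder band).
3. **burden** — YLD from effect sizes via the disability-weight conversion
   factor; deaths averted and YLL from intake reduction via the
   dose-response mortality model; attenuation.
4. **economics** — scenario costs, ΔC/ΔE, ICER with CE-plane quadrant
   handling, net monetary benefit, acceptability curves, benefit–cost
   ratios.
5. **engine** — deterministic runs and seeded Monte-Carlo probabilistic
   sensitivity analysis (PSA).

## Dose-response mortality risk

Relative risk of all-cause death at intake `x` (grams pure ethanol/day):

    ln RR = b1 * ln(x + 1) + b2 * x

with `(b1, b2) = (-0.1030, 0.0035)` for men and `(-0.0645, 0.0029)` for
women. The first term produces the protective dip at moderate intake, the
second the rising excess risk — the familiar J-shape, with `RR(0) = 1`
exactly. The second term is linear in `x`; a literal `b2·ln(x)` variant is
exposed (`relative_risk(..., second_term="log")`) for audit purposes but is
undefined at zero intake, cannot return unit risk for abstainers, and cannot
reproduce the band-level RRs the model is calibrated to, so the linear form
is the default and the calibration target. The residual of the underlying
regression is fixed at zero: the dose-response is deterministic, also in
PSA.

### Band-intake calibration

Band-level mean intakes are unobserved. They are obtained by inverting the
RR curve against the published band RRs (men 1.00 / 0.86 / 0.95 / 0.99 /
1.10 / 1.36; women 1.00 / 0.96 / 0.99 / 1.05 / 1.12 / 1.28 for abstinent
through dependence). The J-shape makes sub-unit targets two-rooted; the root
on the increasing (high-intake) branch is taken so that calibrated intakes
rise monotonically with band severity, and a target of exactly 1 maps to
zero intake (abstainers). Inversion uses Brent's method on [0, 500] g/day to
1e-9 and round-trips each target within 1e-6. The resulting intakes (men:
89.5 / 128.5 / 143.5 / 180.3 / 250.5 g/day moderate→dependence) are frozen
in `audit_bands_nl.csv` so runs never re-calibrate. These values are high in
absolute terms; they should be read as the curve's internal coordinates for
matching the printed RRs, not as survey-calibrated consumption.

## Burden averted

**YLD.** A treatment effect of size `d` (standardized mean difference) is
converted to a disability-weight shift with the conversion factor
`cf = 0.18` DW per unit `d` (95% CI 0.16–0.20). For a scenario entry with
band headcount `N`, coverage `c`, adherence `a`:

    YLD = N * c * a * d * cf * (1 - attenuation)

Adherence moderates the *response*, not the cost: the shift accrues to the
treated-and-adherent headcount. Negative effect draws propagate to negative
YLD (no flooring), so PSA scatter can reach the southern CE-plane quadrants.

**Deaths and YLL.** Every intervention lowers mean intake by 20%
(per-intervention override available). For each gender stratum:

    deaths = N * c * a * m̄ * [RR(x) - RR(0.8x)] * (1 - attenuation)

where `m̄` is the annual mortality rate weighted by the population age
distribution (normal, mean 44.7 y, SD 10.7, truncated to 18–69 and
discretised to integer ages). Deaths are allocated over ages proportionally
to `age weight × mortality rate`, and each avoided death is credited with
the remaining life expectancy at that age — the standard period-DALY
convention; because the model is one-period, deaths themselves are "avoided
this year" only. On the protective limb of the J-curve a 20% cut can *raise*
RR; the resulting negative deaths averted are kept as computed.

**Attenuation.** Both YLD and YLL are damped by 20% (`attenuation = 0.20`),
reflecting residual risk in former heavy drinkers. It is a sensitivity knob,
never sampled; setting it to 0 scales every burden component by exactly
1/0.8.

Intervention contributions are summed within and across disorder bands with
no interaction terms — the catalog interventions are chosen to be
non-overlapping and independent per band.

## Economics

`ICER = ΔC/ΔE` is reported as a ratio only in the northeast quadrant
(costlier and more effective). Cheaper-and-no-less-effective alternatives
are flagged *dominant*, costlier-and-no-more-effective ones *dominated*, a
zero increment on both axes *undefined*, and southwest-quadrant draws carry
the raw ratio under an explicit `sw_ratio` tag. The acceptability curve uses
strict inequality in net monetary benefit (`λΔE − ΔC > 0`; ties count as not
cost-effective), which anchors the curve at 0% for λ = 0 when no draw is
cost-saving. Benefit–cost ratios monetise averted DALYs at λ = €50,000 (the
conservative Dutch lower bound; the customary ceilings run €20,000–€80,000
per DALY).

## Uncertainty handling

Costs: gamma, moment-matched with mean = point estimate and
sd = (high − low)/3.92, i.e. the uncertainty range is read as a central 95%
interval (moment-matching chosen over quantile-fitting for determinism; the
only stated constraint is that the distribution fit within the limits).
Effects: normal with sd = CI width/3.92, untruncated. Conversion factor:
normal(0.18, 0.04/3.92), toggleable. Adherence (0.50 for every intervention,
so that scenario differences reflect technologies rather than differential
compliance), attenuation, and the 20% intake reduction carry no published
uncertainty and are not sampled.

Each PSA iteration draws one cost and one effect per (intervention,
disorder) pair plus the conversion factor, and evaluates *both* scenarios on
the same draws (common random numbers). This is a deliberate design choice:
it makes a shared intervention cancel exactly from every increment and
isolates the technology difference between the systems. Draw order is fixed
by the sorted (intervention, disorder) keys — all cost vectors, then all
effect vectors, then the conversion factor — so a seed fully determines the
result. Only costs and YLD depend on draws; the mortality side is computed
once per scenario and reused. Default 500 iterations (hard cap 10,000);
a 500-iteration run on the packaged fixtures takes well under a second.

## Fixtures and synthetic data

- `population_nl.csv` — AUDIT-band fractions per gender from a 2009 online
  screening monitor (3,621 participants), applied to 987,000 men and
  267,000 women. Published accounts of this population also carry two other
  totals (993,200 + 222,800; a combined 1,255,000); both are selectable as
  presets (`national`, `combined` — the latter split by the national gender
  ratio). Fractions are stored as proportions; loaders reject values > 1.
- `audit_bands_nl.csv` — band definitions, target RRs, frozen calibrated
  intakes.
- `catalog_nl.yaml` — seven interventions, costs in 2009 euros with
  uncertainty ranges, effects with 95% CIs; costs and effects keyed per
  (intervention, disorder) because intensity differs between bands.
- `scenarios_nl.yaml` — the three modeled coverage mixes.
- `mortality_nl_synthetic.csv` — **synthetic**: Gompertz rates
  `level·exp(slope·age)` with (1.80e-5, 0.1016) for men and (1.40e-5,
  0.0996) for women, ages 18–100, anchored on Dutch 2009 period life-table
  rates around ages 40–60. Remaining life expectancy follows the
  life-table recursion `e(a) = (1 − q(a))·(1 + e(a+1))` with certain death
  past the table end (constant-rate closed form: a truncated geometric sum).
  The table reproduces national *levels* (men's e(45) ≈ 34.8 y) but not
  cohort effects, cause-specific structure, or drinker-specific excess
  mortality beyond the RR model.

The synthetic AUDIT-score generator (multinomial band membership, uniform
scores within band) emulates what a screening monitor would collect; it
reproduces band fractions but not the within-band score shape or any
age/score correlation. Consequently, passing tests demonstrate internal
consistency and faithfulness to the published band-level quantities, not
validity of the fixtures as fresh national statistics.

## Numerical choices and degenerate inputs

- Calibration: Brent root-finding, `xtol = 1e-9`; unattainable targets
  (below the curve minimum or beyond 500 g/day) raise a calibration error
  naming the band.
- Degenerate cost ranges (low = high) and zero-width CIs become point
  masses; a PSA with all distributions degenerate reproduces the
  deterministic run exactly.
- Zero-coverage entries, empty scenarios, and zero-intake strata all yield
  exact zeros rather than errors; a scenario compared with itself returns
  zero increments and an `undefined` ICER.
- Costs, YLD, YLL, and deaths scale exactly linearly in population size.

## Worked-scale results and conventions under ambiguity

Under the default fixtures the deterministic comparison gives: base case
€238.3M / 4,748 DALYs averted; eHealth added €301.2M / 9,627; substitution
€163.6M / 4,858 (dominant). Published accounts of this comparison print
slightly different totals (€233M / €319M / €166M; 5,022 / 10,319 DALYs);
the cost side agrees to within ~2% for the base case and substitution
scenarios, while the eHealth-added total cannot be reconstructed from the
printed per-participant costs and coverages — the €86M printed increment
exceeds the €62.9M the catalog arithmetic yields — so the package reports
the table-derived value. On the burden side the defaults sit 5–7% below the
printed totals and the attenuation switch brackets them from above, which is
the expected behaviour given two genuinely open compositional conventions:
whether the disability-weight shift multiplies covered or adherent persons
(adherent here, per the moderation reading of adherence), and the
years-of-life-lost credited per avoided death (remaining life expectancy at
the death-weighted age, here ≈ 26–30 years, the standard DALY convention).

## Limitations

- One-period steady state: no relapse, no carry-over, no multi-year budget
  impact; benefits of treating severe disorders are therefore understated
  relative to lifetime models.
- All-cause mortality only; no chronic-sequelae (e.g. cirrhosis) morbidity
  beyond the effect-size pathway.
- The 20% intake reduction and 50% adherence are uniform by assumption;
  both are per-entry overridable but carry no uncertainty in PSA.
- The mortality fixture is synthetic; country-specific runs should replace
  it with a national life table (same CSV schema).
- Non-clinical policy levers (taxation, advertising restrictions) are out of
  scope by design.
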