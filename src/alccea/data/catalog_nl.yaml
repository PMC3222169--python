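# Intervention catalog, Netherlands, reference year 2009.
# Per-participant full economic cost in euros (point estimate within an
# uncertainty range) and treatment effect as standardized mean difference d
# with 95% CI, keyed per targeted disorder class because price and intensity
# differ between bands for some interventions.  All interventions assume a
# 20% pre-post reduction of mean pure-alcohol intake.
# fixture_version: nl-2009-v1
interventions:
  - id: brief_f2f
    label: Brief face-to-face intervention
    disorders:
      heavy:
        cost: 58
        cost_low: 52
        cost_high: 75
        d: 0.26
        d_ci_low: 0.20
        d_ci_high: 0.32
      hazardous:
        cost: 58
        cost_low: 52
        cost_high: 75
        d: 0.32
        d_ci_low: 0.23
        d_ci_high: 0.42
  - id: online_brief
    label: Online brief intervention (screening + automated feedback)
    disorders:
      heavy:
        cost: 10
        cost_low: 9
        cost_high: 10
        d: 0.19
        d_ci_low: -0.02
        d_ci_high: 0.40
      hazardous:
        cost: 10
        cost_low: 9
        cost_high: 10
        d: 0.19
        d_ci_low: -0.02
        d_ci_high: 0.40
  - id: behavioral
    label: Behavioral intervention (therapist-guided CBT)
    disorders:
      hazardous:
        cost: 2024
        cost_low: 1702
        cost_high: 2550
        d: 0.34
        d_ci_low: 0.12
        d_ci_high: 0.56
      harmful:
        cost: 2024
        cost_low: 1702
        cost_high: 2550
        d: 0.34
        d_ci_low: 0.12
        d_ci_high: 0.56
      dependence:
        cost: 2024
        cost_low: 1702
        cost_high: 2550
        d: 0.32
        d_ci_low: 0.05
        d_ci_high: 0.59
  - id: online_self_help
    label: Online self-help intervention (CBT-based)
    disorders:
      hazardous:
        cost: 207
        cost_low: 198
        cost_high: 224
        d: 0.31
        d_ci_low: -0.69
        d_ci_high: 1.30
      harmful:
        cost: 207
        cost_low: 198
        cost_high: 224
        d: 0.31
        d_ci_low: -0.69
        d_ci_high: 1.30
  - id: online_therapist_led
    label: Online therapist-led intervention (CBT)
    disorders:
      harmful:
        cost: 764
        cost_low: 227
        cost_high: 1451
        d: 0.58
        d_ci_low: 0.29
        d_ci_high: 0.88
      dependence:
        cost: 1276
        cost_low: 979
        cost_high: 1408
        d: 0.59
        d_ci_low: 0.30
        d_ci_high: 0.90
  - id: detox_acamprosate
    label: Ambulatory detoxification + acamprosate
    disorders:
      harmful:
        cost: 1800
        cost_low: 1620
        cost_high: 2232
        d: 0.21
        d_ci_low: 0.14
        d_ci_high: 0.29
      dependence:
        cost: 1800
        cost_low: 1620
        cost_high: 2232
        d: 0.21
        d_ci_low: 0.14
        d_ci_high: 0.29
  - id: aftercare_aa
    label: Aftercare and rehabilitation (AA, 12 months)
    disorders:
      harmful:
        cost: 500
        cost_low: 250
        cost_high: 750
        d: 0.28
        d_ci_low: 0.20
        d_ci_high: 0.37
      dependence:
        cost: 500
        cost_low: 250
        cost_high: 750
        d: 0.28
        d_ci_low: 0.20
        d_ci_high: 0.37
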