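# Modeled Dutch health-care scenarios: coverage per (disorder, intervention).
#   base_case             current care, no eHealth
#   ehealth_added         current care plus eHealth at additional coverage
#   ehealth_substitution  face-to-face coverage halved, eHealth substituted
# Coverages are fractions of the disorder-class population; adherence is 0.5
# for every intervention unless overridden per entry.
# fixture_version: nl-2009-v1
scenarios:
  base_case:
    - {disorder: heavy, intervention: brief_f2f, coverage: 0.10}
    - {disorder: hazardous, intervention: brief_f2f, coverage: 0.10}
    - {disorder: hazardous, intervention: behavioral, coverage: 0.06}
    - {disorder: harmful, intervention: behavioral, coverage: 0.09}
    - {disorder: harmful, intervention: detox_acamprosate, coverage: 0.05}
    - {disorder: harmful, intervention: aftercare_aa, coverage: 0.05}
    - {disorder: dependence, intervention: behavioral, coverage: 0.05}
    - {disorder: dependence, intervention: detox_acamprosate, coverage: 0.05}
    - {disorder: dependence, intervention: aftercare_aa, coverage: 0.05}
  ehealth_added:
    - {disorder: heavy, intervention: brief_f2f, coverage: 0.10}
    - {disorder: heavy, intervention: online_brief, coverage: 0.05}
    - {disorder: hazardous, intervention: brief_f2f, coverage: 0.10}
    - {disorder: hazardous, intervention: online_brief, coverage: 0.05}
    - {disorder: hazardous, intervention: behavioral, coverage: 0.06}
    - {disorder: hazardous, intervention: online_self_help, coverage: 0.06}
    - {disorder: harmful, intervention: behavioral, coverage: 0.09}
    - {disorder: harmful, intervention: online_self_help, coverage: 0.09}
    - {disorder: harmful, intervention: online_therapist_led, coverage: 0.09}
    - {disorder: harmful, intervention: detox_acamprosate, coverage: 0.05}
    - {disorder: harmful, intervention: aftercare_aa, coverage: 0.05}
    - {disorder: dependence, intervention: behavioral, coverage: 0.05}
    - {disorder: dependence, intervention: online_therapist_led, coverage: 0.05}
    - {disorder: dependence, intervention: detox_acamprosate, coverage: 0.05}
    - {disorder: dependence, intervention: aftercare_aa, coverage: 0.05}
  ehealth_substitution:
    - {disorder: heavy, intervention: brief_f2f, coverage: 0.05}
    - {disorder: heavy, intervention: online_brief, coverage: 0.05}
    - {disorder: hazardous, intervention: brief_f2f, coverage: 0.05}
    - {disorder: hazardous, intervention: online_brief, coverage: 0.05}
    - {disorder: hazardous, intervention: behavioral, coverage: 0.03}
    - {disorder: hazardous, intervention: online_self_help, coverage: 0.03}
    - {disorder: harmful, intervention: behavioral, coverage: 0.03}
    - {disorder: harmful, intervention: online_self_help, coverage: 0.03}
    - {disorder: harmful, intervention: online_therapist_led, coverage: 0.03}
    - {disorder: harmful, intervention: detox_acamprosate, coverage: 0.05}
    - {disorder: harmful, intervention: aftercare_aa, coverage: 0.05}
    - {disorder: dependence, intervention: behavioral, coverage: 0.025}
    - {disorder: dependence, intervention: online_therapist_led, coverage: 0.025}
    - {disorder: dependence, intervention: detox_acamprosate, coverage: 0.05}
    - {disorder: dependence, intervention: aftercare_aa, coverage: 0.05}
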