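# AUDIT-band composition of the Dutch target population of problem drinkers,
# per gender, as observed in an online screening monitor (November 2009).
# Fractions are proportions of each gender's target population and sum to 1.
# fixture_version: nl-2009-v1
gender,band,fraction
men,abstinent,0.001
men,moderate,0.016
men,heavy,0.184
men,hazardous,0.222
men,harmful,0.501
men,dependence,0.076
women,abstinent,0.001
women,moderate,0.036
women,heavy,0.235
women,hazardous,0.235
women,harmful,0.434
women,dependence,0.059
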