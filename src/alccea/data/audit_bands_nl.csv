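# AUDIT score bands of the target population with band-level relative
# risk of all-cause death (rr_*) and the mean pure-ethanol intake
# (grams/day) calibrated so the dose-response curve reproduces each RR.
# fixture_version: nl-2009-v1
label,audit_min,audit_max,disorder_class,rr_men,rr_women,intake_men,intake_women
abstinent,0,1,none,1.0,1.0,0.0,0.0
moderate,2,7,none,0.86,0.96,89.4907,84.9923
heavy,8,15,heavy,0.95,0.99,128.4689,98.9482
hazardous,16,19,hazardous,0.99,1.05,143.4811,124.2585
harmful,20,29,harmful,1.1,1.12,180.2577,150.7855
dependence,30,40,dependence,1.36,1.28,250.5198,203.4562
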