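# CKD-EPI 2012 cystatin C equation (serum cystatin C in mg/L).
equation: ckd_epi_cys_2012
version: 1
intercept: 133.0
knot: 0.8
min_exponent: -0.499
max_exponent: -1.328
age_base: 0.996
female_factor: 0.932
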