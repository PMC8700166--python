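# CKD-EPI 2012 creatinine-cystatin C equation.
equation: ckd_epi_crcys_2012
version: 1
intercept: 135.0
kappa: {female: 0.7, male: 0.9}
alpha: {female: -0.248, male: -0.207}
cr_max_exponent: -0.601
cys_knot: 0.8
cys_min_exponent: -0.375
cys_max_exponent: -0.711
age_base: 0.995
female_factor: 0.969
black_factor: 1.08
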