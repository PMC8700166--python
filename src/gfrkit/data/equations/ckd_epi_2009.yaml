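# CKD-EPI 2009 creatinine equation (serum creatinine in mg/dL).
equation: ckd_epi_2009
version: 1
intercept: 141.0
kappa: {female: 0.7, male: 0.9}
alpha: {female: -0.329, male: -0.411}
max_exponent: -1.209
age_base: 0.993
female_factor: 1.018
black_factor: 1.159
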