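# European Kidney Function Consortium creatinine equation.
# Q is the sex-specific median creatinine of healthy individuals (mg/dL for
# adults); for ages below 25 an age-dependent ln(Q) polynomial (Q in umol/L)
# is used.
equation: ekfc
version: 1
intercept: 107.3
alpha_low: 0.322
alpha_high: 1.132
age_knot: 40
age_base: 0.990
adult_q_mg_dl: {female: 0.70, male: 0.90}
adult_age: 25
# ln(Q[umol/L]) = c0 + c1*age + c2*ln(age) + c3*age^2 + c4*age^3
young_lnq_poly:
  male: [3.200, 0.259, -0.543, -0.00763, 0.0000790]
  female: [3.080, 0.177, -0.223, -0.00596, 0.0000686]
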