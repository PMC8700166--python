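# Metabolite-constellation eGFR equation (myo-inositol, valine, creatinine,
# cystatin C, age, sex).  Piecewise by sex and a sex-specific cystatin C
# cutoff; the cutoff boundary belongs to the upper (">=") branch.
equation: gfr_nmr
version: 1
units:
  creatinine: umol/L
  cystatin_c: mg/L
  valine: umol/L
  myo_inositol: umol/L
  output: mL/min/1.73m2
shared:
  creatinine_exponent: -0.3798
  valine_exponent: 0.1628
  myo_inositol_base: 0.9979
  age_base: 0.9963
pivot_marker: cystatin_c
branches:
  - {sex: female, side: below, cutoff: 1.02, intercept: 238, pivot_exponent: -0.4114}
  - {sex: female, side: at_or_above, cutoff: 1.02, intercept: 239, pivot_exponent: -0.6443}
  - {sex: male, side: below, cutoff: 1.22, intercept: 266, pivot_exponent: -0.5867}
  - {sex: male, side: at_or_above, cutoff: 1.22, intercept: 269, pivot_exponent: -0.6419}
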