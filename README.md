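# gfrkit

Toolkit for estimating glomerular filtration rate (GFR) from serum markers
and for validating eGFR equations against tracer-measured GFR (mGFR).

Kidney function is routinely assessed through estimating equations that map
serum filtration markers — classically creatinine, optionally cystatin C —
plus age and sex onto an estimated GFR in mL/min/1.73 m². Single-marker
equations are biased in many patient groups because every marker has
non-GFR determinants. `gfrkit` implements a multi-marker alternative that
adds two NMR-quantified metabolites, **myo-inositol** (a uremic solute,
inversely related to GFR) and **valine** (depleted by the metabolic
acidosis of CKD, positively related to GFR), to creatinine and cystatin C:

```
eGFR = I(sex, cysC) · cysC^e(sex, cysC) · creat^−0.3798 · valine^0.1628
       · 0.9979^myo-inositol · 0.9963^age
```

a piecewise power law whose intercept `I` and cystatin C exponent `e` switch
by sex and by a sex-specific cystatin C cutoff (1.02 mg/L female, 1.22 mg/L
male): intercepts {238, 239, 266, 269} and exponents {−0.4114, −0.6443,
−0.5867, −0.6419} for female/male below/at-or-above the cutoff. Creatinine,
valine and myo-inositol are in µmol/L, cystatin C in mg/L.

The package also provides:

- the benchmark equations it is compared against — CKD-EPI 2009
  (creatinine), CKD-EPI 2012 (cystatin C), CKD-EPI 2012
  (creatinine–cystatin C) and EKFC — plus Dubois body-surface-area
  normalization and unit conversion (`gfrkit.equations`);
- the clinical validation metrics: median signed bias, IQR precision, MAE,
  RMSLE and 1-P15/20/30 accuracy, with percentile-bootstrap 95% CIs,
  Wilcoxon/McNemar/bootstrap paired tests and Benjamini–Hochberg adjustment
  (`gfrkit.metrics`);
- KDIGO CKD staging (G1–G5 with the G3a/G3b split) and categorical
  net-reclassification (NRI) analysis relative to mGFR-based staging
  (`gfrkit.staging`);
- the equation-development machinery: exhaustive enumeration of constrained
  linear-model formulas over a 10-marker pool (487,008 candidates under the
  default constraints), OLS training with raw or log response, 5×5 repeated
  cross-validation, a configurable KPI deselection pipeline, piecewise
  sex/cutoff model engineering and Vuong model comparison
  (`gfrkit.modelsearch`);
- a seeded synthetic-cohort generator emulating the development study's
  marginals, since no patient-level data are public (`gfrkit.synthetic_cohort`);
- cohort CSV/TSV I/O and a CLI (`gfrkit simulate | estimate | evaluate |
  reclassify | rec-curve | search`).

## Worked example

```python
import gfrkit as g
from gfrkit.reports import evaluate_cohort

# one patient: 50-year-old woman, creatinine 70 µmol/L, cystatin C 0.90 mg/L,
# valine 250 µmol/L, myo-inositol 30 µmol/L
g.estimate_gfr_nmr(50, "F", creatinine=70, cystatin_c=0.90,
                   valine=250, myo_inositol=30)      # -> 94.9
g.estimate_ckd_epi(50, "F", creatinine=70, cystatin_c=0.90,
                   variant="crcys2012")              # -> 87.0
g.ckd_stage(58.3)                                    # -> 'G3a'

# benchmark two equations on a synthetic cohort with known mGFR
cohort = g.generate_cohort(g.GeneratorConfig(n=600, seed=42))
metrics, comps = evaluate_cohort(cohort, ["gfr_nmr", "ckd_epi_2012"],
                                 n_boot=1000, seed=0)
```

The metrics table (here filtered to three indicators) looks like:

```
    equation subgroup      metric          unit  estimate  ci_low  ci_high   n
     gfr_nmr  overall median_bias mL/min/1.73m2       8.1     7.5      8.7 600
     gfr_nmr  overall         mae mL/min/1.73m2      10.1     9.5     10.7 600
     gfr_nmr  overall outside_p30             %      15.7    13.0     18.5 600
ckd_epi_2012  overall median_bias mL/min/1.73m2      -0.6    -1.3      0.1 600
ckd_epi_2012  overall         mae mL/min/1.73m2       7.3     6.7      7.8 600
ckd_epi_2012  overall outside_p30             %       3.3     1.8      4.8 600
```

`median_bias` is the median of eGFR − mGFR (negative = underestimation),
`mae` the mean absolute error, and `outside_p30` the percentage of samples
whose estimate misses mGFR by more than 30%, each with a percentile-
bootstrap 95% CI. On this synthetic cohort the marker–GFR links are
invented, so the ranking of equations carries no clinical meaning — see
`docs/methods.md`.

The same workflows are available from the shell, e.g.

```sh
gfrkit simulate --n 600 --seed 42 --out cohort.csv
gfrkit evaluate cohort.csv --equations gfr_nmr,ckd_epi_2012 --out metrics.csv
gfrkit reclassify cohort.csv --new gfr_nmr --comparator ckd_epi_2009 --out nri.csv
```

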