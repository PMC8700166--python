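# Methods

This note documents the models, conventions and design choices behind
`gfrkit`, in the order of the module stack.

## Estimating equations

All equations are multiplicative power laws evaluated on unrounded inputs
and returning unrounded mL/min/1.73 m²; rounding happens only when reports
are serialized. Coefficients are shipped as versioned YAML documents
(`src/gfrkit/data/equations/`) so that printed values are data, not code.

**Piecewise metabolite equation (`gfr_nmr`).** Four branches — sex × side
of a sex-specific cystatin C cutoff (1.02 mg/L female, 1.22 mg/L male) —
share the creatinine exponent (−0.3798), valine exponent (0.1628) and the
per-unit decay bases for myo-inositol (0.9979 per µmol/L) and age (0.9963
per year); the intercept and cystatin C exponent are branch-specific. A
cystatin C value exactly at the cutoff takes the upper ("≥") branch.
Because the printed coefficients are rounded, the two branches do not meet
exactly at the cutoff; the property suite checks they agree within 0.5%
relative there rather than assuming continuity.

**Units.** The canonical internal creatinine unit is µmol/L (the
metabolite equation's unit); the CKD-EPI and EKFC equations are published
in mg/dL and convert internally with the molar-mass factor 88.42. Estimates
are never capped, and the CKD-EPI race coefficients are retained exactly as
published (defaulting to non-black when the flag is absent); the 2021
race-free CKD-EPI refit post-dates this comparison set and is out of scope.

**EKFC rescaling constant Q.** Adults (≥ 25 y) use the sex constants
0.70/0.90 mg/dL. For ages 18–25 the published age-dependent ln(Q)
polynomial (in µmol/L) is used; it lands within ~1.5% of the adult
constants at age 25, so the small discontinuity there is accepted rather
than smoothed.

**Missing inputs** raise a named missing-marker error rather than falling
back to another equation; fallback is a workflow decision, not an equation
property.

## Validation metrics

Errors are `d = eGFR − mGFR`, so underestimation is negative. Quantiles
(median, IQR) use type-7 linear interpolation — the default of the
statistical environments this field works in. "Within x%" is boundary
inclusive: |d| exactly equal to x% of mGFR counts as within. Accuracy is
reported as 1-Px (percentage *outside* tolerance); the REC curve is its
complement over a tolerance grid. RMSLE uses the ln(1+·) form; it is
reported but no published reference value exists to pin it against.

Confidence intervals are percentile bootstrap over whole resampled pairs
(default 1000 replicates, seeded). Replicates on which a statistic is
undefined are skipped with a warning; more than 10% skipped is an error.
Paired comparisons: Wilcoxon signed-rank on signed-error differences for
bias (a flag switches to |error| differences, since either reading of
"bias" is defensible) and on |error| differences for MAE; McNemar with
continuity correction on the within/outside indicators for P15/P20/P30 (an
exact-binomial variant sits behind a flag); and a doubled one-sided
bootstrap crossing fraction for the IQR difference. Benjamini–Hochberg
adjustment is applied across the pairwise equation comparisons within each
indicator.

For eGFR-range stratified reporting each equation is binned by **its own**
estimate, so per-range n differs between equations by construction.

## Staging and net reclassification

KDIGO G-stages partition (0, ∞) as G1 [90, ∞), G2 [60, 90), G3a [45, 60),
G3b [30, 45), G4 [15, 30), G5 (0, 15), applied to unrounded values (no
statement exists that estimates were rounded before staging, so they are
not). Reclassification strata are defined by the mGFR-based stage: the
published per-stratum sample counts match the mGFR stage distribution of
the external cohort exactly, which pins down that reading of the table
header.

The NRI is reported in two flavours. `nri_printed_style` — the difference
of the correct and incorrect percentages after each is rounded to one
decimal — is the primary figure because it reproduces every published NRI
value, including the stratum where the exact ratio rounds differently
(54/214 − 22/214: printed convention 25.2 − 10.3 = 14.9, exact 15.0).
`nri_exact` = 100·(correct − incorrect)/n is always reported alongside.
Samples where both equations stage wrongly but differently are counted
separately (`both_wrong_discordant`) rather than folded into either side;
the published totals equal correct + incorrect, consistent with this.

## Equation search

The search space is every linear model over a marker pool (default: nine
NMR metabolites plus cystatin C) where each marker enters raw or
natural-log transformed, under four constraints: 2–5 features; at most one
interaction; an interaction must anchor on a main-effect parameter; and no
parameter appears under two transforms in one model. An interaction is the
product of two transformed features of *distinct* parameters — squares are
excluded by default (parameters, not features, are the unit of identity in
the one-transform rule), with a toggle for sensitivity analysis. Each
formula structure is trained twice, with raw and with log response.

Under these constraints the closed-form count for the 10-marker pool is
**487,008** (verified against brute-force streaming); the published
candidate total is 487,408, a 0.08% gap that no tested reading of the
constraints reproduces exactly (self-interactions at specific sizes, extra
response options and alternative interaction-transform conventions were
tried). Both the count and the enumeration stream are exposed so other
interpretations can be tested via the constraint config.

Fitting is ordinary least squares; log-response predictions are
back-transformed by plain exponentiation without smearing correction (the
final equation is a plain product form, indicating no bias correction was
applied). All KPIs — MAE, P15/P20/P30, heteroscedasticity (|Spearman| of
|residual| vs fitted), upper-range reach (fraction of mGFR ≥ 90 samples
predicted ≥ 90) — are computed on the GFR scale. Cross-validation is
5-times repeated 5-fold with seeded unstratified shuffling (a stratified
option exists); the stability KPI is the coefficient of variation of the
25 fold MAEs.

Candidate screening is an ordered, configurable rule pipeline with an audit
log, covering the deselection classes used during equation development:
error/accuracy thresholds, CV stability, upper-range reach,
heteroscedasticity, and redundancy pruning (within groups sharing ≥ k
features, candidates dominated on both MAE and P20 are dropped). The
original screening used 14 + 8 expert-guided, data-dependent steps whose
thresholds are not public; they are deliberately **not** hard-coded — the
shipped `default_filter_rules()` are package defaults for synthetic
cohorts, and every threshold is configurable.

Piecewise engineering refits a candidate as one joint OLS on the log scale
in which branch indicators (sex × cutoff side) interact with the intercept
and the log-pivot term only, all other coefficients being shared — the
joint-fit reading is supported by the identical shared coefficients across
the published branches. The Vuong test uses the classical statistic
√n·mean(ℓᵃ−ℓᵇ)/sd(ℓᵃ−ℓᵇ) with Gaussian pointwise log-likelihoods from the
OLS residual variance, two-sided against N(0,1); identical likelihood
vectors are reported as undefined/non-significant with a warning.

## Synthetic cohorts

No patient-level data are public, so two seeded generators make the
toolkit exercisable:

1. **Marginal-emulating cohorts** (`generate_cohort`): mGFR ~ truncated
   normal 67 ± 28 on (3, 183); age 56 ± 14 on (18, 88); 55% male; BMI
   30 ± 6 with sex-specific stature; markers via lognormal links
   ln(marker) = a + b·ln(mGFR) + c·male + ε with the observed
   directionality (creatinine, cystatin C, myo-inositol negative; valine
   positive). The link coefficients are **invented package choices**,
   anchored so typical healthy values appear near mGFR 90 (creatinine
   ≈ 80 µmol/L male, cystatin C ≈ 0.9 mg/L, myo-inositol ≈ 30 µmol/L,
   valine ≈ 240 µmol/L) with log-scale noise of 0.12–0.20; the true joint
   marker–GFR distribution was never published. Consequently tests on
   these cohorts validate *mechanics* (shapes, conventions, invariances),
   never the clinical performance ranking of equations, and the published
   patient-level result tables are not numerically reproducible here.
   Liver disease and clinical indication exist as inert labels for
   stratified partitioning only. Truncation uses rejection sampling with a
   resample cap (error past the cap).

2. **Equation-generated cohorts** (`generate_equation_cohort`): markers
   drawn independently from wide lognormal marginals (cystatin C straddles
   both sex cutoffs), then mGFR = equation(markers)·exp(ε) with
   ε ~ N(0, σ_log²). These have known ground truth; refitting the
   equation's structure must recover every exponent and base, which closes
   the loop between generator, fitter and evaluator.

Stratified partitioning allocates rows within each stratum cell by seeded
shuffle and largest-remainder rounding (per-cell deviation ≤ 1 row).

## Problem sizes and numerical choices

Parameter recovery uses n = 2000 at σ_log = 0.1 with a 3-standard-error
acceptance band per coefficient; bootstrap calibration uses 200 cohorts of
n = 100 at 1000 replicates (binomial noise on the coverage estimate at
that size is about ±1.5%, so the acceptance band is 95% ± 4%). The
bootstrap IQR test doubles the one-sided crossing fraction and caps at 1.
The Spearman heteroscedasticity score falls back to 0 on degenerate
(constant) inputs. All seeded randomness flows through
`numpy.random.default_rng` / `SeedSequence`, so every workflow is
bit-reproducible given its seed.

## Known limitations

- The published cohort-level performance tables and subgroup analyses can
  only be reproduced structurally, not numerically, without the patient
  data.
- The screening pipeline reproduces the *classes* of deselection rules,
  not the expert-chosen thresholds of the original 14 + 8 steps.
- The 400-candidate discrepancy in the search-space count is documented
  but unresolved.
- The BH step-up adjustment is order-preserving and dominates its input
  but is not idempotent in general; no idempotence is claimed or tested.
- Equation inputs below age 18 warn (the equations target adults) but are
  not refused.
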