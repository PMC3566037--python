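# Methods

## The statistical procedure

All analysis variables live on a common dimensionless scale. Measurements
with an external reference (weight and length at birth, weight and height
in childhood, blood pressure) become standard deviation scores (SDS)
through the LMS transform: for reference skewness L, median M and
coefficient of variation S at the child's age and sex,

    z = ((x/M)^L − 1) / (L·S)        L ≠ 0
    z = ln(x/M) / S                  L = 0

with L, M, S interpolated linearly in age and no extrapolation beyond the
reference grid (an out-of-range age is an error — silent clamping would
distort the tails). `|L| < 1e-7` uses the log-limit branch; the general
branch is numerically unstable there. The inverse transform
(`zscore_to_value`) is exact to 1e-9 and is what the generator uses to
back-construct raw measurements.

Within-sample constructs use standardised regression residuals (SRR).
Within each sex stratum, the (regressor, outcome) pairs are screened for
multivariate outliers, a least-squares line is fitted to the retained
records, and residuals are divided by their SD (denominator n−1; a pooled
across-strata SD is available as an option, since "the single standard
deviation of the unexplained residuals distribution" can be read either
way — the within-stratum reading is the default, consistent with the
sex-stratified regressions). An SRR therefore has stratum mean 0, SD 1 and
zero in-sample correlation with its regressor; conditional weight/height
velocity (CWV/CHV) is the SRR of the 7-year SDS on the birth SDS.
Children flagged at any screen are excluded from the analysis entirely and
recorded, step by step, in an exclusion ledger.

Pulse pressure is per-record systolic minus diastolic BP, converted to SDS
against its own reference.

Model suites, per BP outcome (systolic, diastolic, pulse-pressure SDS):
sex-stratified OLS — a load suite (height z; height z + Wr/H; height z +
LMr/H + FMr/LM) and a growth suite (load-only; birth-weight z + CWV; all
five jointly) — with normal-based Wald 95% CIs (β ± 1.959964·SE; the
samples are large enough that the t/normal distinction is immaterial,
matching large-n practice). The logistic suite pools the sexes with a
male-sex indicator and models "higher BP", defined as SDS at or above the
external reference's 95th centile (Φ⁻¹(0.95) = 1.6449 on the z scale; the
threshold is inclusive, and the external-reference centile — not the
sample's own 95th percentile — is the default, with the sample-percentile
mode available for sensitivity). A pooled sex × LMr/H interaction check is
reported alongside.

## Hadi's forward search

The screen at each residualisation step is Hadi's multivariate forward
search on the bivariate (regressor, outcome) scatter:

1. distances from the coordinate-wise median, scaled by the covariance of
   deviations from it; the nearest half of the records then furnishes a
   robust mean/covariance and distances are recomputed;
2. the p+1 cleanest records seed the basic subset, which grows one record
   at a time (re-estimating mean/covariance and re-ranking all records)
   until it holds h = ⌊(n+p+1)/2⌋ records;
3. growth then continues under the outlier test: with the subset covariance
   inflated by cf = 1 + (p+1)/(n−p) + 2/(n−1−3p) (the last term dropped
   when n ≤ 3p+1, where it is non-positive), the subset keeps absorbing
   the nearest record while its squared distance is within the
   chi-square(p) quantile at 1 − α/n; when the nearest outside record
   fails, everything beyond the cutoff is flagged.

Continuing past the half sample is essential for calibration: tested
against the raw half-sample covariance, clean Gaussian data would have
~4–5% of records flagged per screen (the central-half covariance
underestimates scale roughly threefold); with the continued search the
subset absorbs essentially all clean data, so the test is effectively a
Bonferroni-style check against the full-sample covariance and the expected
number of false flags per dataset is of order α. Defaults: α = 0.05,
bivariate screens at each step (whether the original screens were run on
the scatter or on residuals is not documented; the scatter is the natural
reading). Distance ties are broken by record index, so runs are
bit-reproducible. The coordinate-wise median start is not exactly
affine-equivariant, but after re-estimation the flags are stable under
affine maps in practice, and this is property-tested with random
nonsingular transforms.

## The synthetic-cohort generator

Per sex, on the z/SRR scale (every structural variable unit-variance):

    BWz ~ N(0,1)                      capacity
    CWV ~ N(0,1) ⟂ BWz                postnatal growth
    Hz  = b_H·BWz + a_H·CWV + e_H     height load
    LMr = b_L·BWz + a_L·CWV + e_L     relative lean load
    FMr = T(g_F·CWV + e_F)            relative fat load (no BWz path)
    BPz = β_H·Hz + β_L·LMr + β_F·FMr + β_C·BWz + e_BP

T is a standardised lognormal transform making relative fat right-skewed
and bounded below (shape σ = 0.35, skewness ≈ 1.3 — childhood adiposity is
right-skewed, and a Gaussian fat construction would put several percent of
fat-mass values below zero at the calibrated moments). The Gaussian
loading g_F is solved so cov(FMr, CWV) equals the configured a_F exactly,
which keeps the covariance algebra — and therefore the coefficient oracle —
exact despite the skew. The σ default balances two pipeline distortions
that act as selection on a variable correlated with CWV and the BP
residual: positivity clipping of back-constructed fat mass (worse at low
σ) against over-flagging of the lognormal tail at the FMr/LM screen
(worse at high σ); at 0.35 the residual end-to-end bias on the growth
coefficients is below 0.01.

CWV is fully mediated by the three load variables by default (no direct
CWV → BP path; a knob exists for partial mediation), which is why the
joint-model CWV coefficient is exactly zero in expectation. Systolic and
diastolic BP have separate coefficient vectors; the diastolic defaults
(β_H 0.12, β_L 0.02, β_F 0.13, β_C −0.04) are the printed diastolic
values, and their residuals are correlated with the systolic ones at the
value solved from the calibration SDs via var(PP) = var(SBP) + var(DBP) −
2·cov (0.557 male, 0.575 female), so the pulse-pressure SD lands on its
anchor.

**Calibration.** `calibrate_default_config` fixes the systolic load
coefficients (β_H 0.30, β_L 0.20, β_F 0.25 — systolic-sized versions of
the diastolic pattern) and the lean/fat loadings (a_L 0.55, a_F 0.50,
b_L 0.20), then solves the rest exactly from the headline systolic
targets:

    β_C = conditional birth-weight coefficient     (−0.10 m / −0.09 f)
    a_H = (marginal CWV − β_L·a_L − β_F·a_F)/β_H   (targets 0.40 / 0.44)
    b_H = (marginal BWz − β_C − β_L·b_L)/β_H       (targets 0.00 / 0.03)

The male marginal birth-weight null is therefore an exact cancellation of
the direct (negative) and mediated (positive) capacity paths. Two
consistency checks fall out rather than being fitted: the implied
growth-only model r² is 0.16 (male) and 0.19 (female), matching the ~15%
and ~17% systolic variance the growth models explain, and the implied
diastolic marginal coefficients (≈0.14 CWV, ≈−0.01 BWz) match the printed
diastolic growth model.

`implied_coefficients` is the analytic oracle: the expected large-n OLS
coefficients of any predictor subset solve Σ_pp b = Σ_py on the exact DAG
covariance. Tests assert fitted ≈ implied, so the generator and the
pipeline check each other through two independent routes.

**Raw-scale back-construction.** Raw columns invert the pipeline's own
definitions: SDS invert through the reference tables at each child's
drawn age (gestational age N(39.4, 1.8)/N(39.6, 1.7) weeks clipped to the
grid; visit ages N(89.7, 2.1) and N(118.5, 3.9)/N(118.4, 3.9) months);
lean mass = anchored height regression + scaled LMr; fat mass likewise on
lean; weight at 9 y = lean + fat + a constant residual-mass offset that
closes the calibrated weight mean (and, emergently, its SD). The anchor
slopes and residual scales are solved in closed form from the joint sample
moments of the conditioning variable and the planted residual — the two
are correlated through the DAG, so independent scaling would inflate the
lean/fat SDs well above their calibration values. Raw-scale targets are
the per-sex means/SDs of the emulated analytic sample (e.g. male SBP
102.5 ± 9.0 mmHg, lean 25.5 ± 2.9 kg, fat 7.3 ± 4.6 kg); target
correlations lean–height 0.7 and fat–lean 0.6. Back-constructed fat below
0.2 kg is clipped there and counted (~1–2% at the default skew).

**Contamination.** Gross outliers replace a configurable 0.3% of records:
one of the screened measurement pairs is displaced 8–15 column-SDs in a
random direction (floored at 0.05 to stay positive), with truth flags
retained so detection can be scored. Item-level missingness is MCAR per
column at the emulated completeness rates (birth weight 1.1%, birth length
20%, 7-year weight/height ~11%). A planted-logistic mode draws a binary
higher-BP outcome directly from a configured log-odds structure on the
structural variables, for odds-ratio recovery experiments.

**What the generator does not emulate:** real referencing (the synthetic
references are centred on the cohort, so SDS means are ~0, unlike a real
cohort scored against an external population, and higher-BP prevalence is
~5% rather than the ~2.4% a shifted reference gives), heteroskedastic
DXA measurement error, sibling/clustering structure, informative
missingness, and secular trends within the reference grid. Passing tests
therefore demonstrate that the pipeline recovers a planted capacity–load
structure under realistic moments, skew, contamination and missingness —
not that any particular real cohort satisfies the model.

## Known numerical and design choices

* Birth z-scores are gestational-age-adjusted when gestational age is
  present, else scored at term (40 wk) with a logged warning; a
  term-only mode exists because it is not documented whether the original
  birth z-scores were gestation-adjusted.
* Exclusions are sequential (body-composition screens, then velocities),
  and flagged children are removed from all subsequent analysis; earlier
  SRRs are not recomputed after later exclusions, so final-sample SRR
  moments can drift from (0, 1) by a few removed records — the exact
  invariants hold on each SRR's own fitted sample.
* On the derived route, the pipeline re-residualises lean on *raw* height
  and fat on *raw* lean, which re-parameterises the load block within the
  same column span: growth-model coefficients (BWz, CWV) are
  span-invariant and recover the planted values; the load coefficients
  individually do not (they are recovered on the truth columns instead).
* Residual end-to-end biases on the growth coefficients (~0.005) come
  from outlier-screen selection and SRR restandardisation after
  truncation; they are measured by the recovery tests and sit within the
  0.01 acceptance band.
* Degenerate inputs error loudly: zero regressor variance and exact
  outcome–regressor collinearity raise degenerate-fit errors; singular
  screen covariances raise degenerate-geometry errors naming the columns;
  rank-deficient designs raise collinearity errors; logistic separation
  and single-class outcomes are distinct errors.
* Problem sizes: the test suite fits 50 cohorts of 3,000 per sex for the
  recovery and reversal checks, 40 null-configuration cohorts of 600 per
  sex for the type-I-error check, and single cohorts of 2,500 per sex for
  the logistic recovery; `scripts/acceptance.py` uses 50 × 3,000/sex.
  These sizes put Monte Carlo SEMs of the seed-averaged coefficients near
  0.003, an order below the quantities of interest.
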