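# Methods

This note documents the models, conventions and numerical choices behind
`pmet`, and what the synthetic-data tests do and do not demonstrate.

## Multilevel (paired) design

For a patient measured at a reference timepoint (vector `a`) and a
comparison timepoint (vector `b`), the multilevel transformation emits
the two mirrored rows `(a − b, +1)` and `(b − a, −1)`.  Between-patient
variation cancels exactly, classes are balanced by construction, and
classifying the mirror pairs is a multivariate analogue of the paired
*t*-test.  Patients missing either timepoint are excluded from the
multivariate arm and listed on the dataset object; the univariate mixed
models retain them.  A minimum of 6 complete patients is required.

## OPLS-DA

The fit is NIPALS-style with exactly one predictive component (a
two-class problem needs no more) and `n_orth` orthogonal components
selected by cross-validation.  Each orthogonal round computes

    w  ∝ Xᵀy (unit norm),  t = Xw,  p = Xᵀt/(tᵀt),
    w₀ ∝ p − (wᵀp)w (unit norm),  t₀ = Xw₀,  p₀ = Xᵀt₀/(t₀ᵀt₀),
    X ← X − t₀p₀ᵀ,

and the predictive component is then fitted on the deflated matrix.  By
construction every orthogonal score is exactly uncorrelated with `y`
(on centered data with balanced labels) and the orthogonal scores are
mutually orthogonal; both are asserted in tests at 1e-8.  Prediction
scales new data with the training recipe, strips the stored orthogonal
components sequentially, projects on `w`, and assigns
`sign(score · q)` with zero mapped to +1.

Scaling default is autoscaling (mean-centering plus unit variance),
configurable to centering only.  Autoscaling is the common choice for
mixed metabolite panels whose variables live on different scales; the
choice is explicit in every API and the CV refits it inside each
training fold.  Zero-variance columns are centered, flagged, and left
undivided.

VIP scores: with a single predictive component carrying all the
explained y-variance (orthogonal components carry none), the general
VIP formula reduces to `VIP_j = sqrt(p_vars) · |w_j|`, so mean(VIP²) = 1
exactly; this identity is asserted on every fitted model.

## Cross-validation and component selection

Folds partition *patients*, never rows, so mirror pairs always travel
together; an assertion inside the CV loop guards this on every fold.
Defaults are 10 folds and 20 random fold assignments (iterations).  For
unpaired designs (weight-gain prediction) fold assignment is stratified
by class to keep folds balanced.  Per-iteration sensitivity and
specificity are pooled over folds and averaged over iterations;
classification error is `1 − (sens + spec)/2`, which equals the raw
error rate under the balanced multilevel design.

The orthogonal-component count is the first local minimum of the mean
error curve: the smallest index whose error is no worse than its left
neighbour and strictly better than its right neighbour; plateaus
resolve to their leftmost index (fewer components), and a monotonically
decreasing curve yields the last index.  If the residual rank runs out
inside a fold, deeper levels reuse the last available prediction.

## Permutation test

The permutation scheme preserves the design.  Paired data: each
patient's mirror pair keeps or flips its +1/−1 assignment at random
(shuffling rows independently would break the antisymmetry and inflate
the null).  Unpaired data: patient labels are shuffled across patients.
Each permutation reruns the complete CV including component selection
(a flag can pin `n_orth` instead); `p = (#permuted ≥ observed)/n_perm`,
and an observed accuracy exceeding every permutation is reported as
`< 1/n_perm`.  This plain proportion (not `(b+1)/(n+1)`) is the
documented convention of the result object; with ties counted toward
rejection it is slightly conservative, which the calibration test
confirms (rejection rate ≈ 0.04–0.05 at the 0.05 level on null data).

Seeding: one user seed drives a `SeedSequence` that spawns separate
streams for the observed CV, the permutation labels and each
permutation's CV, so results are reproducible and independent of
execution order.

## NMR preprocessing

Order: referencing → baseline → water excision → normalization →
integration; the chain is idempotent.

* Referencing detects the alanine doublet in 1.40–1.55 ppm as two local
  maxima above `median + 5·MAD` of the window, separated by 0.005–0.03
  ppm, and shifts the axis so the left (higher-ppm) peak sits at
  1.47 ppm.  Injected offsets up to ±0.05 ppm are recovered to within
  one axis step.
* Baseline correction subtracts the spectrum minimum (lowest point to
  zero); residual curvature is deliberately left alone — the emulated
  workflow used exactly this rule.
* All windows are closed intervals: a point at 4.33 or 5.13 ppm belongs
  to the excised water region, and the 0.29/8.53 ppm bounds belong to
  the normalization region.  The convention is arbitrary but fixed for
  reproducibility.
* Normalization divides by the trapezoidal area over retained
  (non-water) points in 0.29–8.53 ppm, targeting area 1 (the target
  constant is arbitrary; 1 was chosen).
* Integration is plain trapezoidal on the normalized intensities — no
  lineshape fitting.  Metabolites with several windows either average
  them (`mean`) or use the designated lowest-index window (`single`,
  the resonance with minimum overlap).  The 30-region table ships as
  editable CSV configuration; only the two lipid windows are fixed by
  convention, the rest use textbook shifts spaced ≥ ~0.05 ppm so the
  synthetic regions stay resolvable.  A truncated unit Lorentzian of
  HWHM γ inside a half-width-d window integrates to (2/π)·arctan(d/γ),
  the oracle used by the integration tests.

## Targeted-MS QC

Rule order is fixed: 100× masking → 30% filtering → LOD/2 imputation;
the chain is idempotent and never drops rows.

* The 100× outlier rule is strict (`> 100 × median`); the median is
  computed over observed entries so spikes cannot raise their own
  threshold.
* The 30% rule pools missing with below-LOD fractions (`> 0.30`
  excludes); both fractions are reported separately in the QC report so
  the alternative per-category reading can be audited.  A column at
  exactly 30% survives.
* Below-LOD cells are an explicit censored state until imputation
  replaces them by LOD/2 — never earlier, so the rule is owned by one
  stage.
* CoV on pooled QC replicates uses the sample (n−1) standard deviation,
  with flags at 15% and 25%.
* Residual missing cells (MCAR missingness and masked spikes) are
  median-imputed by `impute_missing_median` for the multivariate arm
  only; the mixed models consume the unimputed block, since tolerating
  missing visits is their purpose.

## Univariate arm

* `lmm_time_effect`: natural-log concentrations, fixed categorical
  timepoint + random per-patient intercept, REML, Wald test on the time
  coefficient.  This is the minimal mixed model matching a
  baseline-vs-follow-up trend with missing-visit tolerance; covariate
  adjustment is out of scope.  On balanced complete data the estimate
  equals the mean within-patient log difference (asserted at 1e-8).
  Degenerate inputs (zero within-patient variability) return the paired
  estimate with p = 1 and a flag instead of a failed REML fit; the
  optimizer falls back from the default BFGS to Powell before declaring
  a convergence error.
* `wilcoxon_signed_rank` (lipoprotein convention): zeros dropped, ties
  mid-ranked, exact null for n ≤ 25 untied differences, normal
  approximation with continuity correction otherwise.
* `fisher_exact_2x2`: two-sided point-probability rule with a 1 + 1e-7
  tie tolerance and the conditional-MLE odds ratio; verified against an
  exhaustive hypergeometric enumeration for all tested tables (N ≤ 40).
* `two_sample_t`: pooled variance by default (Welch optional); group
  levels are ordered lexically so the statistic's sign is deterministic.
* `fdr_bh`: Benjamini–Hochberg step-up, applied within each named data
  block (MRS, MS, lipoproteins) separately — q-values in one block never
  depend on another block.
* Friedewald LDL `tc − hdl − tg/2.2` (mmol/L) refuses tg ≥ 4.5.
* Weight gain: Δ(6 mo − baseline) ≥ 1.5 kg, boundary inclusive; missing
  6-month weight → `unknown`, excluded downstream.
* Log transforms use the natural log throughout; the base only scales
  estimates.

## Synthetic cohort generator

The generator's defaults encode the emulated study design: 60 patients
(35 chemotherapy / 25 not), timepoints 0/6/12 months, 8 patients without
a 6-month weight and 17 gainers among the remaining 52, MS data for 53
patients at 0/6 months, and 48 of 188 MS metabolites failing the
missing/LOD rule (leaving 140).  Group sizes follow `round(n·fraction)`
exactly.

Concentrations are log-normal with per-(patient, variable) random
intercepts: `log x = log μ_j + b_ij + δ_j(group, t) + ε`, where the
intercept and residual variances are set from the configured intraclass
correlation (default ICC 0.5) and total log-SD (default 0.4) — the
underlying study reports no variance components, so these are free,
documented parameters of the generator, chosen as typical for serum
metabolite panels.  Effects are additive on the natural-log scale
(matching the log-transform used in the analysis); the default effect
registry plants the kynurenine rises of 38% (chemotherapy) and 25%
(no chemotherapy) at 6 months.

Weight-gainer status is assigned first and the 6-month weight change
drawn from the matching side of the 1.5 kg threshold (gainers:
1.5 + |N(0, 2)|; non-gainers: 1.4 − |N(0, 2.2)|), with a post-rounding
guard so the 0.1 kg weight rounding can never move a patient across the
threshold.

Below-LOD censoring uses a per-column LOD at a configurable quantile of
the baseline log-normal distribution (2% for reliable columns, 50% for
the designated low-quality columns, which puts them far beyond the 30%
rule on ~100 samples).  MCAR missingness (2%) and instrumental spikes
(0.5%, drawn uniformly at 150–500× the column median, safely beyond the
100× rule) complete the quality problems.  Every censored cell, missing
cell, spike and effect is recorded in the truth ledger.

The lipoprotein panel defines 105 four-letter codes from the grammar
{TP, V1–V5, ID, L1–L6, H1–H4} × {TG, CH, FC, PL, A1, A2, AB}: apoA
parameters are not resolved for VLDL subfractions and apoB is absent
from HDL, which yields exactly 105 names; VLDL-6 is excluded as
unreliable.  Correlation comes from latent per-sample factors (one
global lipemia factor, loading 0.35 of the residual SD, plus one factor
per density class, loading 0.75), so within-class correlations (~0.35)
exceed between-class ones (~0.07).  The exact membership of the panel
and the per-code means are synthetic conventions, not measured values.

Spectra are sums of Lorentzian peaks (areas proportional to
concentrations) on a descending 32k-point axis over −0.5…10 ppm, plus a
residual water hump inside 4.33–5.13 ppm, a smooth positive baseline, a
per-sample global shift offset (clipped normal, SD 0.015 ppm) and white
noise.  The peak table uses textbook chemical shifts keyed to the
30-region integration table, with the alanine doublet split by
0.012 ppm so the reference detector has a realistic target.

## What the synthetic tests do not show

The generator emulates the *design*, not the biology: real serum spectra
have overlapping multiplets, ppm-dependent lineshapes and baseline
artefacts far beyond a Lorentzian sum; real MS missingness is
concentration-dependent rather than MCAR; real lipoprotein covariance is
richer than a two-level factor model; and treatment effects touch
correlated pathways, not independent columns.  Passing tests therefore
demonstrate that the statistical machinery is correct and calibrated
under the stated model — not that the pipeline would reach any
particular accuracy on real cohorts.  The emulated study's own headline
numbers cannot be reproduced because its serum data were never
deposited; the power check is a qualitative analogue at matched design
size.

## Problem sizes used in the test suite

Oracle and invariant tests run on instances of 10–60 rows.  Calibration
uses 200 null datasets (40 patients × 50 variables) with 99
permutations over a reduced CV (1 iteration, max 1 orthogonal
component); parameter recovery uses 100 cohorts of 500 patients for the
mixed model and one 500-patient cohort for the ICC; the power analogue
uses the full design size (35 patients, 140 surviving metabolites,
10×20 CV, 199 permutations).  These sizes keep the whole suite around
two minutes on one CPU while leaving every tolerance at its stated
value.
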