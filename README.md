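# pmet — paired longitudinal serum metabolomics

`pmet` analyses longitudinal two-timepoint metabolomics studies in which
each patient is measured before and after a treatment period, and the
question is whether the metabolite profile *within* patients changed —
for example, serum profiles of breast-cancer patients at baseline and 6
and 12 months after surgery, measured by NMR spectroscopy (MRS),
targeted mass spectrometry (MS) and an NMR-derived lipoprotein
subfraction panel.

It provides, as a tested library plus a thin `pmet` CLI:

* **Multilevel OPLS-DA** — the paired multivariate analysis.  With
  baseline matrix *A* and follow-up matrix *B*, each patient contributes
  the mirrored rows *A−B* (label +1) and *B−A* (label −1); discriminating
  the two classes is a multivariate analogue of the paired *t*-test.
  OPLS-DA is fitted NIPALS-style: each orthogonal round takes
  *w ∝ Xᵀy*, *t = Xw*, *p = Xᵀt/(tᵀt)*, extracts the *y*-orthogonal
  loading direction *w₀ ∝ p − (wᵀp)w* and deflates *X* by *t₀p₀ᵀ*; one
  predictive component is then fitted on the deflated matrix.  Variable
  influence is summarized by VIP scores (mean of squared VIPs is 1 by
  construction).
* **Validation** — patient-grouped 10-fold cross-validation with 20
  random fold assignments; the orthogonal-component count is the first
  local minimum of the mean classification error
  (error = 1 − (sensitivity + specificity)/2); significance comes from a
  pairing-preserving permutation test (per-patient sign flips) with
  *p* = (#permuted ≥ observed)/n_perm.
* **NMR preprocessing** — chemical-shift referencing to the left peak of
  the alanine doublet at 1.47 ppm, baseline-to-zero correction, excision
  of the residual water region (4.33–5.13 ppm), total-area normalization
  over 0.29–8.53 ppm, and trapezoidal integration of 30 configurable
  metabolite regions (including the lipid1 0.8–0.9 ppm and lipid2
  1.55–1.60 ppm signals).
* **Targeted-MS QC** — entries above 100× the metabolite median masked
  as missing, metabolites with more than 30% missing/below-LOD entries
  excluded, below-LOD values imputed as LOD/2, and CoV monitoring of
  pooled QC replicates.
* **Univariate arm** — random-intercept linear mixed models (REML) on
  log concentrations for time trends, Wilcoxon signed-rank tests for
  the non-normal lipoprotein subfractions, two-sample *t* and Fisher's
  exact tests for cohort tables, Benjamini–Hochberg FDR per data block,
  Friedewald LDL (tc − hdl − tg/2.2) and the ≥1.5 kg/6-month
  weight-gain label.
* **Synthetic cohort generator** — seeded log-normal cohorts emulating
  the study design (60 patients, 35 with chemotherapy, 3 timepoints,
  30 MRS signals, 188→140 MS metabolites, 105 lipoprotein subfraction
  variables, rendered 1-D spectra) with every injected effect, censored
  cell, spike and shift offset recorded in a ground-truth ledger.

## Worked example

Simulate a chemotherapy-group cohort in which kynurenine rises 38% and
ADMA 25% at six months, clean the MS block, and test whether the
6-month profile differs from baseline:

```python
import math
import pmet
from pmet.cohort import CohortConfig, EffectSpec
from pmet.msqc import impute_missing_median

cfg = CohortConfig(seed=7, effect_registry=[
    EffectSpec(variable_name="Kynurenine", group="chemo", timepoint=6,
               log_fold_change=math.log(1.38)),
    EffectSpec(variable_name="ADMA", group="chemo", timepoint=6,
               log_fold_change=math.log(1.25)),
])
clinical = pmet.generate_cohort(cfg)
blocks = pmet.simulate_metabolite_matrix(clinical, cfg)
ms_clean, qc = pmet.run_ms_qc(blocks.ms, pmet.simulate_qc_replicates(cfg))
print(f"MS metabolites after QC: {ms_clean.n_variables} of {blocks.ms.n_variables}")

chemo = clinical.loc[clinical.chemo, "patient_id"].tolist()
ds = pmet.build_paired_dataset(impute_missing_median(ms_clean), 0, 6,
                               patients=chemo)
print(f"paired design: {ds.n_patients} patients -> {ds.X.shape[0]} mirrored rows")

res = pmet.permutation_test(ds, n_perm=199, seed=11)
print(f"cross-validated accuracy: {100 * res.observed_accuracy:.1f}%")
print(f"permutation p-value: {res.p_label}")

model = pmet.fit_opls_da(ds.X, ds.y, 1, variables=ds.variables)
print(pmet.vip_scores(model).sort_values(ascending=False).head(3).round(2))
```

prints

```
MS metabolites after QC: 140 of 188
paired design: 32 patients -> 64 mirrored rows
cross-validated accuracy: 68.3%
permutation p-value: 0.0703518
Kynurenine        3.09
C5:1              2.14
lysoPC a C16:0    2.12
```

The QC chain removed the 48 unreliable metabolites; 32 of the 35
chemotherapy patients have MS data at both timepoints, so the multilevel
design has 64 rows.  A two-metabolite effect of this size is near the
detection limit at n = 32: the cross-validated accuracy (68%) sits above
chance but the permutation test does not quite reach 0.05, and the VIP
ranking still puts the truly shifted kynurenine first.  Stronger
multivariate shifts (see `scripts/acceptance.py`) are detected with
accuracy near 100% and p < 0.01.

The full study-shaped run — ten comparisons (two treatment groups ×
{metabolites, lipoproteins} × {6, 12 months}, plus baseline weight-gain
prediction from both blocks) with the univariate arm and per-block FDR —
is one call:

```python
report = pmet.run_full_analysis(pmet.default_plan(), cfg)
pmet.write_report(report, "out/")
```

or, from a shell, `pmet simulate`, `pmet preprocess-nmr`, `pmet qc-ms`,
`pmet analyze` and `pmet report`.

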