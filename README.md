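# strokerad

CT radiomics for discriminating time from stroke onset (TFS) in acute M1
middle-cerebral-artery occlusion: was the infarct imaged within the
intravenous-thrombolysis window (≤ 4.5 h) or beyond it?

Early ischemic density change on non-contrast CT is subtle, but its texture
evolves with time. `strokerad` implements the full quantitative pipeline a
radiomics study of this question needs:

- **3D feature extraction** from a HU volume and an MCA-territory VOI mask:
  396 named features across histogram, formfactor (shape), Haralick, GLCM,
  run-length and size-zone families under a
  `Base_angleA_offsetK[_SD]` naming grid;
- **a three-stage feature-selection cascade**: standardization →
  normality-routed univariate tests (t / Mann–Whitney, keep p < 0.05) →
  greedy Spearman redundancy elimination (|ρ| < 0.9) → LASSO logistic
  regression at the 10-fold cross-validated deviance minimum;
- **the rad-score**, rad = β₀ + Σₖ βₖ·zₖ over the selected standardized
  features, and a **combined logistic model** of the rad-score plus screened
  clinical variables (expected: age, ASPECTS);
- **the evaluation suite**: DeLong AUC CIs and paired ROC comparison, Youden
  operating points, McNemar, Hosmer–Lemeshow calibration, decision-curve
  analysis with the beneficial threshold range, inter/intra-rater ICC, and
  feature–clinical Spearman correlations;
- **a seeded synthetic cohort + CT-phantom generator** calibrated to the
  published per-stratum covariate summaries, so the entire pipeline is
  testable end-to-end without any data download.

See `docs/methods.md` for the model, parameter defaults and the exact
emulation scope of the synthetic data.

## Worked example

Run the whole pipeline on a synthetic replica cohort (46 early / 77 late,
split 85/38) with 48³ phantoms:

```bash
strokerad run --out out/demo --seed 11
```

which logs each stage and ends with

```
evaluate[development]: AUC radiomics 0.933, combined 0.932
evaluate[validation]:  AUC radiomics 0.860, combined 0.857
icc: inter median 0.973, intra median 0.999
validation AUC: radiomics 0.860, combined 0.857
```

Reading the output: the radiomics signature separates early from late
phantoms with a development AUC of 0.93 and holds up at 0.86 on the held-out
validation split (scored with development-derived standardization and
coefficients only — no leakage). Adding the screened clinical variables
(here age) changes little because the phantom signal already dominates. The
inter-rater ICC median of 0.97 says the features are stable under simulated
re-segmentation of the VOI. `out/demo/` now contains `cohort.csv`,
`features.csv` (123 × 396), `selection.json` (every cascade stage),
`model.json`, `report.json` (ROC/CI, operating points, DeLong and McNemar
p-values, Hosmer–Lemeshow, decision-curve ranges), per-split ROC and
decision-curve CSVs, and `manifest.json` with artifact digests — rerunning with the same seed reproduces the digests
bit-for-bit.

The stage commands `simulate`, `extract`, `select`, `fit` and `evaluate`
expose the same steps individually for real NIfTI + CSV inputs; the library
API (`strokerad.features.extract_all`, `strokerad.selection.run_cascade`,
`strokerad.modeling`, `strokerad.evaluation`) is the surface the CLI wraps.

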