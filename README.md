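# lungrad

Radiomics pipeline for imbalance-aware classification of masked lung
ultrasound regions, exercised end to end on a synthetic cohort generator.

The package covers:

- **`lungrad.synthdata`** — synthetic cohorts: speckle images (multiplicative
  gamma noise on a smooth base field) with irregular or square ROI masks,
  class-conditional clinical covariates (gestational age, binary
  comorbidity), a class-stratified 8:2 splitter, and an aliased feature-space
  cohort for classifier benchmarking.
- **`lungrad.preprocess`** — image/mask ingestion (PNG/TIFF and single-frame
  monochrome DICOM via a built-in codec) and ROI discretization: outlier
  clipping at mean ± 3σ, min–max mapping onto 256 integer grey levels
  (bin width 1).
- **`lungrad.radiomics`** — 380 named features per subject: 16 histogram,
  6 directional-spread, 23 GLCM, 13 GLRLM, 13 GLSZM and 5 NGTDM features on
  the original ROI, and the same 76 on each of the four subbands of a
  first-level Daubechies-5 wavelet decomposition (self-contained separable
  DWT, no external wavelet dependency).
- **`lungrad.select`** — 382-column feature table (two clinical covariates +
  radiomics), train-bound min–max normalization, Welch-t / chi-square
  univariate screening, random-forest out-of-bag permutation importance and
  top-k selection.
- **`lungrad.learners`** — ADASYN / SMOTE / random undersampling, discrete
  two-class AdaBoost.M1, RUSBoost and SMOTEBoost with decision-tree base
  learners, and plain / cost-sensitive RBF margin classifiers, all with
  continuous scores for ROC analysis and JSON model serialization.
- **`lungrad.evaluate`** — confusion-count metrics (bACC, SENS, SPEC, PPV,
  NPV), midrank AUC, and bootstrap stratified k-fold cross-validation with
  grid search.
- **`lungrad.pipeline`** — one-config orchestration of the full method grid
  (7 method-regimes) and feature-set grid (clinical-only ablations, full
  feature set on irregular and square ROIs).

## CLI

```bash
lungrad simulate --config cohort.json --out cohort/ --seed 0   # images+masks+manifest
lungrad extract  --manifest cohort/manifest.csv --out features.csv
lungrad select   --features features.csv --manifest cohort/manifest.csv --out selection.json
lungrad train    --features train.csv --method rusboost --out model.json
lungrad evaluate --model model.json --features test.csv
lungrad reproduce-grid --out results/ --seed 0                 # full experiment grids
```

`cohort.json` holds a `CohortSpec` (cohort size, minority count, per-class
texture/covariate parameters, image size, mask kind).

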