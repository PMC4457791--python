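# Methods

This document describes the statistical and numerical model implemented by
`serumpep`: what the synthetic-data generator asserts about the world, how the
preprocessing chain turns raw profile spectra into peak areas, how the
classifiers are trained and evaluated, and where the package's scope ends.

## 1. Scientific model

The package models a two-cohort biomarker study: serum peptidome profiles are
acquired by linear MALDI-TOF over 800–10,000 Da, and the goal is a peptide-peak
classifier that predicts EGFR TKI-sensitive mutation status (labels `mutant` /
`wild`) without a tumor biopsy. A training cohort (default 50 mutant / 50 wild)
supplies peak definitions, differential statistics, and classifier training; a
separate validation cohort (default 52 / 71) is classified blind, and only
afterwards is unblinded for concordance against the tissue assay, treatment
response, and survival.

## 2. Spectral generator

Each patient spectrum is built on a uniform m/z grid (default step 0.25 Da) as

```
intensity = baseline + peaks + noise, clipped at zero
```

* **Peaks** are Gaussians with mass-proportional width, `sigma = m/z / 3000`
  (about 1 Da at 3000 Da), matching linear-TOF resolution. Each peak's **area**
  is drawn per patient from a zero-truncated normal.
* **Informative peaks.** Ten peptides carry class-conditional area
  distributions (`simulate.DISCRIMINATING_PEAKS`); e.g. m/z 4092.4 has area
  4.57 ± 1.63 in the wild class and 10.00 ± 4.29 in the mutant class. The
  five-peptide set m/z 1365.10, 4092.40, 4438.43, 4585.05, 4643.49 is the
  "reference classifier" that parameter-recovery tests expect the GA to find.
* **Background peaks.** 120 class-independent peptides with catalog-level mean
  areas ~N(25, 12²) floored at 1 and per-patient SD = 25% of the mean.
  Centroids are uniform over the window, kept ≥ 10 Da from informative
  centroids and ≥ 6 Da apart. The catalog is drawn from `catalog_seed`
  (default: the config seed). **Both cohorts of one study share the catalog**:
  they assay the same serum matrix, so the non-discriminating peptide
  population must be common even though every patient's areas are fresh draws.
  Reseeding the catalog per cohort would inject a train/validation
  distribution shift that no paired-cohort design has, and it measurably
  breaks classifier transfer whenever a low-level background peak enters the
  model.
* **Baseline**: decaying exponential (amplitude 2.0, decay 2000 Da) plus a
  constant offset 0.2 — the slowly varying chemical background that top-hat
  subtraction must remove.
* **Nuisances**: additive Gaussian noise (sigma 0.05), a lognormal
  multiplicative TIC factor (sigma 0.10), and a per-spectrum affine m/z
  miscalibration (|scale − 1| ≤ 2·10⁻⁴, |offset| ≤ 0.3 Da).
* **Invalid acquisitions**: with probability `invalid_rate` a spectrum's peak
  component (not its baseline or noise) is attenuated 50× — a failed
  crystallization. The generator records the flag; the pipeline must rediscover
  it through QC.
* **Reproducibility**: patient *i* draws from `default_rng([seed, 1, i])`, so
  cohorts are deterministic and stable under resizing; outcome draws use the
  separate substream `[seed, 2, i]`.

Clinical outcomes are generated per patient from the **true** class only:
objective response (PR) with probability 0.596 (mutant) / 0.088 (wild), disease
control adding SD up to 0.872 / 0.353; PFS exponential with median 10.0 / 2.3
months; OS exponential with median 29.0 / 28.0 months, floored at the PFS time;
administrative censoring at 40 months. TKI treatment probability is 0.90 /
0.50, and untreated patients have response recorded as `missing`.

## 3. Preprocessing chain

Order: trim → TIC normalization → recalibration → smoothing → baseline
subtraction → consensus peak detection → integration → QC.

* **TIC normalization** scales each trimmed spectrum so its trapezoidal
  integral equals a target. The pipeline uses the generator's
  `nominal_tic()` so recovered areas stay on the generator's area scale; the
  operation is idempotent.
* **Recalibration** estimates a per-spectrum affine m/z correction from
  prominent peaks shared across the cohort and inverts it by interpolation.
* **Smoothing**: Savitzky–Golay, polynomial order 3, window 2 Da. A wider
  window (e.g. 5 Da) would flatten the narrowest informative peak
  (m/z 1365.1, sigma ≈ 0.46 Da); 2 Da ≈ 9 grid points preserves its area to
  ~1% while still suppressing grid-scale noise.
* **Baseline**: top-hat — the signal minus its morphological (grey) opening
  with a flat structuring element spanning 10% of the mass window. The opening
  is computed on a **2 Da median-despiked copy** of the signal: order-3
  Savitzky–Golay leaves negative sidelobes beside narrow peaks, and the
  opening's erosion otherwise latches onto those artificial minima,
  understating the baseline across wide regions (observed +5–22% area bias).
  The subtraction itself still uses the original intensity, clipped at zero.
* **Noise estimation**: robust local scale of the baseline-corrected signal —
  the median absolute deviation of the first difference within 250 Da
  windows, scaled to sigma. It is insensitive to sparse tall peaks.
* **Consensus peak detection** runs on the cohort mean spectrum: local maxima
  whose height *and* topographic prominence are ≥ 5× local noise. Bounds
  extend to flanking minima or zero crossings and never overlap; centroids are
  intensity-weighted over the top 75% of the peak.
* **Integration**: zero-level trapezoidal area between the consensus bounds.
  Each window is first re-centered on the sample's local apex within ±0.3% of
  the centroid (≤ 2 Da) to absorb residual calibration error, but the apex
  search **never leaves the definition's own bounds** — a small definition
  adjacent to a dominant neighbor must not latch onto that neighbor's flank
  and integrate a different feature than the one it names.
* **QC**: a spectrum is `invalid` unless ≥ 80% of the cohort's *major* peaks
  (cohort-median height ≥ 5× cohort-median noise) reach SNR 5 in that
  spectrum. Scoring against major peaks only matters because consensus
  detection on the low-noise mean spectrum lists peaks no single acquisition
  can show. The 0.8 fraction sits in the middle of the measured separation:
  valid spectra pass ≥ 97% of major peaks even in heavily contaminated
  cohorts, while 50×-attenuated spectra pass ≤ 57% (their strongest peaks
  survive attenuation). Invalid spectra are excluded from statistics and
  training and are labeled `unclassifiable` at prediction time.

## 4. Differential statistics

Per consensus peak, Welch's t-test and the Wilcoxon rank-sum test compare
classes on QC-passing spectra; Benjamini–Hochberg controls the false discovery
rate at 0.05 across peaks. Effect direction and class means/SDs are reported
alongside.

## 5. Classifiers

All models consume standardized peak areas and store the selected peak
centroids, so a saved model can be applied to any feature matrix whose
definitions match within 1.5 Da.

* **GA-kNN** (the primary model): a genetic algorithm selects a peak subset
  for a k-nearest-neighbor classifier (k ∈ {3, 5, 7}). Fitness is
  hierarchical: internal 5-fold CV accuracy dominates; the mean kNN vote
  margin (weight 0.005) and the subset's aggregate univariate evidence
  (weight 0.001) break ties. With ~180 consensus peaks and a separable
  cohort, plain CV-accuracy fitness saturates and the winning subset is
  arbitrary among saturating subsets; the tie-breakers make the selection
  reproducible and biologically meaningful without ever overriding accuracy.
  Operators are statistics-informed (genes are sampled with probability
  increasing in univariate evidence) and the winner gets a memetic
  hill-climb. kNN vote ties resolve to `wild` (never over-call the
  treatment-determining label).
* **SNN**: a supervised nearest-prototype (LVQ-style) model, 3 prototypes per
  class.
* **QC (quick classifier)**: class-mean prototypes over the top univariate
  peaks with a weighted-distance vote.

**Evaluation regime.** `recognition_capability_pct` is resubstitution accuracy.
`cross_validation_pct` is the mean accuracy of stratified 20%-holdout splits
repeated 10 times. For GA models the **outer CV refits the kNN on the already
selected subset** per split; the GA's own internal CV is part of training.
This mirrors the reference software's reporting (feature selection held
fixed) and is stated here explicitly because nesting the GA inside the outer
loop would both change the estimand and multiply runtime ~50×. Best-model
selection: highest `cross_validation_pct`, ties to fewer peaks.

## 6. Clinical evaluation

* **Concordance** keeps unclassifiable spectra in every denominator:
  sensitivity = TP / (TP + FN + invalid-mutant), specificity
  = TN / (TN + FP + invalid-wild), accuracy = (TP + TN) / all. Cohen's kappa
  is computed on the 2×2 of definite calls only, with a large-sample z-test
  of kappa = 0.
* **Response**: ORR (CR+PR) and DCR (CR+PR+SD) per predicted label among
  TKI-treated patients with a recorded response; association by uncorrected
  chi-squared and Fisher's exact test.
* **Survival**: Kaplan–Meier per predicted label (equal to the empirical
  survivor function when nothing is censored) and the log-rank test, both via
  `lifelines`.

## 7. Problem sizes and determinism

The default study (100 + 123 spectra, 36,801-point grid, five candidate
models) runs in ~25 s on one CPU; a single cohort preprocessing pass is a few
seconds. Every stage is deterministic given the config: derived seeds are
spawned as `default_rng([seed, stream, index])` tuples, and `run_full_study`
writes a manifest with SHA-256 digests of every artifact — identical seeds
reproduce identical manifests bit for bit.

## 8. Limitations

* The generator plants exactly the effects the pipeline later estimates;
  recovery tests demonstrate internal consistency, not external validity, and
  classifier performance on synthetic cohorts is optimistic relative to real
  sera (the planted class separation is clean and the nuisance model is
  simple).
* Peak shapes are symmetric Gaussians; real MALDI peaks have asymmetric
  tails, adducts, and matrix clusters that the chain is never challenged
  with.
* Outcomes depend on the true class only — no covariates, treatment lines, or
  informative censoring; survival analysis is two-group log-rank only.
* The mzML reader/writer supports the minimal profile-spectrum subset
  (32/64-bit float arrays, optional zlib), not the full PSI specification.
* Small-sample medians are noisy: at the default validation size the planted
  10-month PFS median is estimated with an SE of roughly 1.5 months, so
  single-seed runs can sit well off the planted value (see README example).
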