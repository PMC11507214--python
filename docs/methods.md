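# Methods

`specfuse` implements a multi-level chemometric fusion pipeline for paired
Raman and FTIR spectra of a binary cohort (healthy `H` vs disease `L`),
together with a synthetic cohort generator that stands in for clinical
plasma data. This note documents the models, the defaults and why they were
chosen, the numerical conventions, and what the synthetic experiments do
and do not demonstrate.

## Study design emulated by the generator

The default `CohortSpec` encodes the design the pipeline targets:

| quantity | default | unit |
| --- | --- | --- |
| subjects | 18 + 18 | per class |
| Raman axis | 610–1720, 1015 points | cm⁻¹ |
| FTIR axis | 400–4000, 1868 points | cm⁻¹ |
| FTIR fingerprint | axis ≤ 1800 cm⁻¹ (727 points) | cm⁻¹ |
| Raman replicates | 25 | per subject |
| FTIR replicates | 10 | per subject |

Both grids are linear; the fingerprint sub-grid then contains exactly 727
points, which makes all downstream feature-count arithmetic (2883- and
1742-wide fused matrices, the percentile selection counts) reproduce the
benchmark table exactly.

Each replicate spectrum is built as

```
y = gain · (background(ν) + class_effect(ν) + drift(ν)) + ε + spikes
```

* **background** — a fixed sum of Gaussian bands per modality mimicking
  dried-plasma spectra (phenylalanine ring breathing at 1003 cm⁻¹, CH
  deformations, amide I/II, the broad O–H/N–H envelope, and a broad
  pseudo-fluorescence pedestal in Raman that the baseline correction is
  expected to remove).
* **per-subject biological variability** — each subject multiplies every
  background band by an independent lognormal factor
  (`subject_sd`, default 0.1). This term is essential: without
  between-subject variance, averaging 25 replicates annihilates the noise
  and any nonzero class effect separates the cohorts perfectly, which
  erases the comparative structure (accuracies between 0.75 and 1.0) that
  real cohorts of this size show.
* **class effect** — additive Gaussian bumps on band height for the `L`
  class at the marker wavenumbers (Raman 624, 966, 1051, 1125, 1248, 1587,
  1650 cm⁻¹; FTIR 1062, 1699 cm⁻¹). Band-position shifts are not modeled.
  Default amplitudes (Raman 0.02, FTIR 0.08, on the scale where the
  strongest background band is 1) were calibrated once so that
  single-modality cross-validated accuracies land in the 0.75–0.9 range and
  fused models above them, the regime real plasma cohorts of this size
  exhibit; per-band effect sizes in real data are unknown, so these are
  package choices.
* **baseline drift** — per-replicate cubic polynomial for Raman
  (fluorescence-like), a near-flat random offset for FTIR, since dry-film
  ATR absorbance needs no baseline removal.
* **multiplicative gain** — lognormal (`scatter_sd` 0.1), the scatter /
  focal-volume effect SNV is meant to remove.
* **noise and spikes** — iid Gaussian noise (sd 0.02) plus
  Poisson-distributed positive spikes in Raman only (cosmic rays are a
  CCD/Raman artifact).

Randomness is drawn from one stream per subject keyed by
`(seed, class, index-within-class)`, so enlarging a cohort never reshuffles
already-generated subjects.

**What the generator does not model:** radiative transfer of ATR or
confocal optics, wavenumber miscalibration, instrument drift over a
measurement session, the spatial geometry of the coffee-ring (only its
statistical consequence, replicate heterogeneity, via per-replicate gain
and drift), and correlated biology across modalities (subject factors are
drawn independently per modality). Passing tests therefore demonstrate
that the pipeline recovers planted structure under these idealized
conditions, not that it would reach the same accuracies on clinical data.

## Preprocessing

Raman, per replicate: despike → AsLS baseline subtraction → SNV; FTIR, per
replicate: SNV only; then replicates are averaged to one spectrum per
subject. SNV is applied per replicate before averaging (configurable via
the row-wise transformer, but this is the default order).

* **Despiking** replaces points whose residual from a 7-point running
  median (mirror padding) exceeds 8 robust standard deviations
  (1.4826·MAD). Mirror padding matters: edge-replicating padding makes a
  spike at the first grid point its own median and undetectable. The
  threshold is deliberately conservative so genuine sharp Raman bands are
  never clipped.
* **AsLS baseline** minimizes `Σ wᵢ(yᵢ−zᵢ)² + λ‖Δ²z‖²` with asymmetric
  weights (`p` above the baseline, `1−p` below), λ = 100, p = 0.01,
  max 10 reweighting iterations, stopping when the weights stabilize
  (tol 1e−6). The banded normal equations are solved with
  `scipy.linalg.solveh_banded`; a dense-matrix solver of the same objective
  serves as the test oracle (agreement ≤ 1e−8 at length 200).
* **SNV** centers and scales each spectrum to mean 0, sd 1. The population
  sd (divisor *n*) is used package-wide — the same convention as the block
  scalers, so the variance identities below hold exactly. Zero-variance
  input raises (a dead channel should fail loudly, not silently).

## Block scaling and fusion

All scalers center columns and are fit on training rows only.

* **Unit-variance block scaling**: column scale `σ·√n_block`, giving each
  column training variance `1/n_block` and each block total variance 1.
  Centering is required for these variance statements to hold in models
  with intercepts.
* **Soft block scaling**: column scale `σ·n_block^{1/4}`, giving column
  variance `1/√n_block` and block total `√n_block` — wide blocks still get
  more total variance than narrow ones, but only in proportion to the
  square root of their width.
* **LLDF** concatenates soft-scaled blocks (Raman first, then FTIR) and
  keeps per-column provenance so fused feature indices map back to
  (modality, wavenumber).
* **MLDF** applies FS or FR per block after unit-variance scaling, then
  soft-scales the *reduced* blocks and concatenates.
* **HLDF** trains one logistic model per block and averages predicted
  probabilities with equal weights; no block scaling is involved. A mean
  probability exactly at the threshold (default 0.5) classifies positive —
  a tie rule has to be fixed somewhere, and positive-on-tie is the
  documented, configurable choice.

A constant (zero-variance) training column raises an error naming the
offending wavenumber; the check uses a relative tolerance of 1e−10 because
the floating-point sd of a constant column is ~1e−16, not 0.

## Feature selection

Features are ranked by absolute regression coefficients of a PLS1 model
(`n_latent` default 5 — training folds have at most 30 subjects, which
bounds the number of useful latent variables; no additional column scaling
inside PLS since the block scalers already did it). Over 100 iterations of
a reshuffled stratified 6-fold split (600 assessments per feature), each
training fold marks its top `⌈pct% · n⌉` features; the final mask keeps the
`⌈pct% · n⌉` features with the highest selection counts, ties broken by
larger mean |RC| and then lower index. The ceiling rule is the unique
rounding consistent with every benchmark feature count (e.g. 1% of 727 → 8,
10% of 1742 → 175).

`reevaluate_mask` optionally re-runs the counting restricted to the
first-pass mask to refine the importance ordering; membership and count are
kept. Inside the outer cross-validation, selection runs on the training
fold only (leakage-free); a whole-dataset mode exists for exploratory use
but is not used in any reported number.

A null-data caveat worth recording: selection counts on a *fixed* null
dataset are not hypergeometric-uniform across assessments, because the same
accidental feature–label correlations persist across resampled folds, so
counts concentrate on whichever features happen to correlate with the
labels in that dataset. The correct null property — and the one tested —
is instability across independent null datasets: masks from different
seeds overlap near the chance level `m²/p`.

`rfe_top_k` refits an L2 logistic model, dropping the weakest-|coefficient|
feature one round at a time. Survivors are ranked by how long they survive
(via a full elimination ranking); `k = n_features` short-circuits to the
input order with no fitting.

## Feature reduction

PCA components are added incrementally (1…10) and a logistic model's
stratified-CV accuracy is recorded at each prefix; the best prefix wins,
ties going to fewer components (parsimony). Arbitrary component subsets are
out of scope — the benchmark reports counts like "6 PCs", consistent with
prefixes. Component signs are fixed by making each loading's
largest-magnitude entry positive, so scores are reproducible across SVD
backends.

## Evaluation

* Stratified 6-fold CV; with 18+18 subjects every fold holds exactly 3+3.
  `k = n` degenerates to leave-one-out.
* The classifier everywhere is L2-regularized logistic regression (C = 1,
  fixed): fused widths (up to 2883) far exceed the 30 training subjects per
  fold, so regularization is structural, not a tuning knob.
* `run_config` repeats the CV with fresh shuffles (default 100 repeats,
  mirroring the selection scheme's 100 iterations); each repeat predicts
  every subject exactly once. The reported uncertainty is the standard
  error of the mean accuracy across repeats. ROC/AUC pools held-out
  probabilities within a repeat and averages AUC over repeats; the AUC is
  the trapezoid over the empirical ROC and equals the Mann–Whitney
  U/(n₁n₂) probability (asserted to 1e−12).

## Statistics

Per-wavenumber two-sided Mann–Whitney U tests (exact for combined n ≤ 25
without ties, otherwise normal approximation with midranks and continuity
correction), annotated with stars at p ≤ 0.05/0.01/0.001/0.0001. No
multiple-testing correction is applied to the stars, matching the
per-wavenumber screening convention; a Benjamini–Hochberg column is
exported alongside, clearly an extension. Band assignment uses a packaged
table of the marker ranges (point bands get a ±4 cm⁻¹ window; ranges are
as observed) with their vibrational modes and molecular classes.

## Problem sizes used in tests and the acceptance script

Stochastic suites run at deliberately reduced scale, chosen as the
package's own trade-off between statistical resolution and turnaround:
20 synthetic cohorts per recovery property (40 for the null-calibration
estimate in the acceptance script), one CV repeat per cohort, and 10–25
frequency-selection iterations when selection runs inside outer CV folds.
The exact assessment-count property runs the full 100 × 6 scheme on a
36 × 30 matrix, where it is cheap. The benchmark accuracies reported by
`scripts/acceptance.py` use 10 CV repeats on one default cohort.

Null calibration is checked against the central 99% binomial interval of
the pooled decision count. Because decisions within a cohort are
correlated, the per-cohort accuracy sd (~0.10) exceeds the binomial value,
making this interval mildly anti-conservative; direct measurement over 100
null cohorts gives a mean accuracy of 0.504 ± 0.011, i.e. the pipeline is
unbiased at the null.

## Known limitations

* Default effect amplitudes are package choices (real per-band effect
  sizes are unreported); absolute accuracies on synthetic cohorts are
  therefore illustrative, and only their qualitative ordering (fusion with
  selection ≥ single modality; chance at the null) is load-bearing.
* The PCA scan's chosen component counts on synthetic cohorts depend on
  the cohort and are not comparable to counts obtained on clinical data.
* The vendor cosmic-ray filter of the acquisition software is proprietary;
  the median-filter despiker is this package's own stand-in and is only
  validated on synthetic spikes.
* `FusionModel` assumes exactly two classes and a fixed block partition of
  its input columns; multi-class cohorts and more than two blocks per
  fusion level are untested territory beyond what the API validates.
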