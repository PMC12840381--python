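# Methods

## Problem and scope

`lvscreen` implements a screening chain that maps a 60-s resting lead-I
ECG plus five clinical covariates to a calibrated probability that the
subject's left-ventricular ejection fraction (LVEF) is below a cutoff —
either the sex-specific lower limit of normal (52% men, 54% women) or the
severe threshold of 40%. No patient data ships with the package: the
synthetic-data module defines the study conditions under which everything
else is tested.

## Synthetic cohort model

**Subjects.** Covariates are drawn independently with prevalences typical
of an outpatient cardiology cohort: 41.8% male, 16.7% smokers, 13.1%
diabetes, 59.5% hypertension, age ~ N(58, 16) clipped to [18, 90]. LVEF
comes from a three-component truncated-normal mixture — normal
N(62, 4) on [55, 78], mildly reduced N(46, 3) on [40, 51.5], severe
N(32, 5) on [15, 39.5] — with default weights 0.202 below-normal overall
and 0.109 below 40%, matching the screening population the pipeline is
designed for (roughly 600 subjects, ~20% / ~11% prevalence). The mild
component's upper bound sits below the male cutoff so mixture membership
implies endpoint membership for either sex; the sex-specific rule itself
is applied only at labelling time.

**Beats.** A beat is a sum of Gaussian kernels (P, Q, R, S; asymmetric
pair for T: trailing σ = 0.82 × leading σ, so the leading T front is the
shallower one and the front-slope ratio SBeta sits slightly below 1), plus
a Gabor burst (180 Hz carrier, 4-ms σ, ~25 μV) centred on R that supplies
the 150–250 Hz intra-QRS band. Defaults: R 1000 μV / σ 10 ms; S −200 μV;
T 300 μV centred +280 ms from R. Sampling is 1 kHz so a 150–250 Hz band
exists comfortably below Nyquist; records are 60 s.

**LVEF→morphology link.** A severity score
`s = clip((55 − LVEF)/15, 0, 2)` (0 at normal EF, 1 at EF 40) shifts
per-subject template parameters linearly, in units of the control-
population SD: T amplitude −1.5 SD·s (SD 60 μV), R-kernel σ +1.0 SD·s
(SD 1.2 ms, with Q and S widths scaled coherently), HF burst amplitude
−1.0 SD·s (SD 5 μV), each plus per-subject Gaussian scatter of one SD and
clipping to physiological ranges. The T-wave position also scatters
(σ 8 ms) between subjects. The link is the simplest monotone one that
leaves the generating parameters recoverable: delineation and feature
tests compare measured values against the stored generating truth.

**Rhythm and noise.** RR intervals are Gaussian (mean 60000/HR at
70 bpm, SD = target SDNN, default 40 ms) truncated at 250 ms — SDNN is
the only heart-rate-variability feature used, so no autonomic spectrum is
modelled. White Gaussian noise (default RMS 15 μV) is added; a 0.2 Hz
baseline-wander sinusoid is available but off by default so analytic
examples stay exact.

**What the generator does not emulate** (hence what passing tests do not
show about real data): atrial fibrillation, bundle-branch block, paced
rhythms, ectopy, electrode motion artefact, beat-to-beat morphology
variation, and any nonlinear or non-monotone LVEF–ECG relationship. The
end-to-end AUCs on synthetic cohorts demonstrate that the pipeline
recovers a planted monotone signal; they are not estimates of clinical
performance.

## Delineation

R peaks: 5–25 Hz band-pass → derivative → squaring → 150-ms moving
integration → threshold at 25% of the 99th percentile, with a 250-ms
refractory and final refinement by raw-signal argmax. Records shorter
than 10 s, flat, or with fewer than 8 beats are rejected, mirroring the
exclusion of unsatisfactory recordings from a screening cohort.

The averaged beat is the pointwise **median** of R-aligned segments
(−300…+500 ms at 60 bpm, scaled by mean RR), robust to occasional
misdetections. QRS onset/offset are found where the derivative magnitude
of a 40 Hz low-passed copy stays below 5% of its local QRS maximum for
8 ms, with sub-sample linear interpolation of the crossing; the low-pass
matters because the boundary threshold must not depend on the record's
high-frequency intra-QRS content. Baseline is the median of the PQ
segment (QRS onset −80…−20 ms). T landmarks use a 15 Hz low-passed copy:
T peak by extremum, T onset/offset as maximum-|slope| points of the two
fronts, T end by extending the trailing tangent to the baseline. A T wave
below twice the PQ-segment noise floor (or 5 μV) marks all T-dependent
fields missing rather than failing the record. All fiducial times are
reported relative to QRS onset, which therefore appears in the feature
table as the degenerate origin column `QRSst` = 0 (kept for schema
completeness; the preprocessor maps constants to 0.5 with a warning).

## Features

Exact formulas of commercial single-lead analysers are proprietary; each
parameter here is a documented approximation consistent with its name,
and `lvscreen-features-1` is recorded in the table metadata as the
extraction version. Choices worth stating:

- QTc uses **Bazett** (QT/√RR[s]); SDNN uses the population SD over the
  whole record.
- RonsF/RoffsF are power-weighted spectral centroids of 40-ms
  Hann-windowed, mean-removed segments centred at QRS onset/offset,
  zero-padded to 4096 points. With a 40-ms window a low-frequency tone's
  centroid is biased upward by the truncation of its spectral lobe at
  0 Hz; the measure is used comparatively across subjects, where the bias
  is common-mode.
- Band energies use a **Daubechies-4 DWT in periodization mode** on
  zero-padded power-of-two windows, which keeps the transform orthonormal
  so detail + approximation energies equal the segment energy exactly
  (tested to 1e-6 relative). At 1 kHz the detail levels 1–4 cover
  250–500, 125–250, 62–125 and 31–62 Hz. HFQRS is the 150–250 Hz FFT
  band energy of the QRS window. Energies are reported in μV²·s.
- Beta/SBeta are max-|slope| ratios of leading vs trailing fronts of the
  R and T waves; T slopes are taken after the 15 Hz low-pass because
  slope landmarks are noise-sensitive (a `smooth_hz=None` escape hatch
  exists for analytic fixtures).
- `…st`/`…fi` suffixes are read as wave start/finish markers; Rpeak,
  Speak, Tpeak are positions (ms), with amplitude roles carried by RA,
  SA, TA. PpeakP/PpeakN are taken as the maximum positive/negative P
  deflections.

## Training procedure

- Labels are strict `<` comparisons against the sex-specific cutoff.
- The 70/30 split is stratified, with test size ⌈0.3 n⌉ (624 → 436/188)
  and a fixed default split seed of 9 843 587.
- Quantile maps (rank → uniform [0,1]) are fitted on the training set
  only and applied unchanged to the test set; binary covariates pass
  through as indicators; train-constant features map to 0.5 with a
  warning. Missing values are imputed with the train median first.
- Feature selection runs 20-fold shuffled stratified CV (folds reduced
  with a warning if the minority class is smaller); per fold an
  L1-logistic model and a gradient-boosted tree model are fitted, and
  three importance scores — |coefficients|, boosting total gain, and
  mean |SHAP value| of the boosted model on the held-out fold (computed
  natively by xgboost's TreeSHAP) — are averaged over folds; the union
  of the three top-10 lists is the model feature set.
- Each architecture is tuned over a fixed grid of at most 12 points by
  stratified 3-fold CV on ROC AUC. "Lasso"/"Ridge" are L1/L2-penalized
  logistic classifiers, since thresholds and AUC require probabilities.
  The MLP carves 30% of the training set into an early-stopping
  validation split. The isotonic calibrator is fitted on out-of-fold
  scores of the selected configuration (calibrating on in-sample scores
  degenerates), then the classifier is refitted on the full training set.
- The Youden threshold maximizes sensitivity + specificity − 1 over the
  midpoints of sorted unique probabilities plus the two degenerate cuts;
  ties break toward the higher threshold (higher specificity — in a
  screening context fewer false positives at equal J).
- The ensemble is the arithmetic mean of member calibrated probabilities
  with its own Youden threshold from the training set.
- Nothing downstream of the split ever touches the test partition; the
  test suite asserts this by refitting on the training partition alone
  and comparing predictions bitwise.

## Numerical and testing choices

- All randomness flows from explicit integer seeds
  (`numpy.random.default_rng`, scikit-learn/xgboost `random_state`,
  single-threaded tree builds), making the full pipeline bit-reproducible.
- Undefined diagnostic metrics (zero denominators) are reported as null,
  never 0 — with small external-test cells the distinction matters.
  Display rounding is half-up to one decimal in percent; raw values are
  retained alongside.
- ROC confidence intervals use a stratified percentile bootstrap
  (2000 reps by default) rather than DeLong, with a fixed seed.
- Test problem sizes: the workhorse suites use 120–200-subject cohorts
  with 20-s records; the end-to-end check uses 600 subjects with full
  60-s records. These sizes were chosen so the whole suite runs on a
  laptop-class single core in a few minutes while keeping ≥ 40 events
  for the severe endpoint during training.

## Known limitations

- Single-lead, average-beat analysis only: no beat-to-beat series, no
  multi-lead reconciliation, no arrhythmia handling.
- Summary statistics published for some fiducial markers in the source
  literature are mutually inconsistent in units/reference points and are
  treated as non-normative; this package fixes QRS onset as the time
  origin instead.
- The mild-dysfunction band (EF 40–52) overlaps heavily with normal
  morphology under the default effect sizes, so below-normal-endpoint
  AUCs are intrinsically lower than below-40 AUCs — as expected for the
  clinical problem.
- The neural-network member is a small MLP stand-in; the reference
  system's network architecture is unspecified.
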