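# Methods

This note documents the models, numerical choices and open design
decisions behind `sitsense`, and what the synthetic experiments do and do
not demonstrate.

## Synthetic seated-posture model

Each of the five sitting behaviors is modelled as a static trunk
orientation sensed by a device strapped at the second thoracic vertebra.
Device frame: x = subject's right, y = up the spine, z = out of the back.
Orientation is intrinsic pitch-then-roll; a posture's sensed vectors are

    a(t) = R(θ + δθ_s + w_p(t), φ + δφ_s + w_r(t))ᵀ g + ε_a(t)
    m(t) = R(·)ᵀ B + ε_m(t)
    ω(t) = d/dt [wander angles] + ε_g(t)

with g = (0, 9.81, 0) m/s², B = (20, −44, 5) µT.

Parameters, defaults, and why:

| parameter | default | rationale |
|---|---|---|
| posture angles (pitch, roll) | A1/A2: roll ∓20°; A3: pitch +20°; A4: pitch −15°; A5: 0 | plausible trunk leans for office sitting; config-exposed, not claims about the source study |
| tremor SD | 0.05 m/s², 0.01 rad/s, 0.5 µT | small relative to orientation contrasts: a learnable but non-trivial problem |
| orientation wander | AR(1), SD 1°, τ = 10 s per axis | postural sway is a slow, bounded drift; the gyroscope output is its time-derivative, giving physically consistent cross-sensor structure |
| per-subject offset | N(0, 2°) on pitch and roll per subject | emulates 6-subject heterogeneity in habitual posture |
| mounting offset | intrinsic yaw 10°, pitch 7°, roll 4° | a strapped phone never sits perfectly axis-aligned; with an exactly aligned mounting, whole channels are identically uninformative (all pitch signal in z, none in x/y), a measure-zero configuration that also breaks transfer of the published feature subset. A generic fixed tilt makes every channel first-order sensitive to posture |
| durations | 712/756/665/590/549 s, split over 6 subjects | the source dataset's per-activity collection times; splitting totals across subjects reproduces its ≈163.5 k-sample scale |

Sample counts are duration × 50 Hz exactly; the few-hundredths-percent
acquisition losses visible in the source dataset's instance counts are
not emulated.

What the generator does **not** emulate: posture transitions and gait,
posture-dependent tremor spectra, sensor bias/scale-factor errors,
magnetic disturbances from furniture, or sample dropout. Consequently
the variance/skewness/entropy features are far less class-informative
here than in real data (they capture mostly isotropic noise), and
passing results say the pipeline is correct and well-calibrated — not
that real sitting data would reach the same accuracies.

## Preprocessing

* Denoiser: zero-phase 4th-order Butterworth low-pass, 5 Hz cutoff.
  Static postures are sub-Hz phenomena; zero-phase filtering avoids lag
  that would smear window boundaries. The cutoff is config-exposed and
  logged in every run manifest.
* Magnitude channels are computed after denoising, before normalization.
* Normalization: per channel, per recording, by max-abs — the simplest
  map achieving the [−1, 1] range exactly. The scale of a recording is a
  deterministic property of that recording; in cross-validation, folds
  are stratified over windows, so every training fold spans every
  recording and a training-only signal scale would be numerically
  indistinguishable from the whole-recording scale. Leakage control is
  therefore placed at the feature level: feature standardizers, hamming
  code edges and CFS-PSO selection are fit inside training folds only.
* Windows: ω_t = 1 s (N = 50) with stride 25 (50 % overlap). The window
  length is a free choice (1-s windows are standard for 50 Hz static-
  posture recognition); windows spanning an activity boundary are
  dropped so every instance has a pure label. "Instances" in all reports
  are windows, not raw samples.

## Feature bank

84 features: 9 statistics × 9 raw channels + 3 per-sensor magnitude
means. Numerical conventions: population (divisor-N) variance and SD;
skewness as the standardized third moment with 0 for constant windows
(a variant dividing by σ instead of σ³ is kept behind
`skewness_as_printed` for comparison with a legacy formulation); wavelet
entropy as the Shannon entropy of the window's relative energy
distribution pᵢ = xᵢ²/Σxⱼ² (scale-free, in [0, ln N]; a dyadic
decomposition variant exists but is off by default); log energy entropy
Σ log₂(xᵢ² + ε) and harmonic mean on |x|, both with ε = 1e−12 guarding
zeros. Any non-finite feature value aborts extraction naming the feature
and window.

## CFS + binary PSO

Symmetrical uncertainty is computed on 10-bin equal-width discretized
features (Pearson variant behind a flag); constant features get zero
correlation. PSO defaults — swarm 20, 100 iterations, w = 0.72,
c₁ = c₂ = 1.49, v_max = 4, sigmoid transfer — are standard
constriction-style settings. The initial swarm seeds the best single
feature, so the returned merit is never below the best singleton; the
global best is monotone over iterations. The exhaustive enumerator
(≤ 20 features; ties to smaller subsets, then lexicographic mask order)
is the exact reference in tests. Selection inside cross-validation is
fit on training folds only, which may be stricter than the original
study's (unstated) procedure.

## Classifiers

* Naive Bayes: per-class Gaussians per feature, population variance
  floored at 1e−9, empirical priors; ties go to the lowest class id.
* KNN: brute-force neighbor search. The hamming metric — reported by the
  study for real-valued features without explanation — is applied to
  per-feature quantile codes (8 levels, edges fit on the training set);
  2 levels recovers a median binarization, which provably mangles the
  neutral posture (its values sit at the center of every feature's
  range, so a median cut splits its cluster). Euclidean on standardized
  features is the alternative.
* SVM: one binary soft-margin RBF machine per class (one-against-all) on
  standardized features; prediction by maximal decision value. Kernel
  scale defaults to √p (the "medium Gaussian" preset convention),
  applied as γ = 1/scale²; C = 1. The binary quadratic program is
  scikit-learn's; the OAA wrapping, scaling and score aggregation are
  this package's.

## Evaluation

Overall accuracy is 100·trace/total of the pooled confusion matrix
(rows true, columns predicted, fixed order A1…A5); per-activity accuracy
is class recall — the definition that reproduces the published
per-activity cells from the published matrices. One published cell pair
(front-movement, accelerometer+gyroscope SVM: 99.66 vs a matrix recall
of 98.67) is irreconcilable under any single definition and is not
reproduced. Per-class TP/TN/FP/FN are emitted alongside. All percentages
round half-up to two decimals. Binary one-vs-rest accuracy
(TP+TN)/(TP+TN+FP+FN) is derivable from the emitted counts.

## Problem sizes and reproducibility

The default synthetic dataset is 6 subjects × ≈27.3 k samples
(≈163.6 k samples, 6,492 windows), on which the full six-classifier
10-fold evaluation runs in well under a minute on one core. Unit tests
use 2-subject, 20–30 s-per-activity datasets. All randomness descends
from one root seed via hashed per-stage child seeds; rerunning any
configuration reproduces raw CSVs, feature matrices and reports
byte-identically (manifests differ only in timings).

## Known limitations

* The published 27-feature preset was selected on private human data;
  on synthetic data many of its variance/entropy members are
  uninformative, and the discriminative load falls on the level
  (MAV/HM/LEE/magnitude) features. The back-lean vs straight pair is
  accordingly the hardest contrast, and naive Bayes — whose pooled
  Gaussian class model is most exposed to between-subject scatter — is
  the most variable performer across dataset seeds (84–99 % pooled
  accuracy over seeds 0–4, versus ≥ 95 % for KNN and SVM; the source
  study likewise reports its lowest per-activity cell for naive Bayes on
  the back lean). Numbers quoted in reports are always tied to an
  explicit seed.
* The full 84-feature bank is one short of the 85 the source study
  mentions without decomposition; the registry is configurable and the
  discrepancy is documented rather than resolved.
* CFS-PSO subsets found on synthetic data need not resemble the
  published subset; they reflect the generator's, not human, physiology.
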