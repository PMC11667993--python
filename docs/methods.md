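# Methods

## The measurement model

`fidgetquant` quantifies how much, and how irregularly, a seated subject
moves in a fixed-camera consultation-room video, without contact sensors.
The measurement chain is deliberately simple:

1. **Grayscale conversion.** Frames are reduced to ITU-R BT.601 luma
   (0.299 R + 0.587 G + 0.114 B, rounded half-to-even). Colour carries no
   extra information for frame differencing and triples the cost.
2. **Per-second downsampling.** Each 1-second block of F frames is reduced
   to d frames at endpoint-inclusive uniform positions,
   index(i) = round(1 + (i−1)(F−1)/(d−1)), i = 1…d (round-half-even).
   Blocks are independent: no frame pair spans a second boundary, so d
   retained frames yield exactly d−1 subtracted images per second — 240 s at
   d = 6 gives exactly 1,200 subtracted images, and d ∈ {6, 15, 30} at 240 s
   gives N ∈ {1,200, 3,360, 6,960}.
3. **Pixel subtraction and thresholding.** Consecutive retained frames are
   subtracted (|f_{k+1} − f_k|, elementwise) and restricted to a per-session
   rectangular region of interest (ROI) covering the subject. A pixel counts
   as *moved* when its absolute difference strictly exceeds the significance
   threshold θ (default 100 on the 0–255 intensity scale — far above sensor
   noise, so a static scene quantifies to exactly zero). Subtraction is
   computed on ROI crops; cropping and |·| subtraction commute, so this is
   purely a speed optimisation (asserted in tests).
4. **Movement vector.** m_k = number of suprathreshold ROI pixels in
   subtracted image k. The series M = (m_1 … m_N) is the subject's
   movement signal at effective rate d−1 samples/second.

### Movement features

Per subject and rate, three scalars summarise M:

- **mean** μ = (1/N) Σ m_k — overall movement volume (pixels);
- **windowed variance** — the population variance (1/W normaliser)
  within each sliding window, averaged over windows (pixels²); windowing
  keeps isolated outliers from dominating a whole-session variance;
- **windowed Shannon entropy** — within each window, P_v is the fraction of
  samples exactly equal to integer value v and SE = −Σ P_v log₂ P_v
  (0·log 0 ≡ 0); the per-window entropies are averaged (bits). Entropy
  measures irregularity: a still or perfectly repetitive window scores 0, a
  window of W all-distinct counts scores log₂ W.

Windows are 5 s long with 2.5 s overlap, converted to samples at the
effective rate: W = round(5·(d−1)), hop = floor(W/2). Window k starts at
offset k·hop; L = floor((N−W)/hop) + 1 windows; trailing samples not
covered by a full window are dropped. At d = 6 (N = 1,200, W = 25,
hop = 12) this gives L = 98. At d = 30 the 2.5 s hop is 72.5 samples and is
floored to 72. An alternative window count sometimes written as L = N − W
is not executable with 50 % overlap (its window offsets index past the end
of the series for any N > W + hop), so the standard overlap count above is
used and recorded in the output sidecar.

Entropy probabilities use exact integer counts rather than histogram bins:
m_k are integers by construction, and the point mass at zero during calm
stretches is precisely what separates regular from irregular movers. A
`bin_width` knob exists for sensitivity analysis only.

## Group statistics

Each feature × rate cell is compared between classes with a two-sample
t-test. Welch's unequal-variance form is the default: high-movement
cohorts are empirically far more dispersed than low-movement ones, making
the pooled-variance assumption unsafe; the pooled test is available via
`equal_var=True`. Significance is read at p < 0.05 with no multiplicity
correction by default (Holm available via a flag).

## Feature-discriminability harness

Which single feature carries the most diagnostic signal is decided by a
head-to-head benchmark: each feature alone is the 1-D input to six model
families (RBF-SVM, random forest, CART decision tree, KNN, AdaBoost on CART
stumps, XGBoost), each tuned over a small fixed grid (see
`classify.DEFAULT_GRIDS`; the SVM grid's large-γ/small-C orientation is
kept as published even though the magnitudes are unusual — an override
exists). Protocol:

- outer loop: stratified 10-fold CV (stratification matters — with ~equal
  classes of ~42, unstratified folds can end up single-class, leaving
  sensitivity or specificity undefined);
- inner loop: stratified 5-fold grid search on the outer-training set,
  selecting the hyperparameters with the best mean inner accuracy (the
  tuning objective is chosen to match the headline metric);
- the winner is refit on the full outer-training set and scored on the
  held-out fold: accuracy, sensitivity, specificity, and ROC AUC from
  continuous scores (class probability or decision function), computed per
  fold and averaged;
- the whole procedure is repeated 10 times with reshuffled folds:
  10 × 10 = 100 train/test pairs.

Per-metric variability across the 100 iterations is summarised by the
standard error of the mean, SEM = σ/√n with n = 100 (sample SD). Fold
metrics undefined for a single-class fold are recorded as missing, excluded
from means, and counted in the summary.

Features are ranked per model family and metric by mean performance
(1 = best, ties share the average rank), then ranks are averaged across
families; model families are ranked the same way for a fixed feature.
Scale-sensitive families (SVM, KNN) are standardised with train-fold
mean/SD inside each outer fold; tree ensembles are scale-invariant and fit
raw inputs. Multi-feature input is accepted by `nested_cv` but the
benchmark surface is single-feature by design.

## Synthetic sessions: what they emulate and what they do not

No consultation recordings can ship with the package, so a seeded generator
supplies data with the statistical structure the method assumes:

- **Rendered sessions** (`render_session`): a uniform background, one
  brighter rectangular "subject" blob confined to the ROI, Gaussian sensor
  noise (σ = 2 intensity units, irrelevant against θ = 100), and a
  displacement process — at each frame, with probability `move_prob`, the
  blob jumps by `amplitude_scale` × (1 + `burstiness` × Pareto(1.5)) pixels
  in one of the four axis directions, clamped at the ROI boundary. Two
  knobs map onto the two clinical movement axes: `move_prob` controls how
  often the subject moves, `burstiness` how irregular the magnitudes are.
- **Fast-path series** (`simulate_movement_series`): draws suprathreshold
  pixel counts directly — 0 with probability 1 − move_prob, otherwise a
  count with mean `amplitude_mean` (exactly that value at burstiness 0; a
  unit-mean gamma multiplier with variance burstiness² otherwise), skipping
  the rendering and subtraction stages.
- **Cohorts** (`generate_cohort`): per-subject seeds are derived
  deterministically from one master seed (`numpy` SeedSequence), and each
  subject's move probability and amplitude are drawn from class-level
  distributions so within-class feature spread is nonzero.

The default class presets were calibrated once, against the windowed-entropy
distributions the method operates at on real cohorts (high class ≈ 2.4 ± 0.6
bits, low class ≈ 1.0 ± 0.4 bits at the d=6 window geometry, a pooled-SD
separation near 2.8), and are not tuned thereafter; at these settings
entropy is the most discriminative feature, ahead of mean and variance.
Passing benchmarks on these cohorts shows the harness recovers a
separation of that strength from the generator's statistics — it does not
show that real consultation video of any particular population separates
this way. The generator deliberately omits photorealistic subjects,
articulated pose, multiple people, camera shake, lighting drift, and lossy
codec artifacts; conclusions about those belong to real recordings.

## Numerical and interface choices

- Lossless storage (PNG frame directories) is the package's interchange
  format: lossy codecs perturb exactly the intensity differences being
  thresholded. Container video is decoded when an imageio plugin can handle
  it; rate metadata mismatches resolve in favour of the container, with a
  warning.
- Round-half-even is used wherever fractional indices or luma values are
  rounded; all rounding rules are deterministic and tested.
- θ is strict (difference must exceed, not equal, the threshold).
- Degenerate t-test inputs (both groups constant and equal) return p = 1.
- Sessions shorter than the analysis clip raise an explicit error rather
  than being padded; padding would deflate every per-second count.
- Per-stage seeds are derived from the master seed by SHA-256, so changing
  one stage's configuration never reshuffles another stage's randomness;
  all derived seeds stay below 2³¹.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely on synthetic data at
reduced spatial resolution (32 × 24 to 160 × 120 frames): ROI pixel counts
scale with resolution, but every bookkeeping law (frame counts, window
counts, fold counts) and every statistical property under test is
resolution-independent. The discriminability benchmark uses the full
43 + 42 cohort, the full 10 × 10 × 5 CV protocol, the fast-path generator at
d = 6 series geometry (N = 1,200), and a 6–8-permutation Monte-Carlo null;
the permutation null uses 2 repeats per permutation, since between-
permutation variation, not fold noise, dominates its uncertainty.

## Known limitations

- The ROI is supplied per session; there is no automatic subject detection,
  and anything else moving inside the ROI is counted as subject movement.
- The within-block frame-selection rule and the window-count rule are
  deterministic conventions chosen for exact bookkeeping; other readings of
  per-second downsampling exist and would change N by a few samples.
- Entropy on exact integer counts is resolution-dependent: halving the
  frame area roughly halves the count alphabet. Comparisons are only
  meaningful within one recording geometry.
- The benchmark estimates discriminability of single features under this
  protocol; it is not a diagnostic device and reports no per-subject
  decision.
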