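# fidgetquant

Objective movement quantification from fixed-camera consultation-room
video, and a benchmark harness for deciding which movement feature best
separates high-fidget from low-fidget subjects.

Hyperactivity assessment in paediatric practice leans on subjective rating
scales filled in by parents and teachers. A plain 2-D camera in the
consultation room offers an objective alternative: if the scene is static
and the subject sits in a known region of the frame, frame differencing
turns "how much does this child move, and how erratically?" into a number.
`fidgetquant` implements that measurement chain and the statistical
machinery to evaluate it, for researchers studying video-based actimetry.

## Method

For a video at F frames/second, each 1-second block is reduced to *d*
frames at endpoint-inclusive uniform positions and consecutive retained
frames are subtracted, giving d−1 subtracted images per second. Within a
per-subject rectangular region of interest (ROI, set of coordinates SA), a
pixel of subtracted image k counts as moved when its absolute intensity
difference strictly exceeds a threshold θ (default 100):

    ROI_k(i,j) = 1  if |Q'_k(i,j)| > θ, else 0,   (i,j) ∈ SA
    m_k = Σ_{(i,j)∈SA} ROI_k(i,j),   M = (m_1, …, m_N)

A 4-minute clip at d = 6 yields exactly N = 240 × 5 = 1,200 subtracted
images. Three features summarise M per subject: the mean
μ = (1/N) Σ m_k; the sliding-window variance v̄ar (population variance per
5 s window, 2.5 s overlap, averaged over windows); and the sliding-window
Shannon entropy s̄e = mean over windows of −Σ_v P_v log₂ P_v, where P_v is
the within-window frequency of exact count value v. Entropy captures
irregularity — the signature of fidgeting — and is bounded by log₂ W for a
W-sample window.

Feature discriminability is estimated with repeated nested cross-
validation: stratified 10-fold outer loop for testing, stratified 5-fold
inner grid search for hyperparameters, repeated 10 times (100 train/test
pairs), over six model families (RBF-SVM, random forest, CART tree, KNN,
AdaBoost, XGBoost) with small fixed grids, each feature entering alone as a
1-D input. Per-metric spread across the 100 iterations is reported as
SEM = σ/√100. Classes are additionally compared per feature × rate with
Welch's two-sample t-test.

Because no consultation recordings can be distributed, the package includes
a seeded synthetic-session generator (moving blob inside the ROI; knobs for
move probability, amplitude, and burstiness) whose default two-class
cohorts reproduce the entropy separation the method operates at on real
cohorts (≈ 2.4 ± 0.6 vs ≈ 1.0 ± 0.4 bits).

## Worked example

```python
import numpy as np
from fidgetquant import (
    SyntheticSessionParams, ROISpec, SubtractionConfig, WindowConfig,
    render_session, quantify_session, extract_features,
)

params = SyntheticSessionParams(
    frame_width=160, frame_height=120, rate=30, duration=240.0,
    roi=ROISpec(30, 20, 130, 100), move_prob=0.5, amplitude_scale=6.0,
    burstiness=1.0, seed=42,
)
seq = render_session(params)                      # 7200 frames, 30 Hz
cfg = SubtractionConfig(theta=100, downsample_rate=6, clip_seconds=240.0)
series = quantify_session(seq, params.roi, cfg)   # N = 1200 counts at 5/s
rec = extract_features(series, WindowConfig(), "demo", "pos")
print(series.n, round(rec.mu, 1), round(rec.var_bar, 1), round(rec.se_bar, 3))
```

prints

```
1200 911.6 313567.0 3.991
```

— 1,200 subtracted images; on average ≈ 912 ROI pixels crossed the movement
threshold per subtracted frame; the windowed variance is large because the
burst process mixes big jumps with still stretches; and the windowed
entropy of ≈ 3.99 bits (out of log₂ 25 ≈ 4.64 for a 25-sample window) marks
a highly irregular mover.

The same flow is scriptable from the shell:

```
fidgetquant simulate --out session/ --seed 42
fidgetquant quantify --video session/ --roi 30,20,130,100 --rate-d 6 --out series.csv
fidgetquant features --series series.csv --out features.csv
fidgetquant run --seed 1 --out results/    # full synthetic cohort pipeline
fidgetquant report results/
```

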