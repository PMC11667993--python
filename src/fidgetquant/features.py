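"""The three movement features: mean, windowed variance, windowed entropy.

Each feature summarises the movement vector M (suprathreshold pixel counts
per subtracted frame) for one subject:

* ``mu`` — the arithmetic mean of M: overall amount of movement.
* ``var_bar`` — population variance within each sliding window, averaged
  over windows: magnitude of movement fluctuation, windowed so isolated
  outliers do not dominate.
* ``se_bar`` — Shannon entropy of the empirical distribution of exact
  integer count values within each window, averaged over windows:
  irregularity/unpredictability of movement. A perfectly still or perfectly
  repetitive window has entropy 0; a window whose W samples are all distinct
  has the maximum, log2(W).

Windows are 5 s with 2.5 s overlap by default, converted to samples at the
series' effective rate (d - 1 subtracted frames per second).

Entropy probabilities come from exact integer value counts, not histogram
bins: the counts are integers by construction, and the mass at zero during
calm stretches is precisely what makes the measure discriminative. An
optional ``bin_width`` knob coarsens the values for sensitivity analysis.
"""

from __future__ import annotations

import numpy as np

from .datatypes import FeatureRecord, MovementSeries, WindowConfig
from .errors import EmptySeriesError


def mean_movement(series: MovementSeries) -> float:
    """Arithmetic mean of the movement vector."""
    if series.n == 0:
        raise EmptySeriesError("cannot average an empty movement series")
    return float(series.m.mean())


def make_windows(series: MovementSeries, cfg: WindowConfig) -> np.ndarray:
    """Slice the series into L overlapping windows of W samples.

    Window k (0-based) starts at offset k * hop; L = floor((N - W)/hop) + 1.
    Trailing samples not covered by a full window are dropped.
    """
    w = cfg.window_samples(series.effective_rate)
    hop = cfg.hop_samples(series.effective_rate)
    n = series.n
    if n < w:
        raise EmptySeriesError(
            f"series of {n} samples is shorter than the {w}-sample window"
        )
    n_windows = (n - w) // hop + 1
    starts = np.arange(n_windows) * hop
    return series.m[starts[:, None] + np.arange(w)]


def windowed_variance(series: MovementSeries, cfg: WindowConfig) -> float:
    """Average over windows of the within-window population variance."""
    windows = make_windows(series, cfg)
    return float(windows.var(axis=1, ddof=0).mean())


def _window_entropy(values: np.ndarray, bin_width: int | None) -> float:
    if bin_width is not None and bin_width > 1:
        values = values // bin_width
    _, counts = np.unique(values, return_counts=True)
    p = counts / values.size
    return float(-(p * np.log2(p)).sum())


def windowed_entropy(
    series: MovementSeries, cfg: WindowConfig, bin_width: int | None = None
) -> float:
    """Average over windows of the within-window Shannon entropy (bits).

    P_v is the fraction of the window's samples equal to integer value v
    (optionally coarsened to bins of ``bin_width``); SE = -sum P_v log2 P_v
    with 0 log 0 = 0.
    """
    windows = make_windows(series, cfg)
    return float(np.mean([_window_entropy(win, bin_width) for win in windows]))


def extract_features(
    series: MovementSeries,
    cfg: WindowConfig,
    subject_id: str,
    label: str,
    rate_d: int | None = None,
) -> FeatureRecord:
    """Bundle the three features with subject identity and sampling rate."""
    d = rate_d if rate_d is not None else int(round(series.effective_rate)) + 1
    return FeatureRecord(
        subject_id=subject_id,
        label=label,
        rate_d=d,
        mu=mean_movement(series),
        var_bar=windowed_variance(series, cfg),
        se_bar=windowed_entropy(series, cfg),
    )
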