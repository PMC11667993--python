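"""Per-second downsampling, pixel subtraction, ROI thresholding.

The quantification pipeline for one session:

1. Clip to the analysis window (default first 240 s) and split into
   1-second blocks of F = rate frames.
2. Within each block keep d frames at endpoint-inclusive uniform positions
   (``select_block_frames``); blocks are independent — no frame pair spans a
   second boundary, so d retained frames yield exactly d - 1 subtracted
   images per second and a 4-minute clip at d = 6 yields 240 x 5 = 1,200.
3. Absolute pixel subtraction of consecutive retained frames
   (``subtract_pair``), restricted to the region of interest.
4. Binarize: a pixel counts as moved when its difference STRICTLY exceeds
   the significance threshold theta (``binarize_roi``).
5. Count suprathreshold ROI pixels per subtracted image
   (``movement_series``): the movement vector M.

Subtraction is computed on ROI crops rather than full frames; cropping and
absolute subtraction commute pixelwise, so this is purely a speed choice.
"""

from __future__ import annotations

import numpy as np

from .datatypes import GraySequence, MovementSeries, ROISpec, SubtractionConfig
from .errors import ConfigurationError, EmptySeriesError, FormatError


def block_indices(rate: int, d: int) -> np.ndarray:
    """0-based within-block indices of the d retained frames.

    Endpoint-inclusive uniform placement over a block of F = rate frames:
    the 1-based index of retained frame i (i = 1..d) is
    ``round(1 + (i - 1)(F - 1)/(d - 1))`` with round-half-even. At d = F this
    is the identity; at F = 30, d = 6 it selects frames {1, 7, 13, 18, 24, 30}.
    """
    if d < 2:
        raise ConfigurationError(f"downsample rate d must be >= 2, got {d}")
    if d > rate:
        raise ConfigurationError(f"downsample rate d={d} exceeds frame rate {rate}")
    return np.array(
        [round(1 + (i - 1) * (rate - 1) / (d - 1)) - 1 for i in range(1, d + 1)],
        dtype=np.intp,
    )


def select_block_frames(seq: GraySequence, d: int) -> GraySequence:
    """Retain d frames per 1-second block of the sequence.

    The sequence must span whole seconds (n_frames divisible by rate).
    """
    rate = int(round(seq.rate))
    if seq.n_frames % rate != 0:
        raise ConfigurationError(
            f"sequence of {seq.n_frames} frames does not span whole seconds at {rate} fps"
        )
    idx = block_indices(rate, d)
    n_blocks = seq.n_frames // rate
    blocks = seq.frames.reshape(n_blocks, rate, seq.height, seq.width)
    selected = blocks[:, idx].reshape(n_blocks * d, seq.height, seq.width)
    return GraySequence(frames=selected, rate=float(d))


def subtract_pair(fa: np.ndarray, fb: np.ndarray) -> np.ndarray:
    """Elementwise absolute difference |fb - fa| of two grayscale frames."""
    fa = np.asarray(fa)
    fb = np.asarray(fb)
    if fa.shape != fb.shape:
        raise FormatError(f"frame shape mismatch: {fa.shape} vs {fb.shape}")
    return np.abs(fb.astype(np.int16) - fa.astype(np.int16)).astype(np.uint8)


def binarize_roi(diff: np.ndarray, roi: ROISpec, theta: int) -> np.ndarray:
    """Binary ROI mask: 1 where the difference strictly exceeds theta.

    Pixels outside the ROI are excluded from the mask entirely; equality
    with theta does not count as movement.
    """
    cropped = roi.crop(np.asarray(diff))
    return (cropped > theta).astype(np.uint8)


def movement_series(
    masks: np.ndarray, effective_rate: float = 1.0
) -> MovementSeries:
    """Sum each binary ROI mask into a suprathreshold pixel count m_k."""
    masks = np.asarray(masks)
    if masks.size == 0 or masks.ndim != 3:
        raise EmptySeriesError("need a nonempty stack of 2-D binary masks")
    counts = masks.reshape(masks.shape[0], -1).sum(axis=1)
    roi_area = int(masks.shape[1] * masks.shape[2])
    return MovementSeries(
        m=counts.astype(np.int64), effective_rate=effective_rate, roi_area=roi_area
    )


def quantify_session(
    seq: GraySequence, roi: ROISpec, cfg: SubtractionConfig
) -> MovementSeries:
    """Full session quantification: clip, downsample, subtract, threshold, count.

    Returns the movement vector with N = clip_seconds x (d - 1) samples at an
    effective rate of d - 1 subtracted frames per second.
    """
    rate = int(round(seq.rate))
    n_needed = int(round(cfg.clip_seconds * rate))
    if seq.n_frames < n_needed:
        raise ConfigurationError(
            f"session has {seq.n_frames} frames but the {cfg.clip_seconds} s "
            f"clip needs {n_needed}"
        )
    roi.validate_within(seq.height, seq.width)
    clipped = GraySequence(frames=seq.frames[:n_needed], rate=float(rate))
    selected = select_block_frames(clipped, cfg.downsample_rate)

    d = cfg.downsample_rate
    n_blocks = int(round(cfg.clip_seconds))
    # ROI crop first: |crop(a) - crop(b)| == crop(|a - b|)
    cropped = selected.frames[:, roi.y0 : roi.y1, roi.x0 : roi.x1]
    blocks = cropped.reshape(n_blocks, d, roi.height, roi.width).astype(np.int16)
    diffs = np.abs(np.diff(blocks, axis=1))               # (blocks, d-1, h, w)
    counts = (diffs > cfg.theta).sum(axis=(2, 3)).reshape(-1)
    return MovementSeries(
        m=counts.astype(np.int64),
        effective_rate=float(d - 1),
        roi_area=roi.area,
    )
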