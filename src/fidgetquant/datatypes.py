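"""Core value types shared across the pipeline.

The pipeline's raw material is a stack of grayscale frames (`GraySequence`);
frame differencing restricted to a rectangular region of interest (`ROISpec`)
and thresholding produce a per-subtracted-frame count series
(`MovementSeries`), from which three scalar features are computed per subject
(`FeatureRecord`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, FormatError


@dataclass(frozen=True)
class ROISpec:
    """Axis-aligned region of interest, 0-based, half-open: [x0, x1) x [y0, y1).

    Set per session (subject height varies), it restricts all movement
    measurement to the area occupied by the subject.
    """

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (0 <= self.x0 < self.x1 and 0 <= self.y0 < self.y1):
            raise ConfigurationError(
                f"invalid ROI rectangle ({self.x0},{self.y0},{self.x1},{self.y1}): "
                "need 0 <= x0 < x1 and 0 <= y0 < y1"
            )

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height

    def validate_within(self, frame_height: int, frame_width: int) -> None:
        if self.x1 > frame_width or self.y1 > frame_height:
            raise ConfigurationError(
                f"ROI {self} exceeds frame bounds {frame_width}x{frame_height}"
            )

    def crop(self, frame: np.ndarray) -> np.ndarray:
        """Crop an H x W (or H x W x C) raster to the ROI."""
        self.validate_within(frame.shape[0], frame.shape[1])
        return frame[self.y0 : self.y1, self.x0 : self.x1]

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.x0, self.y0, self.x1, self.y1)


@dataclass(frozen=True)
class GraySequence:
    """Ordered grayscale frames plus their nominal sampling rate.

    `frames` is an (n, H, W) uint8 array; every frame shares the same
    geometry so pairwise subtraction is well defined.
    """

    frames: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        if f.ndim != 3:
            raise FormatError(f"frames must be (n, H, W); got shape {f.shape}")
        if f.dtype != np.uint8:
            if np.issubdtype(f.dtype, np.integer) and f.min(initial=0) >= 0 and f.max(initial=0) <= 255:
                f = f.astype(np.uint8)
            else:
                raise FormatError("frame intensities must be integers in [0, 255]")
        if self.rate <= 0:
            raise ConfigurationError(f"rate must be positive, got {self.rate}")
        object.__setattr__(self, "frames", f)

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def height(self) -> int:
        return int(self.frames.shape[1])

    @property
    def width(self) -> int:
        return int(self.frames.shape[2])

    @property
    def duration(self) -> float:
        return self.n_frames / self.rate


@dataclass(frozen=True)
class SubtractionConfig:
    """Parameters of the downsample-subtract-threshold stage.

    theta: intensity threshold; a subtracted pixel counts as moved only when
        its absolute difference STRICTLY exceeds theta (default 100).
    downsample_rate: d, frames retained per second before differencing;
        d retained frames yield d - 1 subtracted images per second.
    clip_seconds: length of the analysed prefix of each recording (default
        240 s, i.e. the first 4 minutes, so sessions of varying length are
        compared on equal footing).
    """

    theta: int = 100
    downsample_rate: int = 6
    clip_seconds: float = 240.0

    def __post_init__(self) -> None:
        if not (0 <= self.theta <= 255):
            raise ConfigurationError(f"theta must be in [0, 255], got {self.theta}")
        if self.downsample_rate < 2:
            raise ConfigurationError(
                f"downsample_rate must be >= 2 (need at least one pair per second), got {self.downsample_rate}"
            )
        if self.clip_seconds <= 0:
            raise ConfigurationError(f"clip_seconds must be positive, got {self.clip_seconds}")


@dataclass(frozen=True)
class MovementSeries:
    """Per-subtracted-frame counts of suprathreshold ROI pixels.

    m[k] is the number of pixels inside the ROI whose absolute frame
    difference exceeded the threshold in subtracted image k. The series is
    the 1-D signal every movement feature is computed from.
    """

    m: np.ndarray
    effective_rate: float  # subtracted frames per second = d - 1
    roi_area: int

    def __post_init__(self) -> None:
        m = np.asarray(self.m)
        if m.ndim != 1:
            raise FormatError(f"movement series must be 1-D, got shape {m.shape}")
        if m.size and (m.min() < 0 or m.max() > self.roi_area):
            raise FormatError("movement counts must lie in [0, roi_area]")
        if self.effective_rate <= 0:
            raise ConfigurationError("effective_rate must be positive")
        object.__setattr__(self, "m", m.astype(np.int64))

    @property
    def n(self) -> int:
        return int(self.m.size)


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window geometry for the variance and entropy features.

    Window and overlap are given in seconds (defaults 5 and 2.5) and
    converted to samples at the series' effective rate: W = round(window *
    rate); hop = floor(W * (1 - overlap/window)), i.e. floor(W/2) at the
    default half-overlap. Trailing samples not covered by a full window are
    dropped.
    """

    window_seconds: float = 5.0
    overlap_seconds: float = 2.5

    def __post_init__(self) -> None:
        if self.window_seconds <= 0:
            raise ConfigurationError("window_seconds must be positive")
        if not (0 <= self.overlap_seconds < self.window_seconds):
            raise ConfigurationError("overlap_seconds must be in [0, window_seconds)")

    def window_samples(self, effective_rate: float) -> int:
        w = round(self.window_seconds * effective_rate)
        if w < 1:
            raise ConfigurationError("window shorter than one sample at this rate")
        return w

    def hop_samples(self, effective_rate: float) -> int:
        w = self.window_samples(effective_rate)
        hop = math.floor(w * (1.0 - self.overlap_seconds / self.window_seconds))
        return max(hop, 1)


@dataclass(frozen=True)
class FeatureRecord:
    """One subject x one downsampling rate -> the three movement features."""

    subject_id: str
    label: str
    rate_d: int
    mu: float        # mean suprathreshold pixel count (pixels)
    var_bar: float   # averaged windowed variance (pixels^2)
    se_bar: float    # averaged windowed Shannon entropy (bits)

    def __post_init__(self) -> None:
        if self.mu < 0 or self.var_bar < 0 or self.se_bar < 0:
            raise FormatError("movement features must be nonnegative")

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "label": self.label,
            "rate_d": self.rate_d,
            "mu": self.mu,
            "var_bar": self.var_bar,
            "se_bar": self.se_bar,
        }


FEATURE_COLUMNS = ("mu", "var_bar", "se_bar")
FEATURE_NAMES = {"mu": "mean", "var_bar": "variance", "se_bar": "shannon_entropy"}
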