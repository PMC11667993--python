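"""Decode video into grayscale frame sequences and clip to the analysis window.

Two dialects are supported:

* **PNG frame directories** — the lossless interchange format this package
  writes (``frame_000000.png`` ... plus a ``session.json`` sidecar carrying
  the sampling rate). Lossless storage matters: pixel subtraction thresholds
  raw intensity differences, and lossy codecs perturb exactly the quantity
  being measured.
* **Video containers** (MP4/AVI/MKV/...) via whatever imageio plugin can
  decode them. If no plugin handles the file an I/O error is raised.

Grayscale conversion uses ITU-R BT.601 luma (0.299 R + 0.587 G + 0.114 B),
rounded half-to-even — the dominant convention in video tooling; the choice
is recorded in output sidecars so it is auditable.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np

from .datatypes import GraySequence
from .errors import FormatError, InsufficientFootageError

BT601_WEIGHTS = np.array([0.299, 0.587, 0.114])

_SIDECAR = "session.json"


def to_grayscale(rgb_frame: np.ndarray) -> np.ndarray:
    """Convert an H x W x 3 RGB raster to BT.601 luma, rounded half-even.

    A frame that is already 2-D is passed through unchanged (it is its own
    luma). Channel values must lie in [0, 255].
    """
    arr = np.asarray(rgb_frame)
    if arr.ndim == 2:
        return arr.astype(np.uint8)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(
            f"expected H x W x 3 RGB frame, got shape {arr.shape}"
        )
    if arr.min() < 0 or arr.max() > 255:
        raise FormatError("channel values must lie in [0, 255]")
    luma = arr.astype(np.float64) @ BT601_WEIGHTS
    return np.rint(luma).astype(np.uint8)


def write_session(seq: GraySequence, path: str | Path) -> Path:
    """Write a grayscale sequence as a PNG frame directory (lossless).

    Creates ``path/frame_000000.png`` ... and a ``session.json`` sidecar with
    the sampling rate and conversion provenance. Returns the directory path.
    """
    import imageio.v3 as iio

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(seq.frames):
        iio.imwrite(path / f"frame_{i:06d}.png", frame)
    sidecar = {
        "rate": seq.rate,
        "n_frames": seq.n_frames,
        "height": seq.height,
        "width": seq.width,
        "grayscale": "bt601-round-half-even",
    }
    (path / _SIDECAR).write_text(json.dumps(sidecar, indent=1))
    return path


def _load_frame_dir(path: Path) -> tuple[np.ndarray, float | None]:
    import imageio.v3 as iio

    files = sorted(path.glob("frame_*.png")) or sorted(path.glob("*.png"))
    if not files:
        raise IOError(f"no PNG frames found in directory {path}")
    frames = []
    for f in files:
        img = iio.imread(f)
        if img.ndim == 3:
            img = img[..., :3] if img.shape[2] >= 3 else img[..., 0]
        frames.append(img)
    rate = None
    sidecar = path / _SIDECAR
    if sidecar.exists():
        rate = json.loads(sidecar.read_text()).get("rate")
    return np.stack(frames), rate


def _load_container(path: Path) -> tuple[np.ndarray, float | None]:
    import imageio.v3 as iio

    try:
        frames = iio.imread(path, index=None)
        meta = iio.immeta(path)
    except Exception as exc:  # no plugin for this container in this install
        raise IOError(f"cannot decode video file {path}: {exc}") from exc
    rate = meta.get("fps")
    return np.asarray(frames), rate


def load_session(
    path: str | Path,
    clip_seconds: float | None = None,
    rate: float | None = None,
) -> GraySequence:
    """Load a session, grayscale-convert it and clip it to the analysis window.

    Parameters
    ----------
    path
        PNG frame directory or a decodable video file.
    clip_seconds
        If given, return exactly ``clip_seconds * rate`` frames from the
        start. A shorter recording raises :class:`InsufficientFootageError`
        rather than being silently padded.
    rate
        Nominal sampling rate in frames/second. If the source itself reports
        a rate that disagrees, the source's rate wins with a warning —
        a silent mismatch would corrupt all per-second block logic.
    """
    path = Path(path)
    if path.is_dir():
        raw, src_rate = _load_frame_dir(path)
    elif path.exists():
        raw, src_rate = _load_container(path)
    else:
        raise IOError(f"no such file or directory: {path}")

    if src_rate is not None and rate is not None and src_rate != rate:
        warnings.warn(
            f"{path}: container reports {src_rate} fps but {rate} was requested; "
            "using the container rate",
            stacklevel=2,
        )
    eff_rate = src_rate if src_rate is not None else rate
    if eff_rate is None:
        raise ValueError(f"{path} carries no rate metadata; pass rate= explicitly")

    if raw.ndim == 4:
        frames = np.stack([to_grayscale(f[..., :3]) for f in raw])
    elif raw.ndim == 3:
        frames = raw.astype(np.uint8)
    else:
        raise FormatError(f"unexpected frame stack shape {raw.shape}")

    if clip_seconds is not None:
        n_wanted = int(round(clip_seconds * eff_rate))
        if frames.shape[0] < n_wanted:
            raise InsufficientFootageError(
                f"{path}: {frames.shape[0]} frames "
                f"({frames.shape[0] / eff_rate:.1f} s) < requested clip of "
                f"{clip_seconds} s ({n_wanted} frames)"
            )
        frames = frames[:n_wanted]

    return GraySequence(frames=frames, rate=float(eff_rate))
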