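import numpy as np
import pytest

from fidgetquant import (
    ROISpec,
    SubtractionConfig,
    SyntheticSessionParams,
    WindowConfig,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def tiny_params():
    """A short low-resolution session: 6 s at 10 fps, 40x30 frames."""
    return SyntheticSessionParams(
        frame_width=40,
        frame_height=30,
        rate=10,
        duration=6.0,
        roi=ROISpec(5, 5, 35, 25),
        blob_width=8,
        blob_height=10,
        move_prob=0.6,
        amplitude_scale=3.0,
        burstiness=1.0,
        sensor_noise_sd=2.0,
        seed=11,
    )


@pytest.fixture
def tiny_cfg():
    return SubtractionConfig(theta=100, downsample_rate=5, clip_seconds=6.0)


@pytest.fixture
def default_window():
    return WindowConfig()
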