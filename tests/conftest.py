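import numpy as np
import pytest
from scipy.ndimage import gaussian_filter, shift as nd_shift

from aviresp.config import PipelineConfig
from aviresp.synthetic_data import SyntheticConfig, generate_clip


@pytest.fixture(scope="session")
def default_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def quiet_clip_bundle():
    """A 12-s quiet breathing clip at 1.1 Hz with its truth and ROIs."""
    cfg = SyntheticConfig(true_rr_hz=1.1, duration_s=12.0, seed=11)
    return generate_clip(cfg)


@pytest.fixture(scope="session")
def smooth_texture():
    """A band-limited random texture, reused for flow and pyramid tests."""
    rng = np.random.default_rng(7)
    return gaussian_filter(rng.normal(0.0, 1.0, (128, 128)), 2.0)


def translated_pair(texture: np.ndarray, dx: float, dy: float, crop: int = 16):
    """A frame pair where the second is the first shifted by (dx, dy) px."""
    a = texture[crop:-crop, crop:-crop]
    b = nd_shift(texture, (dy, dx), order=3)[crop:-crop, crop:-crop]
    return a.astype(np.float32), b.astype(np.float32)


def grating_motion_frames(
    n_frames: int = 300,
    fps: float = 30.0,
    omega: float = np.pi / 2,
    amp_px: float = 0.1,
    freq_hz: float = 1.0,
    size: int = 64,
) -> np.ndarray:
    """Analytic sinusoidal grating translating sub-pixel-sinusoidally.

    Evaluated in closed form, so the displacement is exact — no
    interpolation error contaminates gain or frequency measurements.
    """
    _, x = np.mgrid[0:size, 0:size].astype(float)
    t = np.arange(n_frames) / fps
    delta = amp_px * np.sin(2 * np.pi * freq_hz * t)
    return np.stack([np.sin(omega * (x + d)) for d in delta])
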