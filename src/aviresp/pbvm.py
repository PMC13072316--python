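"""Phase-based motion magnification without reconstruction.

Local spatial phase in each steerable-pyramid sub-band encodes local
displacement: a pattern of spatial frequency ω displaced by δ(t) carries
the phase term ω·(x + δ(t)).  Removing the static part with a DC-balanced
ideal temporal band-pass leaves the pure motion signal B(x, t) = ω·δ(t);
adding α·B back to the sub-band phase would displace the pattern by
(1+α)·δ(t).  Since only the respiratory *frequency* is needed downstream,
the amplified phase signals are aggregated directly into a single motion
time series — the magnified video itself is never rendered, which avoids
reconstruction distortion entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, EmptySignalError
from .steerable_pyramid import PyramidStack, temporal_unwrap

DEFAULT_ALPHA = 40.0
DEFAULT_F_LO = 0.3
DEFAULT_F_HI = 3.0


@dataclass(frozen=True)
class BandpassConfig:
    """Ideal (hard frequency-domain mask) temporal band-pass in Hz."""

    f_lo: float = DEFAULT_F_LO
    f_hi: float = DEFAULT_F_HI
    filter_kind: str = "ideal"

    def __post_init__(self) -> None:
        if self.filter_kind != "ideal":
            raise ConfigError(f"unsupported filter kind {self.filter_kind!r}")
        if not 0 < self.f_lo < self.f_hi:
            raise ConfigError(f"need 0 < f_lo < f_hi, got [{self.f_lo}, {self.f_hi}]")

    @property
    def bandwidth_hz(self) -> float:
        """Absolute bandwidth of the pass band."""
        return self.f_hi - self.f_lo

    def validate_for_fps(self, fps: float) -> None:
        if self.f_hi >= fps / 2:
            raise ConfigError(f"f_hi={self.f_hi} Hz at or above Nyquist ({fps / 2} Hz)")


def temporal_bandpass(series: np.ndarray, fps: float, cfg: BandpassConfig) -> np.ndarray:
    """Ideal band-pass along axis 0: keep DFT bins with f_lo ≤ |f| ≤ f_hi.

    DC and all out-of-band bins are zeroed, so the output is real,
    zero-mean, and the operator is linear and idempotent.
    """
    series = np.asarray(series, dtype=np.float64)
    n = series.shape[0]
    if n < 4:
        raise ConfigError(f"series of length {n} too short to filter")
    cfg.validate_for_fps(fps)
    spec = np.fft.rfft(series, axis=0)
    freqs = np.fft.rfftfreq(n, d=1.0 / fps)
    keep = (freqs >= cfg.f_lo) & (freqs <= cfg.f_hi)
    shape = [-1] + [1] * (series.ndim - 1)
    spec = spec * keep.reshape(shape)
    return np.fft.irfft(spec, n=n, axis=0)


@dataclass
class BandSignals:
    """Amplified phase series of one sub-band's retained pixels."""

    scale: int
    orientation: int
    series: np.ndarray  # T × P, radians, zero-mean
    weights: np.ndarray  # P, time-mean squared amplitude


@dataclass
class PhaseSignalSet:
    """Band-passed, amplified phase signals across all sub-bands."""

    bands: list[BandSignals]
    fps: float
    alpha: float
    cfg: BandpassConfig

    @property
    def n_series(self) -> int:
        return sum(b.series.shape[1] for b in self.bands)


@dataclass(frozen=True)
class RespiratorySignal:
    """The single aggregated motion time series fed to spectral analysis."""

    values: np.ndarray
    fps: float
    provenance: dict = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        return self.values.shape[0] / self.fps


def amplify_phase(
    stack: PyramidStack,
    cfg: BandpassConfig = BandpassConfig(),
    alpha: float = DEFAULT_ALPHA,
) -> PhaseSignalSet:
    """Extract, band-pass and amplify per-pixel sub-band phase.

    For every retained pixel of every (scale, orientation) band: the phase
    is temporally unwrapped, band-passed to the respiratory range, and
    scaled so the represented displacement is (1+α) times the true one.
    Pixels whose time-mean amplitude falls below the floor are dropped —
    their phase is noise.  Weights are the time-mean squared amplitudes.
    """
    cfg.validate_for_fps(stack.fps)
    floor = stack.amplitude_floor()
    bands: list[BandSignals] = []
    for scale in range(stack.levels):
        for orient in range(stack.orientations):
            coeffs = stack.subband_series(scale, orient)
            amp = np.abs(coeffs)
            mean_amp = amp.mean(axis=0)
            retain = mean_amp >= floor
            if not retain.any():
                continue
            phase = temporal_unwrap(np.angle(coeffs[:, retain]))
            motion = temporal_bandpass(phase, stack.fps, cfg)
            bands.append(
                BandSignals(
                    scale=scale,
                    orientation=orient,
                    series=(1.0 + alpha) * motion,
                    weights=mean_amp[retain] ** 2,
                )
            )
    if not bands:
        raise EmptySignalError("every pixel fell below the amplitude floor")
    return PhaseSignalSet(bands=bands, fps=stack.fps, alpha=alpha, cfg=cfg)


def aggregate_signal(signal_set: PhaseSignalSet, provenance: dict | None = None) -> RespiratorySignal:
    """Amplitude²-weighted mean of all series with per-series sign alignment.

    The sign of a phase excursion depends on the local gradient direction
    (opposite edges of a moving blob swing in antiphase), so naive
    averaging cancels; each series is flipped when negatively correlated
    with the running weighted mean before being folded in.  Series are
    folded in descending weight order so the alignment reference is the
    most reliable signal available.
    """
    series_list: list[np.ndarray] = []
    weights_list: list[float] = []
    for band in signal_set.bands:
        for j in range(band.series.shape[1]):
            series_list.append(band.series[:, j])
            weights_list.append(float(band.weights[j]))
    weights = np.asarray(weights_list)
    if weights.sum() <= 0 or not series_list:
        raise EmptySignalError("zero total weight: nothing to aggregate")
    order = np.argsort(weights)[::-1]
    acc = np.zeros_like(series_list[0])
    total_w = 0.0
    for idx in order:
        s = series_list[idx]
        w = weights[idx]
        if w <= 0:
            continue
        if total_w > 0 and np.dot(acc, s) < 0:
            s = -s
        acc = acc + w * s
        total_w += w
    values = acc / total_w
    values = values - values.mean()
    return RespiratorySignal(values=values, fps=signal_set.fps, provenance=provenance or {})
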