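"""Respiratory-rate estimation from the FFT magnitude spectrum.

The aggregated motion signal is periodic at the respiratory rate, so its
magnitude spectrum F_k = Σ_n f_n·e^{-i2πkn/N} shows an energy peak at
that frequency.  The peak-validity rule keeps only peaks inside the
physiological band 0.3–3.0 Hz and takes the largest in-band magnitude as
the RR; everything else is treated as interference.  A 10-s window at
30 fps has 0.1-Hz native bin spacing, so an optional 3-point parabolic
interpolation of the log-magnitude around the peak refines the estimate
below the bin width.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .core_io import RoiSpec, VideoClip, crop
from .errors import EmptySignalError, NoValidPeakError
from .pbvm import BandpassConfig, PhaseSignalSet, RespiratorySignal, aggregate_signal, amplify_phase
from .quiet_screening import QuietWindow, select_quiet_segment
from .steerable_pyramid import PyramidStack


@dataclass(frozen=True)
class Spectrum:
    """One-sided DFT magnitude spectrum of a real time series."""

    freqs: np.ndarray  # Hz, ascending from 0 to fps/2
    magnitude: np.ndarray  # |F_k| per bin
    n: int  # signal length N
    fps: float

    @property
    def bin_spacing_hz(self) -> float:
        return self.fps / self.n


@dataclass(frozen=True)
class RRMeasurement:
    """A respiratory-rate estimate with its spectral peak and provenance."""

    rr_hz: float
    peak_magnitude: float
    refined: bool
    window: QuietWindow | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def rr_bpm(self) -> float:
        return 60.0 * self.rr_hz


def compute_spectrum(signal: RespiratorySignal) -> Spectrum:
    """DFT magnitudes of the mean-removed signal, rectangular window, one-sided."""
    values = np.asarray(signal.values, dtype=np.float64)
    if values.shape[0] < 8:
        raise EmptySignalError(f"signal of {values.shape[0]} samples too short for spectral analysis")
    values = values - values.mean()
    spec = np.fft.rfft(values)
    freqs = np.fft.rfftfreq(values.shape[0], d=1.0 / signal.fps)
    return Spectrum(freqs=freqs, magnitude=np.abs(spec), n=values.shape[0], fps=signal.fps)


def _parabolic_refine(spec: Spectrum, k: int) -> tuple[float, bool]:
    """Sub-bin peak frequency by a log-magnitude parabola over bins k−1..k+1."""
    if k <= 0 or k >= spec.magnitude.shape[0] - 1:
        return spec.freqs[k], False
    triplet = spec.magnitude[k - 1 : k + 2]
    # neighbours at numerical-noise level mean the tone sits exactly on the
    # bin: the parabola would fit round-off, so keep the bin frequency
    if np.any(triplet <= 0) or min(triplet[0], triplet[2]) < 1e-9 * triplet[1]:
        return spec.freqs[k], False
    lm, c, rm = np.log(triplet)
    denom = lm - 2 * c + rm
    if denom >= 0:  # not a local maximum in log magnitude
        return spec.freqs[k], False
    p = 0.5 * (lm - rm) / denom
    p = float(np.clip(p, -0.5, 0.5))
    return spec.freqs[k] + p * spec.bin_spacing_hz, True


def select_rr_peak(
    spec: Spectrum,
    f_lo: float = 0.3,
    f_hi: float = 3.0,
    refine: bool = True,
    require_peak_snr: bool = False,
    snr_factor: float = 5.0,
) -> RRMeasurement:
    """Largest in-band magnitude peak → RR; out-of-band peaks are interference.

    Ties break toward the lower frequency.  With ``require_peak_snr`` the
    peak must additionally exceed ``snr_factor`` times the in-band median
    magnitude, rejecting flat/noise-only spectra.
    """
    if not (0 < f_lo < f_hi < spec.fps / 2 + 1e-12):
        raise NoValidPeakError(f"band [{f_lo}, {f_hi}] invalid for fps {spec.fps}")
    in_band = (spec.freqs >= f_lo) & (spec.freqs <= f_hi)
    if not in_band.any():
        raise NoValidPeakError("no spectral bins inside the respiratory band")
    band_mag = spec.magnitude[in_band]
    band_idx = np.nonzero(in_band)[0]
    if band_mag.max() <= 0:
        raise NoValidPeakError("spectrum is zero inside the respiratory band")
    if require_peak_snr:
        floor = np.median(band_mag)
        if band_mag.max() < snr_factor * floor:
            raise NoValidPeakError(
                f"in-band peak {band_mag.max():.3g} below {snr_factor}× median floor {floor:.3g}"
            )
    k = int(band_idx[np.argmax(band_mag)])  # argmax returns first ⇒ lowest frequency on ties
    refined = False
    rr_hz = float(spec.freqs[k])
    if refine:
        rr_hz, refined = _parabolic_refine(spec, k)
        rr_hz = float(np.clip(rr_hz, f_lo, f_hi))
    return RRMeasurement(rr_hz=rr_hz, peak_magnitude=float(spec.magnitude[k]), refined=refined)


def extract_signal(
    quiet_clip: VideoClip,
    spec: RoiSpec,
    cfg: PipelineConfig,
) -> RespiratorySignal:
    """PBVM motion signal from the ROI boxes of an already-quiet sub-clip."""
    boxes = spec.boxes_with_label("thoracodorsal", "tail") or spec.boxes
    bp = BandpassConfig(f_lo=cfg.pbvm.f_lo, f_hi=cfg.pbvm.f_hi)
    band_sets = []
    for box in boxes:
        sub = crop(quiet_clip, box)
        stack = PyramidStack.from_clip(sub.frames, quiet_clip.fps,
                                       levels=cfg.pbvm.levels, orientations=cfg.pbvm.orientations)
        band_sets.append(amplify_phase(stack, bp, alpha=cfg.pbvm.alpha))
    provenance = {"clip_id": quiet_clip.clip_id, "roi_labels": [b.label for b in boxes]}
    if cfg.pbvm.roi_mode == "fused" and len(band_sets) > 1:
        fused = PhaseSignalSet(bands=[b for s in band_sets for b in s.bands],
                               fps=quiet_clip.fps, alpha=cfg.pbvm.alpha, cfg=bp)
        return aggregate_signal(fused, provenance=provenance)
    if len(band_sets) == 1:
        return aggregate_signal(band_sets[0], provenance=provenance)
    # separate mode: aggregate each ROI, then average the per-ROI signals
    signals = [aggregate_signal(s, provenance=provenance) for s in band_sets]
    values = np.mean([s.values for s in signals], axis=0)
    return RespiratorySignal(values=values - values.mean(), fps=quiet_clip.fps, provenance=provenance)


def measure_rr(clip: VideoClip, spec: RoiSpec, cfg: PipelineConfig | None = None) -> RRMeasurement:
    """Full pipeline on one clip: screen → magnify → spectrum → peak.

    Raises the distinct stage errors (no quiet segment, empty signal, no
    valid peak) so batch callers can tally rejection reasons.
    """
    cfg = (cfg or PipelineConfig()).validate(fps=clip.fps)
    quiet_clip, window = select_quiet_segment(
        clip, spec,
        threshold_px=cfg.screening.threshold_px,
        window_s=cfg.screening.window_s,
        stride_s=cfg.screening.stride_s,
        flow_stride_frames=cfg.screening.flow_stride_frames,
        flow_downsample=cfg.screening.flow_downsample,
    )
    signal = extract_signal(quiet_clip, spec, cfg)
    spectrum = compute_spectrum(signal)
    m = select_rr_peak(
        spectrum,
        f_lo=cfg.pbvm.f_lo,
        f_hi=cfg.pbvm.f_hi,
        refine=cfg.spectral.refine,
        require_peak_snr=cfg.spectral.require_peak_snr,
        snr_factor=cfg.spectral.snr_factor,
    )
    provenance = dict(signal.provenance)
    provenance.update(config_digest=cfg.digest(), window=(window.start_frame, window.end_frame))
    return RRMeasurement(rr_hz=m.rr_hz, peak_magnitude=m.peak_magnitude,
                         refined=m.refined, window=window, provenance=provenance)
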