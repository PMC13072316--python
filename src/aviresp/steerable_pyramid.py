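"""Complex steerable pyramid: multi-scale, multi-orientation decomposition.

Frames are decomposed in the frequency domain with polar-separable filters:
octave-spaced radial raised-cosine bands crossed with ``cos^(K-1)`` angular
windows (K = 8 orientations spanning 180°).  The oriented filters are
analytic — supported on a single frequency half-plane and scaled by √2 —
so coefficients are complex and their argument is the local spatial phase.
A pattern translating by a sub-pixel displacement d advances the phase of
the aligned band by ω·d radians, where ω is the band's spatial frequency;
this shift-to-phase law is what the magnification stage exploits.

The filter bank is a tight frame by construction (the squared moduli of
all filters sum to one at every frequency), so ``reconstruct(build(f))``
recovers ``f`` to floating-point precision.  All bands are kept at full
resolution: with at most 4 levels on ROI-sized crops the cost is small and
full resolution keeps per-pixel phase time series trivially aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Sequence

import numpy as np

from .errors import DecompositionError

#: pixels with time-mean amplitude below this fraction of the frame maximum
#: carry numerically meaningless phase and are excluded from aggregation
AMPLITUDE_FLOOR_FRACTION = 1e-6


def adaptive_levels(height: int, width: int) -> int:
    """Pyramid depth for a frame size: ``clamp(floor(log2(min(H,W))) - 4, 1, 4)``.

    Keeps the coarsest radial band supported on structures of roughly 16 px
    and larger; 480×640 frames get 4 levels, ROI crops near 32 px get 1.
    """
    m = min(height, width)
    if m < 8:
        raise DecompositionError(f"frame side {m} px < 8 px: too small to decompose")
    return int(np.clip(int(np.floor(np.log2(m))) - 4, 1, 4))


def _radial_lo(r: np.ndarray, rc: float) -> np.ndarray:
    """Raised-cosine low-pass in log2 radius: 1 below rc/2, 0 above rc."""
    out = np.zeros_like(r)
    with np.errstate(divide="ignore"):
        lg = np.log2(np.maximum(r, 1e-300) / rc)
    out[r <= rc / 2] = 1.0
    band = (r > rc / 2) & (r < rc)
    out[band] = np.cos(np.pi / 2 * (lg[band] + 1.0))
    return out


def _angle_wrap(a: np.ndarray) -> np.ndarray:
    return np.mod(a + np.pi, 2 * np.pi) - np.pi


@dataclass(frozen=True)
class SteerableFilterBank:
    """Precomputed frequency-domain masks for one frame size.

    ``highpass`` and ``lowpass`` are real masks; ``bands[j][k]`` is the
    analytic oriented mask for scale j (0 = finest) and orientation k.
    """

    shape: tuple[int, int]
    levels: int
    orientations: int
    highpass: np.ndarray
    lowpass: np.ndarray
    bands: tuple[tuple[np.ndarray, ...], ...]
    center_frequencies: tuple[float, ...]  # radians/pixel per scale

    @property
    def orientation_angles(self) -> np.ndarray:
        return np.arange(self.orientations) * np.pi / self.orientations


def build_filter_bank(shape: tuple[int, int], levels: int, orientations: int = 8) -> SteerableFilterBank:
    h, w = shape
    if min(h, w) < 2 ** (levels + 2):
        raise DecompositionError(
            f"{levels} levels too deep for {h}×{w} frames (need min side ≥ {2 ** (levels + 2)} px)"
        )
    fy = np.fft.fftfreq(h)[:, None] * 2 * np.pi
    fx = np.fft.fftfreq(w)[None, :] * 2 * np.pi
    r = np.hypot(fy, fx)
    theta = np.arctan2(fy, fx)

    K = orientations
    # normalisation making the 2K half-windows tile the circle:
    #   sum_k alpha^2 cos^{2(K-1)}(theta - k pi/K) = 1
    alpha2 = 2.0 ** (2 * (K - 1)) / (K * comb(2 * (K - 1), K - 1))

    lo_prev = _radial_lo(r, np.pi)
    highpass = np.sqrt(np.clip(1.0 - lo_prev**2, 0.0, None))
    bands: list[tuple[np.ndarray, ...]] = []
    centers: list[float] = []
    for j in range(levels):
        rc = np.pi / 2 ** (j + 1)
        lo_next = _radial_lo(r, rc)
        radial = np.sqrt(np.clip(lo_prev**2 - lo_next**2, 0.0, None))
        lo_prev = lo_next
        centers.append(np.pi / 2 ** (j + 0.5))  # geometric centre of the octave
        level_bands = []
        for k in range(K):
            d = _angle_wrap(theta - k * np.pi / K)
            ang = np.where(np.abs(d) < np.pi / 2, np.cos(d) ** (K - 1), 0.0)
            # analytic: single half-plane, sqrt(2) preserves the tight frame
            level_bands.append((np.sqrt(2.0 * alpha2) * ang * radial).astype(np.float64))
        bands.append(tuple(level_bands))
    lowpass = lo_prev
    return SteerableFilterBank(
        shape=shape, levels=levels, orientations=K, highpass=highpass,
        lowpass=lowpass, bands=tuple(bands), center_frequencies=tuple(centers),
    )


@dataclass
class FramePyramid:
    """Decomposition of one frame: oriented complex sub-bands + residuals."""

    bank: SteerableFilterBank
    subbands: list[list[np.ndarray]]  # [scale][orientation], complex
    highpass: np.ndarray  # real residual
    lowpass: np.ndarray  # real residual (carries DC)

    def band(self, scale: int, orientation: int) -> np.ndarray:
        return self.subbands[scale][orientation]


def build_pyramid(frame: np.ndarray, levels: int | None = None, orientations: int = 8) -> FramePyramid:
    """Decompose one frame; ``levels=None`` uses the adaptive size rule."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise DecompositionError(f"expected a 2-D frame, got shape {frame.shape}")
    if levels is None:
        levels = adaptive_levels(*frame.shape)
    bank = build_filter_bank(frame.shape, levels, orientations)
    return _decompose(frame, bank)


def _decompose(frame: np.ndarray, bank: SteerableFilterBank) -> FramePyramid:
    spectrum = np.fft.fft2(frame)
    subbands = [
        [np.fft.ifft2(spectrum * mask) for mask in level] for level in bank.bands
    ]
    highpass = np.fft.ifft2(spectrum * bank.highpass).real
    lowpass = np.fft.ifft2(spectrum * bank.lowpass).real
    return FramePyramid(bank=bank, subbands=subbands, highpass=highpass, lowpass=lowpass)


def reconstruct(pyramid: FramePyramid) -> np.ndarray:
    """Invert the decomposition; exact (tight frame) up to float round-off."""
    bank = pyramid.bank
    if pyramid.highpass.shape != bank.shape or pyramid.lowpass.shape != bank.shape:
        raise DecompositionError("residual shapes do not match the filter bank")
    acc = np.fft.fft2(pyramid.highpass) * bank.highpass
    acc = acc + np.fft.fft2(pyramid.lowpass) * bank.lowpass
    for level, masks in zip(pyramid.subbands, bank.bands):
        if len(level) != len(masks):
            raise DecompositionError("orientation count does not match the filter bank")
        for coeffs, mask in zip(level, masks):
            if coeffs.shape != bank.shape:
                raise DecompositionError("sub-band shape does not match the filter bank")
            acc = acc + np.fft.fft2(coeffs) * mask
    return np.fft.ifft2(acc).real


@dataclass
class PyramidStack:
    """Per-frame pyramid decomposition of a whole clip, evaluated lazily.

    Materialising every sub-band of every frame would hold
    T·levels·orientations complex grids at once; instead the stack caches
    each frame's 2-D FFT and synthesises one sub-band time series
    (T×H×W complex) at a time on request.
    """

    frames: np.ndarray
    fps: float
    bank: SteerableFilterBank
    _spectra: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.float64)
        if frames.ndim != 3:
            raise DecompositionError(f"expected T×H×W frames, got {frames.shape}")
        if frames.shape[1:] != self.bank.shape:
            raise DecompositionError("frame size does not match the filter bank")
        self.frames = frames
        self._spectra = np.fft.fft2(frames, axes=(1, 2)).astype(np.complex128)

    @classmethod
    def from_clip(cls, frames: np.ndarray, fps: float, levels: int | None = None,
                  orientations: int = 8) -> "PyramidStack":
        frames = np.asarray(frames)
        if levels is None:
            levels = adaptive_levels(frames.shape[1], frames.shape[2])
        bank = build_filter_bank(frames.shape[1:], levels, orientations)
        return cls(frames=frames, fps=fps, bank=bank)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def levels(self) -> int:
        return self.bank.levels

    @property
    def orientations(self) -> int:
        return self.bank.orientations

    def _idft_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        # inverse-DFT as two small matrix products: for ROI-sized crops
        # (often awkward prime dimensions) BLAS beats per-slice Bluestein FFTs
        if not hasattr(self, "_idft_cache"):
            h, w = self.bank.shape
            mh = np.exp(2j * np.pi * np.outer(np.arange(h), np.arange(h)) / h) / h
            mw = np.exp(2j * np.pi * np.outer(np.arange(w), np.arange(w)) / w) / w
            self._idft_cache = (mh.astype(np.complex128), mw.astype(np.complex128))
        return self._idft_cache

    def subband_series(self, scale: int, orientation: int) -> np.ndarray:
        """Complex coefficients of one (scale, orientation) band, T×H×W."""
        mask = self.bank.bands[scale][orientation]
        masked = self._spectra * mask
        h, w = self.bank.shape
        if max(h, w) <= 128:
            mh, mw = self._idft_matrices()
            return np.matmul(np.matmul(mh, masked), mw.T)
        return np.fft.ifft2(masked, axes=(1, 2))

    def amplitude_floor(self) -> float:
        return AMPLITUDE_FLOOR_FRACTION * float(np.abs(self.frames).max())


def temporal_unwrap(phase: np.ndarray, axis: int = 0) -> np.ndarray:
    """Unwrap phase along time only (per pixel); no spatial unwrapping."""
    return np.unwrap(phase, axis=axis)


def phase_series(stack: PyramidStack, scale: int, orientation: int,
                 pixel: tuple[int, int]) -> tuple[np.ndarray, bool]:
    """Temporally unwrapped phase at one pixel of one sub-band.

    Returns ``(series, reliable)``; ``reliable`` is False when the
    time-mean coefficient amplitude at the pixel is below the floor, in
    which case the phase is numerically meaningless noise.
    """
    y, x = pixel
    coeffs = stack.subband_series(scale, orientation)[:, y, x]
    reliable = bool(np.abs(coeffs).mean() >= stack.amplitude_floor())
    return temporal_unwrap(np.angle(coeffs)), reliable
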