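"""Quiet-state screening: dense optical-flow motion amplitude over 10-s windows.

A bird qualifies for RR extraction only when its body is effectively still
for a full 10-s window.  Motion is quantified with a dense, sub-pixel
optical-flow estimator between (strided) frame pairs inside the body box;
each pair is summarised as a single displacement vector (the median flow
over gradient-bearing pixels), the vectors are integrated into a
trajectory, and a window's amplitude is the largest excursion of that
trajectory from the window's first frame.  Zero-mean respiratory motion
(≤ 0.5 px) therefore never trips the threshold, while slow drift
accumulates: the quiet criterion is amplitude ≤ 1.5 px over 10 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.registration import optical_flow_ilk

from .core_io import BoundingBox, RoiSpec, VideoClip, crop
from .errors import NoQuietSegmentError, ScreeningError

#: quiet-state trajectory amplitude threshold, pixels over one window
DEFAULT_THRESHOLD_PX = 1.5
#: screening window length, seconds
DEFAULT_WINDOW_S = 10.0
#: window stride, seconds
DEFAULT_STRIDE_S = 1.0
#: frames between flow pairs; 3 at 30 fps samples motion at 10 Hz, ample
#: for drift and for respiratory motion below 3 Hz
DEFAULT_FLOW_STRIDE_FRAMES = 3
#: spatial down-sampling factor for flow (displacements rescaled back)
DEFAULT_FLOW_DOWNSAMPLE = 2


@dataclass(frozen=True)
class QuietWindow:
    """One screening window [start_frame, end_frame); quiet iff amplitude ≤ threshold."""

    start_frame: int
    end_frame: int
    amplitude: float
    is_quiet: bool


@dataclass(frozen=True)
class MotionTrace:
    """Frame-to-frame displacement of the tracked body inside one box.

    ``dx``/``dy`` are signed per-step displacements in pixels at the
    native frame rate (one entry per consecutive frame pair, T−1 entries);
    strided flow estimates are spread uniformly over the frames they span,
    so the cumulative sum is the trajectory in native frame units.
    """

    clip_id: str
    box: BoundingBox
    dx: np.ndarray
    dy: np.ndarray

    def __post_init__(self) -> None:
        if self.dx.shape != self.dy.shape or self.dx.ndim != 1:
            raise ScreeningError("dx/dy must be equal-length 1-D arrays")
        if not (np.all(np.isfinite(self.dx)) and np.all(np.isfinite(self.dy))):
            raise ScreeningError("non-finite displacements")

    @property
    def per_frame_displacement(self) -> np.ndarray:
        """Unsigned per-step displacement magnitudes, length T−1."""
        return np.hypot(self.dx, self.dy)

    @property
    def n_steps(self) -> int:
        return self.dx.shape[0]

    def trajectory(self) -> np.ndarray:
        """Cumulative position (T×2, [x, y]) relative to the first frame."""
        x = np.concatenate([[0.0], np.cumsum(self.dx)])
        y = np.concatenate([[0.0], np.cumsum(self.dy)])
        return np.stack([x, y], axis=1)


def _summarise_flow(flow_v: np.ndarray, flow_u: np.ndarray, reference: np.ndarray) -> tuple[float, float]:
    """Collapse a dense flow field to one displacement vector.

    Median over pixels with appreciable spatial gradient: flat interior
    pixels carry no displacement information (aperture problem) and would
    bias the median toward zero.
    """
    gy, gx = np.gradient(reference)
    gmag = np.hypot(gy, gx)
    mask = gmag > 0.25 * gmag.max()
    if mask.sum() < 9:
        mask = np.ones_like(mask)
    return float(np.median(flow_u[mask])), float(np.median(flow_v[mask]))


def estimate_flow(
    clip: VideoClip,
    box: BoundingBox,
    flow_stride_frames: int = DEFAULT_FLOW_STRIDE_FRAMES,
    downsample: int = DEFAULT_FLOW_DOWNSAMPLE,
) -> MotionTrace:
    """Per-frame body displacement inside ``box`` from dense optical flow.

    Flow is computed with the iterative Lucas–Kanade estimator between
    frames ``flow_stride_frames`` apart, optionally on spatially
    down-sampled crops (displacements are rescaled), and spread uniformly
    over the spanned frames so the returned series has one entry per
    consecutive frame pair.
    """
    sub = crop(clip, box)
    if sub.shape[0] < 8 or sub.shape[1] < 8:
        raise ScreeningError(f"box {box} too small for flow estimation (need ≥ 8×8 px)")
    frames = sub.frames.astype(np.float32)
    if downsample > 1:
        frames = frames[:, ::downsample, ::downsample]
    T = frames.shape[0]
    stride = max(1, int(flow_stride_frames))
    dx = np.zeros(T - 1)
    dy = np.zeros(T - 1)
    for start in range(0, T - 1, stride):
        stop = min(start + stride, T - 1)
        a, b = frames[start], frames[stop]
        if np.array_equal(a, b):
            continue
        v, u = optical_flow_ilk(a, b, radius=5, num_warp=3)
        ux, uy = _summarise_flow(v, u, a)
        n = stop - start
        dx[start:stop] = ux * downsample / n
        dy[start:stop] = uy * downsample / n
    return MotionTrace(clip_id=clip.clip_id, box=box, dx=dx, dy=dy)


def window_amplitude(trace: MotionTrace, start: int, end: int) -> float:
    """Largest trajectory excursion (pixels) from the window's first frame."""
    cx = np.cumsum(trace.dx[start : end - 1])
    cy = np.cumsum(trace.dy[start : end - 1])
    if cx.size == 0:
        return 0.0
    return float(np.hypot(cx, cy).max())


def classify_windows(
    trace: MotionTrace,
    fps: float,
    threshold_px: float = DEFAULT_THRESHOLD_PX,
    window_s: float = DEFAULT_WINDOW_S,
    stride_s: float = DEFAULT_STRIDE_S,
) -> list[QuietWindow]:
    """Slide a ``window_s`` window over the trace and label each quiet/active."""
    n_frames = trace.n_steps + 1
    wf = int(round(window_s * fps))
    sf = max(1, int(round(stride_s * fps)))
    if wf > n_frames:
        raise ScreeningError(f"window of {wf} frames longer than clip of {n_frames} frames")
    windows = []
    for start in range(0, n_frames - wf + 1, sf):
        amp = window_amplitude(trace, start, start + wf)
        windows.append(QuietWindow(start_frame=start, end_frame=start + wf,
                                   amplitude=amp, is_quiet=amp <= threshold_px))
    return windows


def select_quiet_segment(
    clip: VideoClip,
    spec: RoiSpec,
    threshold_px: float = DEFAULT_THRESHOLD_PX,
    window_s: float = DEFAULT_WINDOW_S,
    stride_s: float = DEFAULT_STRIDE_S,
    flow_stride_frames: int = DEFAULT_FLOW_STRIDE_FRAMES,
    flow_downsample: int = DEFAULT_FLOW_DOWNSAMPLE,
) -> tuple[VideoClip, QuietWindow]:
    """Earliest quiet window's sub-clip, or a rejection if none exists.

    Screening runs on the body box when the spec has one, else on the
    union of all ROI boxes.
    """
    bodies = spec.boxes_with_label("body")
    if bodies:
        box = bodies[0]
    else:
        box = BoundingBox(
            min(b.x0 for b in spec.boxes), min(b.y0 for b in spec.boxes),
            max(b.x1 for b in spec.boxes), max(b.y1 for b in spec.boxes), "body",
        )
    trace = estimate_flow(clip, box, flow_stride_frames=flow_stride_frames, downsample=flow_downsample)
    windows = classify_windows(trace, clip.fps, threshold_px=threshold_px,
                               window_s=window_s, stride_s=stride_s)
    for w in windows:
        if w.is_quiet:
            return clip.slice_frames(w.start_frame, w.end_frame), w
    raise NoQuietSegmentError(
        f"{clip.clip_id}: no quiet {window_s:g}-s window below {threshold_px:g} px "
        f"(min amplitude {min(w.amplitude for w in windows):.2f} px)"
    )
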