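"""Synthetic breathing-blob thermal clips with known ground truth.

The generator emulates what the pipeline actually consumes from real
footage: a warm, smooth-edged elliptical body on a cooler background whose
boundary undulates sub-pixel-sinusoidally at a known respiratory frequency
on two arcs — the thoracodorsal (back) arc and the tail arc, in phase, as
thoracic and air-sac mechanics move both regions with a common rhythm.
Edges are evaluated analytically (a sigmoid of the signed radial distance)
so sub-pixel displacement is rendered exactly, without interpolation
artifacts; sensor noise, slow whole-body drift and transient motion bursts
are optional.  Intensities are abstract thermal units on a fixed-point
1/64 grid for platform-independent reproducibility — the pipeline consumes
relative motion, not radiometric temperature.

Cohort presets echo the physiological regimes of meat broilers: mean RR of
roughly 1.1 Hz in the brooding stage, 0.9 Hz growing, 0.6 Hz fattening,
rising under heat stress to about 2.7 Hz for brooding birds at +5 °C and
about +50% for fattening birds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core_io import BoundingBox, RoiSpec, VideoClip
from .errors import ConfigError

#: per-stage mean true RR (Hz) at each heat increment (°C above optimum)
RR_PRESETS: dict[str, dict[int, float]] = {
    "brooding": {0: 1.1, 2: 1.6, 4: 2.1, 5: 2.7},
    "growing": {0: 0.9, 2: 1.2, 4: 1.5, 5: 1.8},
    "fattening": {0: 0.6, 2: 0.7, 4: 0.8, 5: 0.9},
}
#: between-bird SD of true RR within a preset, Hz
RR_PRESET_SD = 0.12
#: age ranges (days) per growth stage, used for trend analyses
STAGE_AGE_RANGES: dict[str, tuple[int, int]] = {
    "brooding": (4, 14),
    "growing": (15, 24),
    "fattening": (25, 36),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic clip; defaults mirror the acquisition
    conditions the pipeline targets (30 fps thermal video, 1-min clips)."""

    fps: float = 30.0
    duration_s: float = 60.0
    frame_hw: tuple[int, int] = (120, 160)
    center: tuple[float, float] = (60.0, 80.0)  # (y, x) pixels
    axes: tuple[float, float] = (50.0, 30.0)  # (semi-x, semi-y) pixels
    true_rr_hz: float = 1.1
    breath_amp_px: float = 0.2
    noise_sd: float = 0.5
    drift_px_per_s: float = 0.0
    burst: tuple[float, float, float] | None = None  # (start_s, length_s, amp_px)
    antiphase_tail: bool = False
    background: float = 20.0
    body_contrast: float = 60.0
    edge_softness_px: float = 0.75  # sigmoid scale; ≈3-px soft boundary
    seed: int = 0
    clip_id: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.fps > 2 * self.true_rr_hz:
            raise ConfigError(f"fps {self.fps} must exceed twice the RR {self.true_rr_hz}")
        if not 0 <= self.breath_amp_px < 1:
            raise ConfigError("breath_amp_px must be sub-pixel (in [0, 1))")
        h, w = self.frame_hw
        cy, cx = self.center
        ax, ay = self.axes
        margin = 10.0
        if cx - ax < margin / 2 or cx + ax > w - margin / 2 or cy - ay < margin / 2 or cy + ay > h - margin / 2:
            raise ConfigError(f"blob (center {self.center}, axes {self.axes}) exceeds {h}×{w} frame")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator knows: the truth the pipeline must recover."""

    clip_id: str
    true_rr_hz: float
    quiet_per_window: tuple[bool, ...]
    roi: RoiSpec
    stage: str | None = None
    heat_delta: int | None = None
    age_days: int | None = None


def _arc_weight(theta: np.ndarray, center: float, half_width: float) -> np.ndarray:
    """Smooth cos² bump on the arc |θ − center| < half_width."""
    d = np.mod(theta - center + np.pi, 2 * np.pi) - np.pi
    w = np.cos(np.pi / 2 * d / half_width) ** 2
    return np.where(np.abs(d) < half_width, w, 0.0)


def _roi_boxes(cfg: SyntheticConfig) -> list[BoundingBox]:
    cy, cx = cfg.center
    ax, ay = cfg.axes
    thoraco = BoundingBox(
        int(cx - 0.35 * ax), int(cy - ay - 7), int(cx + 0.35 * ax), int(cy - 0.25 * ay), "thoracodorsal"
    )
    tail = BoundingBox(
        int(cx - ax - 7), int(cy - 0.55 * ay), int(cx - 0.45 * ax), int(cy + 0.55 * ay), "tail"
    )
    body = BoundingBox(
        max(0, int(cx - ax - 8)), max(0, int(cy - ay - 8)),
        min(cfg.frame_hw[1], int(cx + ax + 8)), min(cfg.frame_hw[0], int(cy + ay + 8)), "body",
    )
    return [body, thoraco, tail]


def _quiet_flags(cfg: SyntheticConfig, n_frames: int, window_s: float = 10.0,
                 threshold_px: float = 1.5) -> tuple[bool, ...]:
    """Analytic quiet/active label per 1-s-strided window, from the config."""
    flags = []
    wf = int(round(window_s * cfg.fps))
    sf = int(round(cfg.fps))
    for start in range(0, n_frames - wf + 1, sf):
        t0, t1 = start / cfg.fps, (start + wf) / cfg.fps
        amp = abs(cfg.drift_px_per_s) * (t1 - t0)
        if cfg.burst is not None:
            b0, blen, bamp = cfg.burst
            if t0 < b0 + blen and b0 < t1:
                amp += abs(bamp)
        flags.append(amp <= threshold_px)
    return tuple(flags)


def generate_clip(cfg: SyntheticConfig) -> tuple[VideoClip, GroundTruth, RoiSpec]:
    """Render a breathing-blob clip; bit-identical for identical configs."""
    h, w = cfg.frame_hw
    n_frames = int(round(cfg.duration_s * cfg.fps))
    if n_frames < 2:
        raise ConfigError("duration too short for the frame rate")
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(n_frames) / cfg.fps
    delta = cfg.breath_amp_px * np.sin(2 * np.pi * cfg.true_rr_hz * t)

    # whole-blob centre trajectory: drift plus optional smooth burst, along +x
    shift_x = cfg.drift_px_per_s * t
    if cfg.burst is not None:
        b0, blen, bamp = cfg.burst
        phase = np.clip((t - b0) / max(blen, 1e-9), 0.0, 1.0)
        shift_x = shift_x + bamp * 0.5 * (1 - np.cos(np.pi * phase))

    cy, cx = cfg.center
    ax, ay = cfg.axes
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)

    def head(center_x: float) -> np.ndarray:
        # slightly warmer head end; orients the fallback detector
        return 0.25 * cfg.body_contrast * np.exp(
            -(((xx - (center_x + 0.65 * ax)) / (0.25 * ax)) ** 2 + ((yy - cy) / (0.5 * ay)) ** 2)
        )

    head_spot = head(cx)

    frames = np.empty((n_frames, h, w), dtype=np.float32)
    tail_sign = -1.0 if cfg.antiphase_tail else 1.0
    s = cfg.edge_softness_px

    def geometry(center_x: float) -> tuple[np.ndarray, np.ndarray]:
        dx_ = xx - center_x
        dy_ = yy - cy
        r = np.hypot(dx_, dy_)
        theta = np.arctan2(dy_, dx_)
        base_r = ax * ay / np.sqrt((ay * np.cos(theta)) ** 2 + (ax * np.sin(theta)) ** 2)
        bump = _arc_weight(theta, -np.pi / 2, np.deg2rad(40)) + tail_sign * _arc_weight(
            theta, np.pi, np.deg2rad(30)
        )
        return base_r - r, bump  # signed distance to the static edge, arc weight

    static_geometry = not np.any(shift_x != 0.0)
    if static_geometry:
        # breathing only deforms the two arcs: render the static frame once
        # and re-evaluate the sigmoid on the narrow moving-edge region
        dist0, bump = geometry(cx)
        moving = (np.abs(bump) > 1e-9) & (np.abs(dist0) < 12 * s)
        body0 = cfg.body_contrast / (1.0 + np.exp(-dist0 / s))
        base_frame = cfg.background + body0 + head_spot * (body0 / cfg.body_contrast)
        d_m, b_m, head_m = dist0[moving], bump[moving], head_spot[moving]
        for i in range(n_frames):
            frame = base_frame.copy()
            body_m = cfg.body_contrast / (1.0 + np.exp(-(d_m + delta[i] * b_m) / s))
            frame[moving] = cfg.background + body_m + head_m * (body_m / cfg.body_contrast)
            if cfg.noise_sd > 0:
                frame = frame + rng.normal(0.0, cfg.noise_sd, size=frame.shape)
            frames[i] = frame
    else:
        for i in range(n_frames):
            dist, bump = geometry(cx + shift_x[i])
            body = cfg.body_contrast / (1.0 + np.exp(-(dist + delta[i] * bump) / s))
            frame = cfg.background + body + head(cx + shift_x[i]) * (body / cfg.body_contrast)
            if cfg.noise_sd > 0:
                frame = frame + rng.normal(0.0, cfg.noise_sd, size=frame.shape)
            frames[i] = frame
    frames = np.round(frames * 64.0) / 64.0  # fixed-point render, reproducible

    clip = VideoClip(frames=frames.astype(np.float32), fps=cfg.fps, clip_id=cfg.clip_id)
    roi = RoiSpec(clip_id=cfg.clip_id, boxes=tuple(_roi_boxes(cfg)), frame_range=(0, n_frames - 1))
    truth = GroundTruth(
        clip_id=cfg.clip_id, true_rr_hz=cfg.true_rr_hz,
        quiet_per_window=_quiet_flags(cfg, n_frames), roi=roi,
    )
    return clip, truth, roi


def generate_cohort(
    n: int,
    stage: str,
    heat_delta: int = 0,
    seed: int = 0,
    duration_s: float = 12.0,
    **clip_kwargs,
) -> list[tuple[VideoClip, GroundTruth]]:
    """Draw ``n`` birds from a stage/heat-increment preset and render clips.

    True RR per bird is normal around the preset mean with SD 0.12 Hz
    (the between-bird spread of manual counts), truncated to the
    physiological band [0.3, 3.0] Hz.  Clips default to 12 s — one full
    screening window plus margin — to keep cohort studies tractable.
    """
    if stage not in RR_PRESETS:
        raise ConfigError(f"unknown stage {stage!r}; choose from {sorted(RR_PRESETS)}")
    if heat_delta not in RR_PRESETS[stage]:
        raise ConfigError(f"unknown heat increment {heat_delta}; choose from {sorted(RR_PRESETS[stage])}")
    if n < 1:
        raise ConfigError("cohort size must be ≥ 1")
    mean_rr = RR_PRESETS[stage][heat_delta]
    age_lo, age_hi = STAGE_AGE_RANGES[stage]
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        rr = float(np.clip(rng.normal(mean_rr, RR_PRESET_SD), 0.3, 3.0))
        age = int(rng.integers(age_lo, age_hi + 1))
        clip_seed = int(rng.integers(0, 2**31 - 1))
        cfg = SyntheticConfig(
            true_rr_hz=rr, duration_s=duration_s, seed=clip_seed,
            clip_id=f"{stage}_d{heat_delta}_{i:03d}", **clip_kwargs,
        )
        clip, truth, _ = generate_clip(cfg)
        truth = replace(truth, stage=stage, heat_delta=heat_delta, age_days=age)
        out.append((clip, truth))
    return out
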