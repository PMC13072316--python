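"""Domain types and I/O: video clips, ROI annotations, pseudo-color handling.

Conventions used everywhere in the package: arrays are row-major ``(y, x)``,
pixel and frame indices are 0-based, and every interval — bounding boxes,
frame ranges of windows — is half-open ``[lo, hi)``.  The only exception is
:class:`RoiSpec.frame_range`, which is inclusive on both ends to match the
annotation file format.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
from skimage import measure

from .errors import AnnotationError, BoundsError, DetectionError, VideoFormatError

ROI_LABELS = ("thoracodorsal", "tail", "body")

_FRAME_SUFFIXES = (".png", ".tif", ".tiff")


@dataclass(frozen=True)
class VideoClip:
    """A uniformly sampled stack of scalar thermal-intensity frames.

    ``frames`` has shape ``(T, H, W)`` in arbitrary thermal-intensity units;
    ``fps`` is the sampling rate in Hz; ``t0`` the clip start time in seconds.
    """

    frames: np.ndarray
    fps: float
    clip_id: str = "clip"
    t0: float = 0.0

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise VideoFormatError(f"frames must be T×H×W, got shape {frames.shape}")
        if frames.shape[0] < 2:
            raise VideoFormatError("a clip needs at least 2 frames")
        if not np.all(np.isfinite(frames)):
            raise VideoFormatError("frame intensities must be finite")
        if not self.fps > 0:
            raise VideoFormatError(f"fps must be positive, got {self.fps}")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Frame (height, width)."""
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def time_axis(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) / self.fps

    def slice_frames(self, start: int, stop: int) -> "VideoClip":
        """Temporal sub-clip over the half-open frame range [start, stop)."""
        if not (0 <= start < stop <= self.n_frames):
            raise BoundsError(f"frame range [{start}, {stop}) outside clip of {self.n_frames} frames")
        return replace(self, frames=self.frames[start:stop], t0=self.t0 + start / self.fps)


@dataclass(frozen=True)
class BoundingBox:
    """Half-open pixel box [x0, x1) × [y0, y1), 0-based."""

    x0: int
    y0: int
    x1: int
    y1: int
    label: str = "body"

    def __post_init__(self) -> None:
        if not (0 <= self.x0 < self.x1 and 0 <= self.y0 < self.y1):
            raise AnnotationError(f"inverted or negative box {self}")
        if self.label not in ROI_LABELS:
            raise AnnotationError(f"unknown ROI label {self.label!r}; allowed: {ROI_LABELS}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    def shift(self, dx: int, dy: int) -> "BoundingBox":
        return BoundingBox(self.x0 + dx, self.y0 + dy, self.x1 + dx, self.y1 + dy, self.label)


@dataclass(frozen=True)
class RoiSpec:
    """ROI boxes valid over an inclusive frame range of one clip."""

    clip_id: str
    boxes: tuple[BoundingBox, ...]
    frame_range: tuple[int, int] = (0, -1)  # -1 = until end of clip

    def __post_init__(self) -> None:
        if not self.boxes:
            raise AnnotationError("RoiSpec needs at least one box")
        object.__setattr__(self, "boxes", tuple(self.boxes))

    def boxes_with_label(self, *labels: str) -> tuple[BoundingBox, ...]:
        return tuple(b for b in self.boxes if b.label in labels)


# ---------------------------------------------------------------------------
# pseudo-color handling


def rainbow_lut(n: int = 256) -> np.ndarray:
    """A rainbow palette (blue→cyan→green→yellow→red), shape (n, 3) uint8.

    Thermal cameras export pseudo-colored footage through a palette of this
    family; the inverse mapping below recovers the palette index as a
    monotone intensity proxy.  The exact palette of any given camera is
    unknown, so recovered values are a proxy, not temperatures.
    """
    x = np.linspace(0.0, 1.0, n)
    r = np.clip(1.5 - np.abs(4.0 * x - 3.0), 0, 1)
    g = np.clip(1.5 - np.abs(4.0 * x - 2.0), 0, 1)
    b = np.clip(1.5 - np.abs(4.0 * x - 1.0), 0, 1)
    return np.round(np.stack([r, g, b], axis=1) * 255).astype(np.uint8)


def collapse_pseudo_color(rgb_frames: np.ndarray, lut: np.ndarray | None = None) -> np.ndarray:
    """Map T×H×W×3 pseudo-colored frames to scalar palette indices.

    Nearest-neighbour lookup against the palette; returns float32 T×H×W.
    """
    if lut is None:
        lut = rainbow_lut()
    flat = rgb_frames.reshape(-1, 3).astype(np.int32)
    # squared distance to each palette entry, chunked to bound memory
    out = np.empty(flat.shape[0], dtype=np.float32)
    lut32 = lut.astype(np.int32)
    chunk = 1 << 18
    for i in range(0, flat.shape[0], chunk):
        d = flat[i : i + chunk, None, :] - lut32[None, :, :]
        out[i : i + chunk] = np.argmin(np.einsum("ijk,ijk->ij", d, d), axis=1)
    return out.reshape(rgb_frames.shape[:-1])


# ---------------------------------------------------------------------------
# clip I/O


def _read_frames(path: Path) -> tuple[np.ndarray, float | None]:
    """Read a frame stack; returns (frames, container fps or None)."""
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES)
        if not files:
            raise VideoFormatError(f"no frame files in directory {path}")
        import imageio.v3 as iio

        frames = [np.asarray(iio.imread(f)) for f in files]
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise VideoFormatError(f"non-uniform frame sizes in {path}: {sorted(shapes)}")
        return np.stack(frames), None
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        return frames, None
    # video container (AVI/MP4) through imageio
    import imageio.v3 as iio

    try:
        frames = iio.imread(path, plugin="pyav")
        meta = iio.immeta(path, plugin="pyav")
    except Exception:
        try:
            frames = iio.imread(path)
            meta = iio.immeta(path)
        except Exception as exc:  # pragma: no cover - backend-dependent
            raise VideoFormatError(f"cannot read video container {path}: {exc}") from exc
    return np.asarray(frames), meta.get("fps")


def load_clip(
    path: str | Path,
    color_mode: str = "gray",
    fps: float | None = None,
    clip_id: str | None = None,
) -> VideoClip:
    """Load a clip from a TIFF stack, a frame directory, or an AVI/MP4 file.

    ``fps`` precedence: caller override, then container metadata, else an
    error — thermal exports routinely carry wrong or missing rate metadata,
    so silence is not an option.  ``color_mode='pseudo_color'`` collapses
    3-channel rainbow-palette frames to a scalar intensity proxy.
    """
    path = Path(path)
    if not path.exists():
        raise VideoFormatError(f"no such file: {path}")
    frames, meta_fps = _read_frames(path)
    if frames.size == 0 or frames.shape[0] == 0:
        raise VideoFormatError(f"clip {path} contains no frames")
    if color_mode == "pseudo_color":
        if frames.ndim != 4 or frames.shape[-1] != 3:
            raise VideoFormatError("pseudo_color mode expects 3-channel frames")
        frames = collapse_pseudo_color(frames)
    elif color_mode == "gray":
        if frames.ndim == 4:
            frames = frames.mean(axis=-1)
    else:
        raise VideoFormatError(f"unknown color_mode {color_mode!r}")
    eff_fps = fps if fps is not None else meta_fps
    if eff_fps is None:
        raise VideoFormatError(f"{path}: no frame rate in container metadata; pass fps explicitly")
    return VideoClip(frames=frames.astype(np.float32), fps=float(eff_fps), clip_id=clip_id or path.stem)


def save_clip(clip: VideoClip, path: str | Path) -> Path:
    """Write a clip losslessly as a multi-page TIFF or a directory of TIFFs.

    Integer-valued frames round-trip bit-exactly; float frames are stored
    as float32 TIFF pages.
    """
    path = Path(path)
    frames = clip.frames
    if np.allclose(frames, np.round(frames)) and frames.min() >= 0 and frames.max() <= 65535:
        frames = np.round(frames).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, frames)
    else:
        path.mkdir(parents=True, exist_ok=True)
        width = len(str(clip.n_frames - 1))
        for i, frame in enumerate(frames):
            tifffile.imwrite(path / f"frame_{i:0{width}d}.tiff", frame)
    return path


def crop(clip: VideoClip, box: BoundingBox) -> VideoClip:
    """Spatial crop of every frame to ``box``; fps and timing unchanged."""
    h, w = clip.shape
    if box.x1 > w or box.y1 > h:
        raise BoundsError(f"box {box} outside {h}×{w} frames")
    return replace(clip, frames=clip.frames[:, box.y0 : box.y1, box.x0 : box.x1])


# ---------------------------------------------------------------------------
# ROI annotations

_ROI_COLUMNS = ["clip_id", "label", "x0", "y0", "x1", "y1", "frame_start", "frame_end"]


def load_rois(path: str | Path) -> list[RoiSpec]:
    """Read ROI annotations from CSV (header clip_id,label,x0,y0,x1,y1,
    frame_start,frame_end) or an equivalent JSON list of records."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = pd.DataFrame(json.loads(path.read_text()))
    else:
        rows = pd.read_csv(path)
    missing = set(_ROI_COLUMNS) - set(rows.columns)
    if missing:
        raise AnnotationError(f"{path}: missing columns {sorted(missing)}")
    specs: list[RoiSpec] = []
    for (clip_id, fstart, fend), grp in rows.groupby(["clip_id", "frame_start", "frame_end"], sort=False):
        boxes = []
        for idx, row in grp.iterrows():
            try:
                boxes.append(
                    BoundingBox(int(row.x0), int(row.y0), int(row.x1), int(row.y1), str(row.label))
                )
            except (AnnotationError, ValueError) as exc:
                raise AnnotationError(f"{path} row {idx}: {exc}") from exc
        specs.append(RoiSpec(clip_id=str(clip_id), boxes=tuple(boxes), frame_range=(int(fstart), int(fend))))
    return specs


def save_rois(specs: Iterable[RoiSpec], path: str | Path) -> Path:
    path = Path(path)
    records = []
    for spec in specs:
        for b in spec.boxes:
            records.append(
                dict(clip_id=spec.clip_id, label=b.label, x0=b.x0, y0=b.y0, x1=b.x1, y1=b.y1,
                     frame_start=spec.frame_range[0], frame_end=spec.frame_range[1])
            )
    df = pd.DataFrame.from_records(records, columns=_ROI_COLUMNS)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=1))
    else:
        df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# fallback body detector


def fallback_detect(
    frame: np.ndarray,
    intensity_quantile: float = 0.7,
    min_area_px: int = 16,
) -> list[BoundingBox]:
    """Locate the bird body and derive thoracodorsal/tail ROIs by geometry.

    Thresholds the frame at the given intensity quantile (a warm body on a
    cooler background), keeps the largest connected component as the body,
    and splits its bounding box along the major axis into thirds: the
    middle third is the thoracodorsal ROI and the third farther from the
    brighter (head) end is the tail ROI.  A deterministic geometric
    stand-in for a learned detector — adequate for single-bird frames, not
    a tracker.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise DetectionError(f"expected a single 2-D frame, got shape {frame.shape}")
    if np.ptp(frame) == 0:
        raise DetectionError("constant frame: nothing to detect")
    thr = np.quantile(frame, intensity_quantile)
    mask = frame > thr
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        raise DetectionError("no pixels above the intensity threshold")
    areas = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(areas)) + 1
    if areas[best - 1] < min_area_px:
        raise DetectionError(f"largest warm component has area {areas[best - 1]} px < {min_area_px}")
    ys, xs = np.nonzero(labels == best)
    y0, y1 = int(ys.min()), int(ys.max()) + 1
    x0, x1 = int(xs.min()), int(xs.max()) + 1
    body = BoundingBox(x0, y0, x1, y1, "body")

    horizontal = body.width >= body.height
    if horizontal:
        edges = np.round(np.linspace(x0, x1, 4)).astype(int)
        thirds = [BoundingBox(edges[i], y0, edges[i + 1], y1, "body") for i in range(3)]
        end_mean = [frame[y0:y1, t.x0 : t.x1].mean() for t in (thirds[0], thirds[2])]
    else:
        edges = np.round(np.linspace(y0, y1, 4)).astype(int)
        thirds = [BoundingBox(x0, edges[i], x1, edges[i + 1], "body") for i in range(3)]
        end_mean = [frame[t.y0 : t.y1, x0:x1].mean() for t in (thirds[0], thirds[2])]
    # head = brighter end third; tail = opposite end
    tail_third = thirds[2] if end_mean[0] >= end_mean[1] else thirds[0]
    thorax = thirds[1]
    return [
        body,
        BoundingBox(thorax.x0, thorax.y0, thorax.x1, thorax.y1, "thoracodorsal"),
        BoundingBox(tail_third.x0, tail_third.y0, tail_third.x1, tail_third.y1, "tail"),
    ]
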