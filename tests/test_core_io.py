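import numpy as np
import pandas as pd
import pytest

from aviresp.core_io import (
    BoundingBox,
    RoiSpec,
    VideoClip,
    collapse_pseudo_color,
    crop,
    fallback_detect,
    load_clip,
    load_rois,
    rainbow_lut,
    save_clip,
    save_rois,
)
from aviresp.errors import AnnotationError, BoundsError, DetectionError, VideoFormatError


def _clip(frames, fps=30.0, clip_id="c"):
    return VideoClip(frames=np.asarray(frames, dtype=np.float32), fps=fps, clip_id=clip_id)


@pytest.fixture
def integer_clip():
    rng = np.random.default_rng(0)
    return _clip(rng.integers(0, 4096, size=(20, 24, 32)).astype(np.float32))


class TestVideoClip:
    def test_invariants_rejected(self):
        with pytest.raises(VideoFormatError):
            _clip(np.zeros((1, 4, 4)))  # T < 2
        with pytest.raises(VideoFormatError):
            _clip(np.zeros((3, 4, 4)), fps=0.0)
        bad = np.zeros((3, 4, 4))
        bad[1, 2, 2] = np.nan
        with pytest.raises(VideoFormatError):
            _clip(bad)

    def test_temporal_slice_updates_t0(self, integer_clip):
        sub = integer_clip.slice_frames(5, 15)
        assert sub.n_frames == 10
        assert sub.t0 == pytest.approx(5 / 30.0)
        np.testing.assert_array_equal(sub.frames, integer_clip.frames[5:15])


class TestClipRoundTrip:
    def test_tiff_stack_identity(self, integer_clip, tmp_path):
        path = save_clip(integer_clip, tmp_path / "clip.tiff")
        loaded = load_clip(path, fps=30.0)
        np.testing.assert_array_equal(loaded.frames, integer_clip.frames)
        assert loaded.fps == 30.0

    def test_frame_directory_identity(self, integer_clip, tmp_path):
        path = save_clip(integer_clip, tmp_path / "stack")
        loaded = load_clip(path, fps=25.0)
        np.testing.assert_array_equal(loaded.frames, integer_clip.frames)
        assert loaded.fps == 25.0

    def test_missing_fps_is_an_error(self, integer_clip, tmp_path):
        path = save_clip(integer_clip, tmp_path / "clip.tiff")
        with pytest.raises(VideoFormatError, match="frame rate"):
            load_clip(path)  # TIFF carries no rate metadata

    def test_missing_file(self, tmp_path):
        with pytest.raises(VideoFormatError):
            load_clip(tmp_path / "absent.tiff", fps=30.0)

    def test_quantized_mean_preserved(self, tmp_path):
        # constant-100 clip with sub-unit noise: 8-bit-style rounding
        # must keep the loaded mean within half a quantization step
        rng = np.random.default_rng(1)
        frames = np.round(100.0 + rng.normal(0, 0.3, (10, 16, 16)))
        path = save_clip(_clip(frames), tmp_path / "q.tiff")
        loaded = load_clip(path, fps=30.0)
        assert abs(loaded.frames.mean() - 100.0) < 0.5


class TestPseudoColor:
    def test_constant_color_maps_to_constant(self):
        lut = rainbow_lut()
        rgb = np.tile(lut[140], (4, 8, 8, 1))
        scalar = collapse_pseudo_color(rgb)
        assert np.all(scalar == 140)

    def test_palette_round_trip_is_monotone(self):
        lut = rainbow_lut()
        idx = collapse_pseudo_color(lut[None, None, :, :])
        np.testing.assert_array_equal(idx.ravel(), np.arange(256))


class TestCrop:
    def test_full_frame_identity(self, integer_clip):
        h, w = integer_clip.shape
        out = crop(integer_clip, BoundingBox(0, 0, w, h))
        np.testing.assert_array_equal(out.frames, integer_clip.frames)

    def test_single_pixel_series(self, integer_clip):
        out = crop(integer_clip, BoundingBox(0, 0, 1, 1))
        np.testing.assert_array_equal(out.frames[:, 0, 0], integer_clip.frames[:, 0, 0])
        assert out.frames.shape == (integer_clip.n_frames, 1, 1)

    def test_adjacent_halves_reassemble(self, integer_clip):
        h, w = integer_clip.shape
        left = crop(integer_clip, BoundingBox(0, 0, w // 2, h))
        right = crop(integer_clip, BoundingBox(w // 2, 0, w, h))
        np.testing.assert_array_equal(
            np.concatenate([left.frames, right.frames], axis=2), integer_clip.frames
        )

    def test_out_of_bounds(self, integer_clip):
        h, w = integer_clip.shape
        with pytest.raises(BoundsError):
            crop(integer_clip, BoundingBox(0, 0, w + 1, h))

    def test_crop_commutes_with_temporal_slice(self, integer_clip):
        box = BoundingBox(3, 2, 20, 10)
        a = crop(integer_clip.slice_frames(4, 16), box)
        b = crop(integer_clip, box).slice_frames(4, 16)
        np.testing.assert_array_equal(a.frames, b.frames)


class TestRoiAnnotations:
    def test_csv_round_trip_and_grouping(self, tmp_path):
        specs = [
            RoiSpec(
                clip_id=f"clip{i}",
                boxes=(
                    BoundingBox(0, 0, 10, 10, "thoracodorsal"),
                    BoundingBox(12, 0, 20, 10, "tail"),
                ),
                frame_range=(0, 299),
            )
            for i in range(3)
        ]
        path = save_rois(specs, tmp_path / "rois.csv")
        loaded = load_rois(path)
        assert len(loaded) == 3
        assert all(len(s.boxes) == 2 for s in loaded)
        assert loaded[0].frame_range == (0, 299)

    def test_json_round_trip(self, tmp_path):
        spec = RoiSpec(clip_id="c", boxes=(BoundingBox(1, 2, 3, 4, "body"),), frame_range=(0, 10))
        loaded = load_rois(save_rois([spec], tmp_path / "rois.json"))
        assert loaded[0].boxes[0] == BoundingBox(1, 2, 3, 4, "body")

    def test_inverted_box_rejected_with_row(self, tmp_path):
        df = pd.DataFrame(
            [dict(clip_id="c", label="tail", x0=5, y0=0, x1=5, y1=4, frame_start=0, frame_end=9)]
        )
        df.to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(AnnotationError, match="row 0"):
            load_rois(tmp_path / "bad.csv")

    def test_unknown_label_rejected(self):
        with pytest.raises(AnnotationError, match="label"):
            BoundingBox(0, 0, 4, 4, "wing")

    def test_missing_columns(self, tmp_path):
        pd.DataFrame([dict(clip_id="c", label="tail")]).to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(AnnotationError, match="missing columns"):
            load_rois(tmp_path / "bad.csv")


def _ellipse_frame(h=60, w=100, cy=30, cx=50, ay=14, ax=30, head_dx=18):
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    body = 60.0 * (((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 < 1.0)
    head = 20.0 * (np.hypot(xx - (cx + head_dx), yy - cy) < 6)
    return 20.0 + body + head


class TestFallbackDetect:
    def test_ellipse_body_box_contains_blob(self):
        frame = _ellipse_frame()
        boxes = {b.label: b for b in fallback_detect(frame)}
        body = boxes["body"]
        # strict-interior ellipse pixels span exactly [21, 80) × [17, 44)
        assert (body.x0, body.y0, body.x1, body.y1) == (21, 17, 80, 44)
        assert set(boxes) == {"body", "thoracodorsal", "tail"}

    def test_tail_is_far_from_bright_head(self):
        # head spot on the +x side → tail third on the -x side
        boxes = {b.label: b for b in fallback_detect(_ellipse_frame())}
        assert boxes["tail"].x1 <= boxes["thoracodorsal"].x0 + 1

    def test_translation_equivariance(self):
        frame = _ellipse_frame()
        shifted = np.roll(np.roll(frame, 5, axis=0), -7, axis=1)
        ref = fallback_detect(frame)
        moved = fallback_detect(shifted)
        for a, b in zip(ref, moved):
            assert b == a.shift(-7, 5)

    def test_constant_frame(self):
        with pytest.raises(DetectionError):
            fallback_detect(np.full((40, 40), 5.0))

    def test_pure_noise_extreme_quantile(self):
        rng = np.random.default_rng(3)
        with pytest.raises(DetectionError):
            fallback_detect(rng.normal(size=(64, 64)), intensity_quantile=0.999)

    def test_larger_of_two_blobs_wins(self):
        frame = np.zeros((60, 120))
        frame[10:30, 10:50] = 50.0  # area 800
        frame[35:45, 80:100] = 50.0  # area 200
        body = [b for b in fallback_detect(frame, intensity_quantile=0.5) if b.label == "body"][0]
        assert (body.x0, body.y0, body.x1, body.y1) == (10, 10, 50, 30)
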