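import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from aviresp.errors import DecompositionError
from aviresp.steerable_pyramid import (
    PyramidStack,
    adaptive_levels,
    build_filter_bank,
    build_pyramid,
    phase_series,
    reconstruct,
)


@pytest.fixture(scope="module")
def smooth_frame():
    rng = np.random.default_rng(2)
    return gaussian_filter(rng.normal(0.0, 1.0, (48, 64)), 1.5)


def _grating(omega=np.pi / 2, size=64, shift=0.0, angle=0.0):
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    u = np.cos(angle) * xx + np.sin(angle) * yy
    return np.sin(omega * (u + shift))


class TestAdaptiveLevels:
    @pytest.mark.parametrize(
        "hw,expected", [((480, 640), 4), ((32, 32), 1), ((8, 8), 1), ((120, 160), 2), ((256, 256), 4)]
    )
    def test_size_rule(self, hw, expected):
        assert adaptive_levels(*hw) == expected

    def test_too_small(self):
        with pytest.raises(DecompositionError):
            adaptive_levels(7, 640)

    def test_too_deep_for_size(self):
        with pytest.raises(DecompositionError):
            build_filter_bank((32, 32), levels=4)


class TestDecomposition:
    def test_constant_frame_energy_in_lowpass(self):
        p = build_pyramid(np.full((32, 32), 7.0), levels=1)
        for k in range(8):
            assert np.abs(p.band(0, k)).max() < 1e-10
        assert p.lowpass.mean() == pytest.approx(7.0, rel=1e-12)

    def test_linearity(self, smooth_frame):
        g = np.roll(smooth_frame, 5, axis=1)
        pa, pb = build_pyramid(smooth_frame, 2), build_pyramid(g, 2)
        pc = build_pyramid(2.0 * smooth_frame - 3.0 * g, 2)
        np.testing.assert_allclose(
            pc.band(1, 3), 2.0 * pa.band(1, 3) - 3.0 * pb.band(1, 3), atol=1e-12
        )

    def test_grating_orientation_selectivity(self):
        # horizontal wave vector → orientation band 0; the flat-tiling
        # cos^7 angular window leaks cos^14(22.5°) ≈ 0.33 into adjacent
        # bands and essentially nothing beyond them
        p = build_pyramid(_grating(), levels=1)
        energy = np.array([np.sum(np.abs(p.band(0, k)) ** 2) for k in range(8)])
        dominant = energy[0]
        assert dominant == energy.max()
        for k in (2, 3, 4, 5, 6):
            assert dominant > 10 * energy[k]
        for k in (1, 7):
            assert energy[k] / dominant == pytest.approx(np.cos(np.pi / 8) ** 14, abs=0.02)

    def test_rotated_grating_permutes_orientation_profile(self):
        # rotating the wave vector by 2 × 22.5° moves the energy two bands
        # over (diagonal gratings leak slightly on the periodic grid, so
        # only the dominant band and its concentration are compared)
        p0 = build_pyramid(_grating(angle=0.0), levels=1)
        p2 = build_pyramid(_grating(angle=2 * np.pi / 8), levels=1)
        e0 = np.array([np.sum(np.abs(p0.band(0, k)) ** 2) for k in range(8)])
        e2 = np.array([np.sum(np.abs(p2.band(0, k)) ** 2) for k in range(8)])
        assert int(np.argmax(e2)) == (int(np.argmax(e0)) + 2) % 8
        for k in range(8):
            if k not in (1, 2, 3):  # dominant band ± 1
                assert e2[2] > 10 * e2[k]

    def test_deterministic(self, smooth_frame):
        a = build_pyramid(smooth_frame, 2).band(0, 4)
        b = build_pyramid(smooth_frame.copy(), 2).band(0, 4)
        np.testing.assert_array_equal(a, b)


class TestReconstruction:
    def test_round_trip_error(self, smooth_frame):
        p = build_pyramid(smooth_frame, 2)
        rel = np.linalg.norm(reconstruct(p) - smooth_frame) / np.linalg.norm(smooth_frame)
        assert rel <= 1e-4

    def test_zeroed_pyramid_gives_zero(self, smooth_frame):
        p = build_pyramid(smooth_frame, 2)
        p.subbands = [[np.zeros_like(b) for b in lev] for lev in p.subbands]
        p.highpass = np.zeros_like(p.highpass)
        p.lowpass = np.zeros_like(p.lowpass)
        assert np.abs(reconstruct(p)).max() == 0

    def test_scaling_coefficients_scales_frame(self, smooth_frame):
        p = build_pyramid(smooth_frame, 2)
        p.subbands = [[2.0 * b for b in lev] for lev in p.subbands]
        p.highpass = 2.0 * p.highpass
        p.lowpass = 2.0 * p.lowpass
        np.testing.assert_allclose(reconstruct(p), 2.0 * smooth_frame, atol=1e-10)

    def test_mismatched_shapes_rejected(self, smooth_frame):
        p = build_pyramid(smooth_frame, 2)
        p.subbands[0][0] = p.subbands[0][0][:-1, :]
        with pytest.raises(DecompositionError):
            reconstruct(p)

    def test_tight_frame_energy_conservation(self, smooth_frame):
        # Σ filter² = 1 ⇒ Σ_bands ||masked spectrum||² equals input energy.
        bank = build_pyramid(smooth_frame, 2).bank
        spec2 = np.abs(np.fft.fft2(smooth_frame)) ** 2
        total = np.sum(spec2 * bank.highpass**2) + np.sum(spec2 * bank.lowpass**2)
        for lev in bank.bands:
            for mask in lev:
                total += np.sum(spec2 * mask**2)
        assert total == pytest.approx(np.sum(spec2), rel=1e-10)


class TestPhaseSeries:
    def test_static_video_constant_phase(self, smooth_frame):
        stack = PyramidStack.from_clip(np.tile(smooth_frame, (6, 1, 1)), 30.0, levels=1)
        series, reliable = phase_series(stack, 0, 0, (24, 30))
        assert reliable
        assert np.ptp(series) < 1e-9

    def test_translating_grating_linear_phase_slope(self):
        # sub-pixel velocity v ⇒ phase slope ω·v per frame in the aligned band
        omega, v = np.pi / 2, 0.05
        frames = np.stack([_grating(omega, shift=v * i) for i in range(40)])
        stack = PyramidStack.from_clip(frames, 30.0, levels=1)
        series, reliable = phase_series(stack, 0, 0, (32, 32))
        assert reliable
        slope = np.polyfit(np.arange(40), series, 1)[0]
        assert slope == pytest.approx(omega * v, rel=0.05)

    def test_full_period_translation_unwraps_to_2pi(self):
        omega = np.pi / 2
        period = 2 * np.pi / omega
        shifts = np.linspace(0.0, period, 12)
        frames = np.stack([_grating(omega, shift=s) for s in shifts])
        stack = PyramidStack.from_clip(frames, 30.0, levels=1)
        series, _ = phase_series(stack, 0, 0, (16, 40))
        assert series[-1] - series[0] == pytest.approx(2 * np.pi, rel=1e-6)

    @pytest.mark.parametrize("d", [0.1, 0.5, 1.0])
    def test_shift_to_phase_law(self, d):
        # the load-bearing property: Δphase/ω recovers the displacement
        omega = np.pi / 2
        frames = np.stack([_grating(omega), _grating(omega, shift=d)])
        stack = PyramidStack.from_clip(frames, 30.0, levels=1)
        c = stack.subband_series(0, 0)
        dphase = np.angle(c[1] * np.conj(c[0]))[16:48, 16:48].mean()
        assert dphase / omega == pytest.approx(d, rel=0.05)

    def test_low_amplitude_pixel_flagged(self):
        # constant frames put everything in the lowpass residual: oriented
        # coefficients are round-off, and their phase must be flagged
        frames = np.tile(np.full((32, 32), 3.0), (6, 1, 1))
        stack = PyramidStack.from_clip(frames, 30.0, levels=1)
        _, reliable = phase_series(stack, 0, 0, (16, 16))
        assert not reliable
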