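"""Illumination estimation, smoke weights, YCbCr fusion and luma stretch."""

import numpy as np
import pytest

from endodefog.blending import (
    WEIGHT_FLOOR,
    BlendConfig,
    blend_channels,
    classify_smoke,
    estimate_illumination,
    recombine,
    smoke_weight,
    stretch_histogram,
)
from endodefog.frames import rgb_to_ycbcr, ycbcr_to_rgb


def recursive_pass_oracle(signal, sigma_spatial, sigma_range):
    """Direct causal+anticausal recursive filtering of one row, written
    independently of the production implementation."""
    sig = list(map(float, signal))
    n = len(sig)
    a = np.exp(-np.sqrt(2.0) / sigma_spatial)
    d = [0.0] + [
        1.0 + (sigma_spatial / sigma_range) * abs(sig[i] - sig[i - 1])
        for i in range(1, n)
    ]
    out = sig[:]
    for i in range(1, n):
        v = a ** d[i]
        out[i] = (1 - v) * out[i] + v * out[i - 1]
    for i in range(n - 2, -1, -1):
        v = a ** d[i + 1]
        out[i] = (1 - v) * out[i] + v * out[i + 1]
    return np.array(out)


class TestEstimateIllumination:
    def test_constant_plane_is_fixed_point(self):
        plane = np.full((10, 12), 0.4)
        out = estimate_illumination(plane, 30.0, 0.2)
        np.testing.assert_allclose(out, 0.4, atol=1e-12)

    def test_tiny_sigma_range_blocks_all_diffusion(self, rng):
        plane = rng.uniform(size=(8, 10))
        out = estimate_illumination(plane, 30.0, 1e-9)
        np.testing.assert_allclose(out, plane, atol=1e-9)

    def test_single_row_matches_independent_oracle(self):
        signal = np.array([0.2] * 6 + [0.8] * 6)
        out = estimate_illumination(signal.reshape(1, -1), 5.0, 0.3, iterations=1)
        oracle = recursive_pass_oracle(signal, 5.0, 0.3)
        np.testing.assert_allclose(out[0], oracle, atol=1e-12)

    def test_accepts_rgb_frame(self, vessel_scene):
        clean, _ = vessel_scene
        out = estimate_illumination(clean)
        assert out.shape == clean.shape[:2]
        assert out.min() >= 0 and out.max() <= 1

    def test_rejects_non_positive_sigmas(self):
        with pytest.raises(ValueError):
            estimate_illumination(np.zeros((4, 4)), 0.0, 0.2)
        with pytest.raises(ValueError):
            estimate_illumination(np.zeros((4, 4)), 30.0, -1.0)


class TestSmokeWeight:
    def test_weight_one_inside_heavy_interval(self):
        g = np.full((2, 2), 64 / 255)
        w = smoke_weight(g, BlendConfig(), "heavy")
        np.testing.assert_array_equal(w, 1.0)

    def test_weight_one_inside_thin_interval(self):
        g = np.full((2, 2), 150 / 255)
        w = smoke_weight(g, BlendConfig(), "thin")
        np.testing.assert_array_equal(w, 1.0)

    def test_floor_beyond_transition(self):
        g = np.full((2, 2), 250 / 255)
        w = smoke_weight(g, BlendConfig(transition_width=16), "heavy")
        np.testing.assert_array_equal(w, WEIGHT_FLOOR)

    def test_linear_ramp_midpoint(self):
        g = np.full((1, 1), 136 / 255)
        w = smoke_weight(g, BlendConfig(transition_width=16), "heavy")
        assert w[0, 0] == pytest.approx(0.5)

    def test_hard_intervals_with_zero_transition(self):
        cfg = BlendConfig(transition_width=0)
        assert smoke_weight(np.full((1, 1), 129 / 255), cfg, "heavy")[0, 0] == WEIGHT_FLOOR

    def test_unresolved_level_rejected(self):
        with pytest.raises(ValueError):
            smoke_weight(np.zeros((2, 2)), BlendConfig(), "auto")


class TestClassifySmoke:
    @pytest.mark.parametrize(
        "level, expected",
        [(64 / 255, "heavy"), (200 / 255, "thin"), (128 / 255, "thin")],
    )
    def test_mean_luma_rule(self, level, expected):
        frame = np.full((4, 4, 3), level)
        assert classify_smoke(frame) == expected


class TestBlendChannels:
    def test_one_sided_weights_return_first_branch(self, rng):
        j = rng.uniform(size=(6, 6, 3))
        l = rng.uniform(size=(6, 6, 3))
        wj = np.ones((6, 6))
        wl = np.full((6, 6), WEIGHT_FLOOR)
        fused = blend_channels(j, l, wj, wl)
        ref = rgb_to_ycbcr(j)
        assert np.abs(fused.y - ref.y).max() < 2 * WEIGHT_FLOOR

    def test_equal_weights_give_midpoint(self, rng):
        j = rng.uniform(size=(5, 5, 3))
        l = rng.uniform(size=(5, 5, 3))
        w = np.full((5, 5), 0.7)
        fused = blend_channels(j, l, w, w)
        jy, ly = rgb_to_ycbcr(j), rgb_to_ycbcr(l)
        np.testing.assert_allclose(fused.y, 0.5 * (jy.y + ly.y), atol=1e-12)
        np.testing.assert_allclose(fused.cb, 0.5 * (jy.cb + ly.cb), atol=1e-12)

    def test_three_to_one_weighted_mean(self):
        j = np.full((2, 2, 3), 0.8)
        l = np.full((2, 2, 3), 0.4)
        fused = blend_channels(j, l, np.full((2, 2), 3.0), np.ones((2, 2)))
        jy = rgb_to_ycbcr(j).y
        ly = rgb_to_ycbcr(l).y
        np.testing.assert_allclose(fused.y, 0.75 * jy + 0.25 * ly, atol=1e-12)

    def test_convex_combination_bound(self, rng):
        j = rng.uniform(size=(7, 7, 3))
        l = rng.uniform(size=(7, 7, 3))
        wj = rng.uniform(WEIGHT_FLOOR, 1.0, size=(7, 7))
        wl = rng.uniform(WEIGHT_FLOOR, 1.0, size=(7, 7))
        fused = blend_channels(j, l, wj, wl)
        jy, ly = rgb_to_ycbcr(j), rgb_to_ycbcr(l)
        for plane, pj, pl in [
            (fused.y, jy.y, ly.y),
            (fused.cb, jy.cb, ly.cb),
            (fused.cr, jy.cr, ly.cr),
        ]:
            lo = np.minimum(pj, pl) - 1e-12
            hi = np.maximum(pj, pl) + 1e-12
            assert (plane >= lo).all() and (plane <= hi).all()

    def test_shape_mismatch_rejected(self, rng):
        j = rng.uniform(size=(4, 4, 3))
        with pytest.raises(ValueError):
            blend_channels(j, j, np.ones((4, 4)), np.ones((3, 3)))


class TestStretchHistogram:
    def test_full_span_endpoints(self):
        plane = np.array([[0.0, 0.5], [1.0, 0.25]])
        out = stretch_histogram(plane)
        assert out[0, 0] == pytest.approx(15 / 255, abs=1e-12)
        assert out[1, 0] == pytest.approx(236 / 255, abs=1e-12)
        assert out[0, 1] == pytest.approx(125.5 / 255, abs=1e-9)

    def test_extrema_exact_for_random_planes(self, rng):
        for _ in range(100):
            plane = rng.uniform(size=(12, 12))
            out = stretch_histogram(plane)
            assert out.min() == pytest.approx(15 / 255, abs=1e-12)
            assert out.max() == pytest.approx(236 / 255, abs=1e-12)

    def test_rank_preserving(self, rng):
        plane = rng.uniform(size=(10, 10))
        out = stretch_histogram(plane)
        assert (
            np.argsort(plane.ravel()) == np.argsort(out.ravel())
        ).all()

    def test_constant_plane_maps_to_midpoint(self, caplog):
        out = stretch_histogram(np.full((4, 4), 0.3))
        np.testing.assert_allclose(out, (15 + 236) / 2 / 255)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            BlendConfig(stretch_low=240, stretch_high=15)


class TestRecombine:
    def test_neutral_chroma_gives_grayscale(self):
        y = np.full((3, 3), 0.5)
        neutral = np.full((3, 3), 128 / 255)
        rgb = recombine(y, neutral, neutral)
        np.testing.assert_allclose(rgb[..., 0], rgb[..., 1], atol=1e-9)
        np.testing.assert_allclose(rgb[..., 1], rgb[..., 2], atol=1e-9)

    def test_inverse_pair_without_stretch(self, rng):
        frame = rng.uniform(size=(8, 8, 3))
        ycc = rgb_to_ycbcr(frame)
        back = recombine(ycc.y, ycc.cb, ycc.cr)
        assert np.abs(back - frame).max() < 2 / 255

    def test_gamut_exceeding_planes_clipped(self):
        y = np.full((3, 3), 235 / 255)
        cb = np.full((3, 3), 240 / 255)
        cr = np.full((3, 3), 16 / 255)
        rgb = recombine(y, cb, cr)
        assert rgb.min() >= 0.0 and rgb.max() <= 1.0
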