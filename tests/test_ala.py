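"""Adaptive local averaging: per-pixel contract and oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aladenoise.ala import AlaParams, ala_filter, ala_pixel, patch_variability
from helpers import naive_ala, random_plane


class TestPatchVariability:
    def test_constant_window_zero(self):
        y = np.full((7, 7), 50.0)
        assert patch_variability(y, (3, 3), 1, "stddev") == 0.0
        assert patch_variability(y, (3, 3), 1, "range") == 0.0

    def test_single_outlier_hand_value(self):
        # 3x3 window with eight zeros and one 255:
        # population stddev = 255*sqrt(8)/9, range = 255
        y = np.zeros((5, 5))
        y[2, 2] = 255.0
        assert patch_variability(y, (2, 2), 1, "stddev") == pytest.approx(255 * np.sqrt(8) / 9)
        assert patch_variability(y, (2, 2), 1, "range") == 255.0

    def test_corner_window_clipped(self):
        y = np.arange(25, dtype=np.float64).reshape(5, 5)
        # corner sees only the in-bounds 2x2 block {0, 1, 5, 6}
        block = y[:2, :2]
        assert patch_variability(y, (0, 0), 1) == pytest.approx(block.std())

    def test_center_outside_plane(self):
        with pytest.raises(IndexError):
            patch_variability(np.zeros((4, 4)), (4, 0), 1)


class TestAlaPixel:
    def test_constant_plane_fixed_point(self):
        y = np.full((9, 9), 77.0)
        assert ala_pixel(y, (4, 4), AlaParams(threshold=5.0)) == 77.0

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(7)
        y = random_plane(rng, 9, 9)
        params = AlaParams(threshold=5.6, max_extent=8)
        oracle = naive_ala(y, 5.6, r_max=4)
        assert ala_pixel(y, (4, 4), params) == oracle[4, 4]

    def test_edge_pixel_untouched_when_smallest_window_fails(self):
        y = np.zeros((9, 9))
        y[:, 4:] = 255.0
        # r=1 window at the boundary mixes 0 and 255: stddev >> threshold
        params = AlaParams(threshold=10.0)
        assert ala_pixel(y, (4, 4), params) == y[4, 4]
        assert ala_pixel(y, (4, 3), params) == y[4, 3]


class TestAlaFilter:
    def test_constant_plane_identity(self):
        y = np.full((20, 20), 96.0)
        assert np.array_equal(ala_filter(y, AlaParams(threshold=5.0)), y)

    @pytest.mark.parametrize("th", [0.0, 2.0, 5.6, 50.0])
    def test_equals_naive_oracle(self, th):
        rng = np.random.default_rng(int(th * 10))
        y = random_plane(rng, 40, 37)
        params = AlaParams(threshold=th)
        fast = ala_filter(y, params)
        assert np.array_equal(fast, naive_ala(y, th))

    def test_equals_naive_oracle_range_statistic(self):
        rng = np.random.default_rng(11)
        y = random_plane(rng, 32, 32)
        params = AlaParams(threshold=30.0, variability_statistic="range")
        fast = ala_filter(y, params)
        assert np.array_equal(fast, naive_ala(y, 30.0, statistic="range"))

    def test_smooth_region_with_structured_plane(self):
        # piecewise scene: smoothing confined to each side of the contour
        y = np.full((48, 48), 50.0)
        y[:, 24:] = 200.0
        rng = np.random.default_rng(12)
        noisy = np.round(np.clip(y + rng.normal(0, 5, y.shape), 0, 255))
        params = AlaParams(threshold=12.0)
        out = ala_filter(noisy, params)
        left_in, left_out = noisy[:, :20], out[:, :20]
        right_in, right_out = noisy[:, 28:], out[:, 28:]
        assert left_out.var() < left_in.var()
        assert right_out.var() < right_in.var()
        # half-max crossing of every row stays at the contour column
        crossings = (out >= 125).argmax(axis=1)
        assert np.all(np.abs(crossings - 24) <= 1)

    def test_edge_preservation_exact(self):
        y = np.zeros((32, 32))
        y[:, 16:] = 255.0
        out = ala_filter(y, AlaParams(threshold=10.0))
        assert np.array_equal(out, y)

    def test_monotone_smoothing_over_seeds(self):
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            y = np.round(np.clip(128 + rng.normal(0, 10, (32, 32)), 0, 255))
            out = ala_filter(y, AlaParams(threshold=8.0))
            assert out.var() <= y.var()

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        th=st.floats(0.0, 60.0, allow_nan=False),
        h=st.integers(8, 24),
        w=st.integers(8, 24),
    )
    def test_range_preservation_property(self, seed, th, h, w):
        rng = np.random.default_rng(seed)
        y = random_plane(rng, h, w)
        out = ala_filter(y, AlaParams(threshold=th))
        assert out.min() >= y.min() - 1e-9
        assert out.max() <= y.max() + 1e-9

    def test_mean_brightness_conserved_on_noise(self):
        rng = np.random.default_rng(13)
        y = np.round(np.clip(96 + rng.normal(0, 10, (64, 64)), 0, 255))
        out = ala_filter(y, AlaParams(threshold=22.0))
        assert abs(out.mean() - y.mean()) / y.mean() < 0.01

    def test_degenerate_plane_rejected(self):
        with pytest.raises(ValueError):
            ala_filter(np.zeros((1, 5)), AlaParams(threshold=5.0))


class TestAlaParams:
    def test_extent_validation(self):
        with pytest.raises(ValueError):
            AlaParams(threshold=1.0, min_extent=5, max_extent=4)
        with pytest.raises(ValueError):
            AlaParams(threshold=-1.0)

    def test_radius_mapping_and_halo(self):
        p = AlaParams(threshold=1.0)
        assert (p.r_min, p.r_max, p.halo) == (1, 20, 20)
        q = AlaParams(threshold=1.0, min_extent=4, max_extent=12)
        assert (q.r_min, q.r_max) == (2, 6)
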