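"""Adaptive and baseline filters: weights, normalization, oracles,
equivariances."""

import numpy as np
import pytest

from oolsf import (FilterParams, GrayImage, bilateral_filter, build_bank,
                   detect, gaussian_filter, oolsf_filter, range_weights,
                   spatial_weights)
from oolsf.filters import spatial_weight_table
from conftest import naive_bilateral, naive_oolsf


class TestSpatialWeights:
    def test_center_weight_is_one(self, default_params):
        for t in range(default_params.n):
            for s in range(default_params.m):
                w = spatial_weights(t, s, default_params)
                assert w[4, 4] == 1.0
                assert np.all(w > 0.0) and np.all(w <= 1.0)

    def test_vertical_kernel_cross_section_value(self, default_params):
        # theta = 0, offset x = 1, sigma = 1.6 (largest scale)
        w = spatial_weights(0, 3, default_params)
        expected = np.exp(-1.0 / (2.0 * 1.6 ** 2))
        assert expected == pytest.approx(0.8226, abs=5e-5)
        for row in range(9):
            assert w[row, 5] == pytest.approx(expected, abs=1e-12)

    def test_constant_along_line_direction(self, default_params):
        # theta = 0: columns constant; theta = 90 (t=6): rows constant
        w0 = spatial_weights(0, 1, default_params)
        assert all(np.ptp(w0[:, c]) == 0.0 for c in range(9))
        w90 = spatial_weights(6, 1, default_params)
        assert all(np.ptp(w90[r, :]) < 1e-15 for r in range(9))

    def test_matches_bank_kernel_magnitude_on_support(self, default_params,
                                                      default_bank):
        """On the line support the adaptive weights are the magnitude of
        the raw detection kernel; outside it the kernel is cut to zero
        while the weight stays positive."""
        for t, s in [(0, 0), (3, 2), (7, 1), (11, 3)]:
            w = spatial_weights(t, s, default_params)
            raw = default_bank.kernel(t, s).values
            on = raw != 0.0
            np.testing.assert_allclose(w[on], np.abs(raw[on]), atol=1e-12)
            assert np.all(w[~on] > 0.0)

    def test_invalid_indices_raise(self, default_params):
        with pytest.raises(ValueError):
            spatial_weights(12, 0, default_params)
        with pytest.raises(ValueError):
            spatial_weights(0, 4, default_params)


class TestRangeWeights:
    def test_equal_intensity_gives_weight_one(self):
        w = range_weights(np.full((5, 5), 0.3), 0.3, 0.04)
        np.testing.assert_array_equal(w, np.ones((5, 5)))

    def test_one_sigma_difference(self):
        w = range_weights(np.array([[0.54]]), 0.5, 0.04)
        assert w[0, 0] == pytest.approx(np.exp(-0.5), abs=1e-12)
        assert np.exp(-0.5) == pytest.approx(0.6065, abs=5e-5)

    def test_strictly_decreasing_in_intensity_gap(self):
        diffs = np.linspace(0.0, 1.0, 50)
        w = range_weights(diffs[None, :], 0.0, 0.04)[0]
        assert np.all(np.diff(w) < 0.0)

    def test_non_positive_sigma_rejected(self):
        with pytest.raises(ValueError):
            range_weights(np.zeros((3, 3)), 0.0, 0.0)


class TestConstantImages:
    @pytest.mark.parametrize("value", [0.0, 0.37, 1.0])
    def test_all_filters_pass_constants_through(self, value, default_params):
        img = GrayImage(np.full((20, 20), value), "dark")
        for out in (oolsf_filter(img, default_params),
                    bilateral_filter(img, 1.0, 0.04),
                    gaussian_filter(img, 1.0)):
            np.testing.assert_allclose(out.values, value, atol=1e-12)


class TestConvexity:
    def test_outputs_bounded_by_window_extremes(self, default_params):
        rng = np.random.default_rng(9)
        vals = rng.random((40, 40))
        img = GrayImage(vals, "dark")
        k = default_params.k
        padded = np.pad(vals, k // 2, mode="reflect")
        from numpy.lib.stride_tricks import sliding_window_view
        win = sliding_window_view(padded, (k, k))
        lo = win.min(axis=(-1, -2)) - 1e-12
        hi = win.max(axis=(-1, -2)) + 1e-12
        for out in (oolsf_filter(img, default_params),
                    bilateral_filter(img, 1.2, 0.1, k),
                    gaussian_filter(img, 1.2, k)):
            assert np.all(out.values >= lo)
            assert np.all(out.values <= hi)


class TestOracleEquivalence:
    def test_oolsf_matches_double_loop_oracle(self, default_params,
                                              default_bank):
        rng = np.random.default_rng(7)
        vals = rng.random((64, 64))
        img = GrayImage(vals, "dark")
        det = detect(img, default_bank)
        out = oolsf_filter(img, default_params, bank=default_bank,
                           detection=det)
        ref = naive_oolsf(vals, default_params, det.theta_index,
                          det.scale_index)
        assert np.max(np.abs(out.values - ref)) < 1e-10

    def test_bilateral_matches_double_loop_oracle(self):
        rng = np.random.default_rng(7)
        vals = rng.random((64, 64))
        out = bilateral_filter(GrayImage(vals, "dark"), 1.5, 0.1, 9)
        ref = naive_bilateral(vals, 1.5, 0.1, 9)
        assert np.max(np.abs(out.values - ref)) < 1e-10


class TestGaussianBaseline:
    def test_impulse_response_center_value(self):
        """The center output of an impulse equals the normalized center
        weight of the Gaussian window (closed form)."""
        vals = np.zeros((21, 21))
        vals[10, 10] = 1.0
        sigma = 1.3
        out = gaussian_filter(GrayImage(vals, "dark"), sigma, 9)
        r = np.arange(-4, 5)
        xx, yy = np.meshgrid(r, r)
        w = np.exp(-(xx ** 2 + yy ** 2) / (2.0 * sigma ** 2))
        assert out.values[10, 10] == pytest.approx(w[4, 4] / w.sum(),
                                                   rel=1e-12)

    def test_bilateral_degenerates_to_gaussian_for_huge_sigma_r(self):
        """With the range kernel flattened (sigma_r >> intensity span) the
        bilateral filter is a windowed Gaussian mean."""
        rng = np.random.default_rng(15)
        img = GrayImage(rng.random((64, 64)), "dark")
        blf = bilateral_filter(img, 1.5, 1e4, 9)
        gss = gaussian_filter(img, 1.5, 9)
        assert np.max(np.abs(blf.values - gss.values)) < 1e-6


class TestOolsfProperties:
    def test_shift_equivariance_away_from_borders(self, default_params,
                                                  default_bank):
        rng = np.random.default_rng(23)
        vals = rng.random((48, 48))
        shifted = np.roll(vals, (3, 5), axis=(0, 1))
        out = oolsf_filter(GrayImage(vals, "dark"), default_params,
                           bank=default_bank).values
        out_shifted = oolsf_filter(GrayImage(shifted, "dark"),
                                   default_params, bank=default_bank).values
        k = default_params.k
        band = k + 5
        inner = np.s_[band:-band, band:-band]
        np.testing.assert_allclose(
            np.roll(out, (3, 5), axis=(0, 1))[inner], out_shifted[inner],
            atol=1e-12)

    def test_quarter_turn_equivariance(self, default_params, default_bank):
        """Filtering commutes with a 90-degree rotation at interior pixels
        (the orientation grid contains every angle's complement)."""
        rng = np.random.default_rng(31)
        vals = rng.random((64, 64))
        out = oolsf_filter(GrayImage(vals, "dark"), default_params,
                           bank=default_bank).values
        out_rot = oolsf_filter(GrayImage(np.rot90(vals), "dark"),
                               default_params, bank=default_bank).values
        band = default_params.k
        inner = np.s_[band:-band, band:-band]
        diff = np.abs(out_rot - np.rot90(out))[inner]
        assert diff.max() < 1e-10

    def test_image_smaller_than_window_rejected(self, default_params):
        with pytest.raises(ValueError, match="smaller"):
            oolsf_filter(GrayImage(np.zeros((5, 5)), "dark"),
                         default_params)

    def test_spatial_table_matches_single_windows(self, default_params):
        table = spatial_weight_table(default_params)
        for t, s in [(0, 0), (5, 2), (11, 3)]:
            np.testing.assert_array_equal(table[t, s],
                                          spatial_weights(t, s,
                                                          default_params))
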