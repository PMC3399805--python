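"""Box-counting and Minkowski dimension estimators against oracles."""

import numpy as np
import pytest
from scipy import ndimage

from vascomplex.estimators import (
    BoxCountModel,
    MinkowskiModel,
    box_counts,
    minkowski_areas,
)
from vascomplex.scaling import RegressionRange, fit_dimension
from vascomplex.synthetic import koch_curve, sierpinski_carpet

LOG8_LOG3 = np.log(8) / np.log(3)  # carpet dimension ~ 1.8928
LOG4_LOG3 = np.log(4) / np.log(3)  # Koch dimension ~ 1.2619


def _bruteforce_box_count(img, eps):
    h, w = img.shape
    count = 0
    for top in range(0, h, eps):
        for left in range(0, w, eps):
            if img[top : top + eps, left : left + eps].any():
                count += 1
    return count


def _bruteforce_dilation_area(img, n):
    return int(ndimage.binary_dilation(img, structure=np.ones((2 * n + 1, 2 * n + 1))).sum())


class TestBoxCounts:
    def test_single_pixel_counts_one_at_every_scale(self):
        img = np.zeros((64, 64), dtype=np.uint8)
        img[17, 42] = 1
        curve = box_counts(img)
        np.testing.assert_array_equal(curve.measures, np.ones(7))
        assert fit_dimension(curve).value == pytest.approx(0.0)

    def test_fully_foreground_image_counts_all_cells(self):
        img = np.ones((256, 256), dtype=np.uint8)
        curve = box_counts(img)
        np.testing.assert_array_equal(curve.measures, (256 / curve.scales) ** 2)
        assert fit_dimension(curve).value == pytest.approx(2.0)

    def test_matches_bruteforce_occupancy_oracle(self, rng):
        img = (rng.random((64, 64)) < 0.08).astype(np.uint8)
        curve = box_counts(img)
        for eps, n in zip(curve.scales, curve.measures):
            assert n == _bruteforce_box_count(img, int(eps))

    def test_nonsquare_image_with_partial_edge_boxes(self, rng):
        img = (rng.random((37, 61)) < 0.2).astype(np.uint8)
        curve = box_counts(img)
        for eps, n in zip(curve.scales, curve.measures):
            assert n == _bruteforce_box_count(img, int(eps))

    def test_counts_monotone_and_bounded(self, rng):
        img = (rng.random((50, 70)) < 0.15).astype(np.uint8)
        curve = box_counts(img)
        assert curve.measures[0] == img.sum()  # N(1) = foreground count
        assert np.all(np.diff(curve.measures) <= 0)
        for eps, n in zip(curve.scales, curve.measures):
            assert n <= np.ceil(70 / eps) * np.ceil(50 / eps)

    def test_grid_anchor_shifts_counts_on_nonsquare_canvas(self, rng):
        # the matrix-size sensitivity of box counting: moving the grid
        # origin on a non-power-of-two canvas changes the counts
        img = np.zeros((436, 364), dtype=np.uint8)
        yy, xx = np.mgrid[0:436, 0:364]
        img[((yy * 7 + xx * 3) % 11 == 0) & ((yy + xx) % 5 < 2)] = 1
        c0 = box_counts(img, anchor=(0, 0))
        c1 = box_counts(img, anchor=(3, 5))
        assert np.any(c0.measures != c1.measures)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError, match="foreground"):
            box_counts(np.zeros((8, 8), dtype=np.uint8))


class TestMinkowskiAreas:
    def test_single_pixel_areas_are_square_sizes(self):
        img = np.zeros((64, 64), dtype=np.uint8)
        img[30, 30] = 1
        curve = minkowski_areas(img, n_max=10)
        np.testing.assert_array_equal(curve.measures, (2 * np.arange(11) + 1.0) ** 2)
        assert fit_dimension(curve).value == pytest.approx(0.0)

    def test_fully_foreground_area_saturates_at_canvas(self):
        img = np.ones((40, 40), dtype=np.uint8)
        curve = minkowski_areas(img, n_max=5)
        np.testing.assert_array_equal(curve.measures, np.full(6, 1600.0))
        assert fit_dimension(curve).value == pytest.approx(2.0)

    def test_horizontal_line_scales_like_a_curve(self):
        img = np.zeros((120, 460), dtype=np.uint8)
        img[60, 30:430] = 1  # length 400, far from borders
        curve = minkowski_areas(img, n_max=8)
        for n, area in enumerate(curve.measures):
            assert area == (2 * n + 1) * (400 + 2 * n)  # rectangle of the dilation
        est = fit_dimension(curve, RegressionRange(3, 8))
        assert est.value == pytest.approx(1.0, abs=0.1)

    def test_matches_bruteforce_dilation_oracle(self, rng):
        img = (rng.random((64, 64)) < 0.03).astype(np.uint8)
        curve = minkowski_areas(img, n_max=6)
        for n in range(7):
            assert curve.measures[n] == _bruteforce_dilation_area(img, n)

    def test_first_area_is_foreground_count_and_monotone(self, rng):
        img = (rng.random((48, 48)) < 0.1).astype(np.uint8)
        curve = minkowski_areas(img, n_max=12)
        assert curve.measures[0] == img.sum()
        assert np.all(np.diff(curve.measures) >= 0)
        assert curve.measures[-1] <= 48 * 48

    def test_translation_invariance_away_from_borders(self):
        base = np.zeros((200, 200), dtype=np.uint8)
        base[90:110, 90:110] = np.tri(20, dtype=np.uint8)
        shifted = np.roll(base, (15, -12), axis=(0, 1))
        c0 = minkowski_areas(base, n_max=8)
        c1 = minkowski_areas(shifted, n_max=8)
        np.testing.assert_array_equal(c0.measures, c1.measures)

    def test_radius_rescaling_leaves_slope_unchanged(self):
        img = (np.random.default_rng(0).random((64, 64)) < 0.05).astype(np.uint8)
        curve = minkowski_areas(img, n_max=10)
        est = fit_dimension(curve)
        from vascomplex.scaling import ScalingCurve

        rescaled = ScalingCurve(curve.scales * 3.7, curve.measures, "minkowski")
        est2 = fit_dimension(rescaled)
        assert est2.slope == pytest.approx(est.slope, abs=1e-12)


class TestAnalyticPrefractals:
    def test_carpet_box_dimension(self):
        res = BoxCountModel(sierpinski_carpet(5)).fit()
        assert res.value == pytest.approx(LOG8_LOG3, abs=0.06)
        assert abs(res.fit_r) >= 0.995

    def test_carpet_minkowski_dimension(self):
        res = MinkowskiModel(sierpinski_carpet(5)).fit()
        assert res.value == pytest.approx(LOG8_LOG3, abs=0.08)

    @pytest.mark.parametrize("depth,scale", [(4, 3), (5, 1)])
    def test_koch_both_estimators_near_analytic_value(self, depth, scale):
        img = koch_curve(depth, scale=scale, margin=10)
        d_b = BoxCountModel(img).fit().value
        d_m = MinkowskiModel(img).fit().value
        assert d_b == pytest.approx(LOG4_LOG3, abs=0.08)
        assert d_m == pytest.approx(LOG4_LOG3, abs=0.08)

    def test_estimators_agree_on_strictly_self_similar_sets(self):
        # D_b and D_m approximate the same dimension only for strictly
        # self-similar sets; assert their agreement there
        img = sierpinski_carpet(5)
        d_b = BoxCountModel(img).fit().value
        d_m = MinkowskiModel(img).fit().value
        assert d_b == pytest.approx(d_m, abs=0.08)


class TestModelSurface:
    def test_results_carry_summary_and_curve_frame(self):
        res = BoxCountModel(sierpinski_carpet(4)).fit()
        text = res.summary()
        assert "Box-counting" in text and f"{res.value:.4f}" in text
        frame = res.curve_frame()
        assert set(frame.columns) == {"scale", "measure", "log_scale", "log_measure", "in_range"}
        assert frame["in_range"].sum() == len(res.range)

    def test_plot_loglog_returns_axes(self):
        import matplotlib

        matplotlib.use("Agg")
        res = MinkowskiModel(sierpinski_carpet(3)).fit()
        ax = res.plot_loglog()
        assert len(ax.lines) == 3
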