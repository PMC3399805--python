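"""Generators: DLA clusters, prefractals, cascades, the AVM cohort."""

import numpy as np
import pytest
from scipy import ndimage

from vascomplex.pipeline import cohort_fd_table, compare_hemispheres, max_slope
from vascomplex.synthetic import (
    CohortParams,
    DLAConfig,
    binomial_cascade,
    cascade_count_grid,
    generate_cohort,
    generate_dla,
    generate_dla_geometry,
    generate_prefractal,
    koch_curve,
    sierpinski_carpet,
    sierpinski_triangle,
)


class TestDLA:
    def test_budget_one_freezes_only_the_seed(self):
        img = generate_dla(DLAConfig(height=64, width=64, budget=1, rng_seed=0))
        assert img.sum() == 1
        assert img[32, 32] == 1

    def test_same_seed_is_bit_identical(self):
        cfg = DLAConfig(height=128, width=128, rng_seed=9)
        np.testing.assert_array_equal(generate_dla(cfg), generate_dla(cfg))

    def test_different_seeds_differ(self):
        a = generate_dla(DLAConfig(height=128, width=128, rng_seed=1))
        b = generate_dla(DLAConfig(height=128, width=128, rng_seed=2))
        assert np.any(a != b)

    def test_cluster_connected_and_budget_bounded(self):
        cfg = DLAConfig(height=128, width=128, budget=400, rng_seed=4)
        img = generate_dla(cfg)
        assert img.sum() <= cfg.budget + 1
        n_comp = ndimage.label(img, structure=np.ones((3, 3)))[1]
        assert n_comp == 1

    def test_growth_radially_bounded_by_stopping_rule(self):
        cfg = DLAConfig(height=128, width=128, rng_seed=3)
        img = generate_dla(cfg)
        ys, xs = np.nonzero(img)
        radius = np.sqrt((ys - 64.0) ** 2 + (xs - 64.0) ** 2).max()
        assert radius <= cfg.stop_fraction * 64 + 2.0

    def test_invivo_geometry_is_center_cropped(self):
        img = generate_dla_geometry("364x436", rng_seed=5)
        assert img.shape == (436, 364)
        full = generate_dla(DLAConfig(height=436, width=436, rng_seed=5))
        np.testing.assert_array_equal(img, full[:, 36:400])

    @pytest.mark.parametrize(
        "kwargs", [dict(budget=0), dict(stop_fraction=0.6), dict(sticking=5), dict(seed_pos=(999, 0))]
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DLAConfig(height=64, width=64, **kwargs)


class TestPrefractals:
    def test_carpet_depth_one_has_eight_pixels(self):
        img = sierpinski_carpet(1)
        assert img.shape == (3, 3)
        assert img.sum() == 8
        assert img[1, 1] == 0

    @pytest.mark.parametrize("depth", [1, 2, 3, 4, 5])
    def test_carpet_count_matches_generator_formula(self, depth):
        assert sierpinski_carpet(depth).sum() == 8**depth

    @pytest.mark.parametrize("depth", [1, 3, 6])
    def test_triangle_count_matches_generator_formula(self, depth):
        img = sierpinski_triangle(depth)
        assert img.shape == (2**depth, 2**depth)
        assert img.sum() == 3**depth

    def test_koch_depth_zero_is_a_straight_line(self):
        img = koch_curve(0)
        assert img.sum() == img.shape[1]
        assert (img.sum(axis=0) == 1).all()

    def test_koch_scale_and_margin(self):
        img = koch_curve(2, scale=2, margin=5)
        assert img.shape[1] == 9 * 2 + 1 + 10

    def test_dispatch_and_limits(self):
        np.testing.assert_array_equal(generate_prefractal("sierpinski_carpet", 2), sierpinski_carpet(2))
        with pytest.raises(ValueError):
            generate_prefractal("menger_sponge", 2)
        with pytest.raises(ValueError):
            sierpinski_carpet(9)  # canvas limit


class TestCascade:
    def test_balanced_weights_give_uniform_measure(self):
        m = binomial_cascade(0.5, 6)
        np.testing.assert_allclose(m, 1 / 64)

    def test_depth_three_masses_are_weight_products(self):
        m = binomial_cascade(0.7, 3)
        products = sorted(
            (0.7 if b == "0" else 0.3) * (0.7 if c == "0" else 0.3) * (0.7 if d == "0" else 0.3)
            for b, c, d in (format(i, "03b") for i in range(8))
        )
        np.testing.assert_allclose(sorted(m), products)
        assert m.sum() == pytest.approx(1.0)
        assert m.max() == pytest.approx(0.7**3)

    def test_count_grid_preserves_mass_ratios(self):
        grid = cascade_count_grid(0.7, 8, total=2**22)
        assert grid.shape == (1, 256)
        np.testing.assert_allclose(grid[0] / grid.sum(), binomial_cascade(0.7, 8), atol=1e-6)

    def test_degenerate_weights_rejected(self):
        with pytest.raises(ValueError):
            binomial_cascade(1.0, 4)
        with pytest.raises(ValueError):
            binomial_cascade(0.5, 0)


NOISE_FREE = dict(slope_noise_sd=0.0, diam_noise_sd=0.0)


class TestCohort:
    def test_subject_invariants(self):
        subs = generate_cohort(3, 2, rng_seed=0)
        assert len(subs) == 5
        for s in subs:
            assert s.left_image.shape == (436, 182)
            assert set(np.unique(s.left_image)) <= {0, 1}
            assert len(s.times) >= 10
            steps = np.diff(s.times)
            assert np.allclose(steps, steps[0])
            if s.group == "patient":
                assert s.avm_side in ("left", "right")
                avm = s.branch_count_left if s.avm_side == "left" else s.branch_count_right
                other = s.branch_count_right if s.avm_side == "left" else s.branch_count_left
                assert avm > other
                assert s.nidus_diameters is not None and len(s.nidus_diameters) == 4
            else:
                assert s.avm_side is None
                assert s.branch_count_left == s.branch_count_right

    def test_reproducible_per_seed(self):
        a = generate_cohort(2, 2, rng_seed=11)
        b = generate_cohort(2, 2, rng_seed=11)
        for s, t in zip(a, b):
            np.testing.assert_array_equal(s.left_image, t.left_image)
            np.testing.assert_array_equal(s.intensities, t.intensities)

    def test_noise_free_slope_and_diameter_monotone_in_tangle_size(self):
        # two patients with pinned tangle sizes d1 < d2 < d3: the larger
        # tangle must yield the larger transit slope and nidus diameter
        results = []
        for d in (20, 60, 120):
            params = CohortParams(nidus_branches_low=d, nidus_branches_high=d, **NOISE_FREE)
            s = generate_cohort(1, 0, params=params, rng_seed=2)[0]
            results.append((max_slope(s.times, s.intensities), float(np.mean(s.nidus_diameters))))
        slopes, diams = zip(*results)
        assert slopes[0] < slopes[1] < slopes[2]
        assert diams[0] < diams[1] < diams[2]

    def test_branch_count_drives_max_slope_exactly_at_zero_noise(self):
        params = CohortParams(**NOISE_FREE)
        subs = generate_cohort(6, 4, params=params, rng_seed=3)
        totals = np.array([s.total_branches for s in subs], dtype=float)
        slopes = np.array([max_slope(s.times, s.intensities) for s in subs])
        r = np.corrcoef(totals, slopes)[0, 1]
        assert r >= 0.9  # affine construction, discretization error only

    def test_controls_left_right_differences_center_at_zero(self):
        subs = generate_cohort(0, 20, rng_seed=1)
        table = cohort_fd_table(subs)
        _, paired = compare_hemispheres(table)
        row = paired.set_index(["contrast", "method"]).loc[("HC: left - right", "D_b")]
        assert abs(row["mean_diff"]) <= 2.5 * row["sem_diff"] + 1e-12
        assert row["p"] > 0.01

    def test_strong_effect_zero_noise_avm_dominates_all_estimators(self):
        params = CohortParams(
            nidus_branches_low=60,
            nidus_branches_high=120,
            angle_jitter_deg=3.0,
            length_jitter=0.03,
            nidus_center_jitter=0.0,
            **NOISE_FREE,
        )
        subs = generate_cohort(6, 0, params=params, rng_seed=5)
        piv = cohort_fd_table(subs).pivot_table(
            index=["subject", "role"], columns="method", values="value"
        )
        for sid in piv.index.get_level_values(0).unique():
            for method in ("D_b", "D_m", "D_0", "D_1", "D_2"):
                assert piv.loc[(sid, "avm"), method] > piv.loc[(sid, "no_avm"), method]

    def test_degenerate_parameters_rejected(self):
        with pytest.raises(ValueError, match="branches"):
            CohortParams(tree_depth=0)
        with pytest.raises(ValueError):
            CohortParams(nidus_branches_low=0)
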