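"""Grids, plug-in bandwidths, weighted KDEs, HDR and niche statistics."""

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings, strategies as st

from nichekde.kde import (
    ComparabilityError,
    DensityGrid,
    Grid2D,
    GridExtentError,
    InsufficientObservationsError,
    density_grid_from_values,
    evaluate_kde,
    hdr_mask,
    kde_diagnostics,
    make_common_grid,
    niche_breadth,
    niche_overlap,
    niche_position,
    normal_scale_bandwidth,
    plugin_bandwidth,
)


class TestGrid:
    def test_unit_square_spacing(self):
        g = Grid2D(0, 1, 0, 1, 101)
        assert g.dx == pytest.approx(0.01)
        assert g.dy == pytest.approx(0.01)
        assert g.cell_area == pytest.approx(1e-4)

    def test_padding_expands_range(self):
        scores = np.array([[0.0, 0.0], [10.0, 10.0]])
        g = make_common_grid(scores, resolution=101, padding_fraction=0.1)
        assert (g.xmin, g.xmax) == (-1.0, 11.0)
        assert (g.ymin, g.ymax) == (-1.0, 11.0)

    def test_hash_identifies_identical_grids(self):
        a = Grid2D(0, 1, 0, 2, 64)
        b = Grid2D(0, 1, 0, 2, 64)
        c = Grid2D(0, 1, 0, 2, 65)
        assert a.hash() == b.hash() != c.hash()

    def test_degenerate_axis_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            make_common_grid(np.array([[0.0, 1.0], [0.0, 2.0]]))

    def test_minimum_resolution_enforced(self):
        with pytest.raises(ValueError):
            Grid2D(0, 1, 0, 1, 31)


class TestPluginBandwidth:
    def test_within_factor_two_of_normal_scale_on_gaussian_data(self):
        x = np.random.default_rng(1).standard_normal((1000, 2))
        h = plugin_bandwidth(x)
        h_ns = normal_scale_bandwidth(x)
        gen_eigs = scipy.linalg.eigvalsh(h, h_ns)
        assert gen_eigs.min() > 0.5
        assert gen_eigs.max() < 2.0

    def test_affine_equivariance_under_scaling(self):
        x = np.random.default_rng(2).standard_normal((400, 2))
        h = plugin_bandwidth(x)
        h3 = plugin_bandwidth(3.0 * x)
        np.testing.assert_allclose(h3, 9.0 * h, rtol=1e-10)

    def test_uniform_weight_scaling_is_invariant(self):
        x = np.random.default_rng(3).standard_normal((200, 2))
        h1 = plugin_bandwidth(x, weights=np.ones(200))
        hk = plugin_bandwidth(x, weights=np.full(200, 7.0))
        np.testing.assert_array_equal(h1, hk)

    def test_result_is_symmetric_positive_definite(self):
        x = np.random.default_rng(4).standard_normal((150, 2)) @ np.array(
            [[1.0, 0.6], [0.0, 0.4]]
        )
        h = plugin_bandwidth(x)
        np.testing.assert_allclose(h, h.T)
        assert np.linalg.eigvalsh(h).min() > 0

    def test_too_few_observations_raise_with_context(self):
        x = np.zeros((9, 2))
        with pytest.raises(InsufficientObservationsError, match="S1 2010"):
            plugin_bandwidth(x, context="S1 2010")


class TestEvaluate:
    def test_single_point_peak_value(self):
        grid = Grid2D(-3, 3, -3, 3, 61)
        dg = evaluate_kde(np.array([[0.0, 0.0]]), None, np.eye(2), grid)
        # kernel maximum of a bivariate standard normal: 1/(2*pi)
        assert dg.density.max() == pytest.approx(1 / (2 * np.pi), rel=1e-12)
        px, py = niche_position(dg)
        assert (px, py) == (0.0, 0.0)

    def test_captured_mass_contract(self, rng):
        x = rng.standard_normal((500, 2))
        grid = make_common_grid(x, resolution=101, padding_fraction=0.15)
        dg = evaluate_kde(x, None, plugin_bandwidth(x), grid)
        assert 0.98 <= dg.mass <= 1.0
        assert (dg.density >= 0).all()

    def test_weight_three_equals_three_coincident_points(self):
        grid = Grid2D(-4, 4, -4, 4, 64)
        pts = np.array([[0.5, -0.2], [1.0, 1.0]])
        h = 0.3 * np.eye(2)
        a = evaluate_kde(pts, np.array([3.0, 1.0]), h, grid)
        b = evaluate_kde(
            np.vstack([np.repeat(pts[:1], 3, axis=0), pts[1:]]), None, h, grid
        )
        np.testing.assert_allclose(a.density, b.density, atol=1e-15)

    def test_grid_too_small_raises(self, rng):
        x = rng.standard_normal((100, 2)) * 5
        grid = Grid2D(-1, 1, -1, 1, 32)
        with pytest.raises(GridExtentError, match="padding"):
            evaluate_kde(x, None, np.eye(2), grid)

    def test_non_spd_bandwidth_rejected(self):
        grid = Grid2D(-1, 1, -1, 1, 32)
        with pytest.raises(ValueError, match="positive definite"):
            evaluate_kde(np.zeros((1, 2)), None, -np.eye(2), grid)


class TestHDR:
    def _discrete_grid(self, masses):
        grid = Grid2D(0, 1, 0, 1, 32)
        density = np.zeros(grid.shape)
        for k, m in enumerate(masses):
            density[5 + k, 7] = m / grid.cell_area
        return density, grid

    def test_discrete_masses_cumulative_rule(self):
        density, grid = self._discrete_grid([0.50, 0.30, 0.15, 0.05])
        mask, threshold = hdr_mask(density, grid, level=0.95)
        assert mask.sum() == 3  # 0.5 + 0.3 + 0.15 reaches 0.95, boundary in
        assert threshold == pytest.approx(0.15 / grid.cell_area)

    def test_level_one_masks_all_positive_cells(self):
        density, grid = self._discrete_grid([0.50, 0.30, 0.15, 0.05])
        mask, _ = hdr_mask(density, grid, level=1.0)
        assert mask.sum() == 4

    @given(level=st.floats(0.05, 0.99))
    @settings(max_examples=25, deadline=None)
    def test_mask_grows_with_level(self, level):
        density, grid = self._discrete_grid([0.40, 0.25, 0.15, 0.12, 0.08])
        small, _ = hdr_mask(density, grid, level=level * 0.5)
        large, _ = hdr_mask(density, grid, level=level)
        assert small.sum() <= large.sum()
        assert (large | small == large).all()  # nesting

    def test_invalid_level_rejected(self):
        density, grid = self._discrete_grid([1.0])
        with pytest.raises(ValueError):
            hdr_mask(density, grid, level=1.2)


class TestBreadthPosition:
    def test_breadth_of_discrete_example(self):
        grid = Grid2D(0, 1, 0, 1, 32)
        density = np.zeros(grid.shape)
        for k, m in enumerate([0.5, 0.3, 0.15, 0.05]):
            density[3, 4 + k] = m / grid.cell_area
        dg = density_grid_from_values(density, grid, level=0.95)
        assert niche_breadth(dg) == 3
        assert niche_breadth(dg) <= grid.resolution**2

    def test_smoothing_monotonicity(self):
        # quadrupling H strictly inflates the 95% region, seed by seed
        grid = Grid2D(-8, 8, -8, 8, 101)
        h = 0.25 * np.eye(2)
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal((200, 2))
            b1 = niche_breadth(evaluate_kde(x, None, h, grid))
            b4 = niche_breadth(evaluate_kde(x, None, 4 * h, grid))
            assert b4 > b1

    def test_position_near_mode_of_standard_normal(self):
        # the standard normal's KDE mode is flat-topped, so single draws
        # wander ~0.2; the Monte-Carlo mean must sit within 0.15 of the
        # true mode at the origin
        positions = []
        for seed in range(8):
            x = np.random.default_rng(seed).standard_normal((2000, 2))
            grid = make_common_grid(x, resolution=151, padding_fraction=0.15)
            dg = evaluate_kde(x, None, plugin_bandwidth(x), grid)
            positions.append(niche_position(dg))
            assert max(np.abs(positions[-1])) < 0.8  # sanity per draw
        mean_pos = np.mean(positions, axis=0)
        assert np.abs(mean_pos).max() < 0.15

    def test_position_of_unique_max_cell_is_exact(self):
        grid = Grid2D(0, 1, 0, 1, 32)
        density = np.zeros(grid.shape)
        density[10, 20] = 5.0
        dg = density_grid_from_values(density, grid)
        assert niche_position(dg) == (grid.x_centers[20], grid.y_centers[10])

    def test_position_tie_breaks_to_lowest_linear_index(self):
        grid = Grid2D(0, 1, 0, 1, 32)
        density = np.zeros(grid.shape)
        density[4, 9] = density[20, 3] = 1.0
        dg = density_grid_from_values(density, grid)
        assert dg.density[4, 9] == dg.density[20, 3]
        assert niche_position(dg) == (grid.x_centers[9], grid.y_centers[4])


class TestOverlap:
    @pytest.fixture(scope="class")
    def pair(self):
        rng = np.random.default_rng(10)
        a = rng.standard_normal((800, 2))
        b = rng.standard_normal((800, 2)) + np.array([1.5, 0.0])
        grid = make_common_grid(np.vstack([a, b]), resolution=121,
                                padding_fraction=0.2)
        h = 0.08 * np.eye(2)
        return (
            evaluate_kde(a, None, h, grid),
            evaluate_kde(b, None, h, grid),
        )

    def test_identity_overlap_near_one(self, pair):
        fa, _ = pair
        assert niche_overlap(fa, fa) >= 0.98

    def test_symmetry_exact(self, pair):
        fa, fb = pair
        assert niche_overlap(fa, fb) == niche_overlap(fb, fa)

    def test_bounds(self, pair):
        fa, fb = pair
        assert 0.0 < niche_overlap(fa, fb) < 1.0

    def test_disjoint_supports_overlap_negligible(self):
        grid = Grid2D(-5, 35, -5, 5, 151)
        h = np.eye(2)
        fa = evaluate_kde(np.zeros((1, 2)), None, h, grid)
        fb = evaluate_kde(np.array([[30.0, 0.0]]), None, h, grid)
        assert niche_overlap(fa, fb) < 0.001

    def test_translation_invariance(self):
        rng = np.random.default_rng(11)
        a = rng.standard_normal((400, 2))
        b = rng.standard_normal((400, 2)) + np.array([1.0, 0.5])
        shift = np.array([5.3, -2.7])
        h = 0.1 * np.eye(2)
        g1 = make_common_grid(np.vstack([a, b]), resolution=101)
        g2 = make_common_grid(np.vstack([a + shift, b + shift]), resolution=101)
        o1 = niche_overlap(evaluate_kde(a, None, h, g1), evaluate_kde(b, None, h, g1))
        o2 = niche_overlap(
            evaluate_kde(a + shift, None, h, g2), evaluate_kde(b + shift, None, h, g2)
        )
        assert o1 == pytest.approx(o2, abs=1e-6)

    def test_weight_doubling_changes_nothing(self, rng):
        pts = rng.standard_normal((50, 2))
        w = rng.uniform(1, 5, 50)
        grid = make_common_grid(pts, resolution=64, padding_fraction=0.3)
        h = 0.2 * np.eye(2)
        d1 = evaluate_kde(pts, w, h, grid)
        d2 = evaluate_kde(pts, 2 * w, h, grid)
        np.testing.assert_allclose(d1.density, d2.density, atol=1e-15)
        assert niche_breadth(d1) == niche_breadth(d2)

    def test_mismatched_grids_rejected(self, pair):
        fa, _ = pair
        other = evaluate_kde(
            np.zeros((1, 2)), None, np.eye(2), Grid2D(-5, 5, -5, 5, 64)
        )
        with pytest.raises(ComparabilityError):
            niche_overlap(fa, other)

    def test_hdr_union_mode_not_larger_than_full(self, pair):
        fa, fb = pair
        assert niche_overlap(fa, fb, mode="hdr_union") <= niche_overlap(fa, fb)

    def test_resolution_robustness(self):
        rng = np.random.default_rng(12)
        a = rng.standard_normal((2000, 2))
        b = rng.standard_normal((2000, 2)) + np.array([2.0, 0.0])
        h = 0.15**2 * np.eye(2)
        vals = {}
        for res in (101, 201):
            g = make_common_grid(np.vstack([a, b]), resolution=res,
                                 padding_fraction=0.1)
            vals[res] = niche_overlap(
                evaluate_kde(a, None, h, g), evaluate_kde(b, None, h, g)
            )
        assert abs(vals[101] - vals[201]) < 0.01


class TestDiagnostics:
    def test_unimodal_single_fragment(self, rng):
        x = rng.standard_normal((300, 2))
        grid = make_common_grid(x, resolution=64, padding_fraction=0.2)
        diag = kde_diagnostics(evaluate_kde(x, None, 0.2 * np.eye(2), grid))
        assert diag["hdr_fragments"] == 1
        assert diag["boundary_mass_fraction"] < 0.01

    def test_separated_modes_fragment(self, rng):
        a = rng.standard_normal((200, 2)) * 0.3
        b = rng.standard_normal((200, 2)) * 0.3 + np.array([8.0, 0.0])
        x = np.vstack([a, b])
        grid = make_common_grid(x, resolution=101, padding_fraction=0.15)
        diag = kde_diagnostics(evaluate_kde(x, None, 0.05 * np.eye(2), grid))
        assert diag["hdr_fragments"] == 2
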