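"""Elevation-range residuals, wetland score, soil richness, and the
hierarchical heterogeneity combination."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from resilscape.heterogeneity import (
    HeterogeneityComponents,
    combine_heterogeneity,
    elev_range_residuals,
    soil_richness,
    wetland_components,
    wetland_score,
)
from resilscape.raster_core import NeighborhoodSpec, focal_apply_bruteforce
from tests.conftest import make_grid


def _components(z_lv, z_er, z_ws, z_sr):
    return HeterogeneityComponents(
        z_landform_variety=make_grid(z_lv),
        z_elev_range_resid=make_grid(z_er),
        z_wetland_score=make_grid(z_ws),
        z_soil_richness=make_grid(z_sr),
    )


class TestElevRangeResiduals:
    def test_constant_dem_zero_residuals(self):
        dem = make_grid(np.full((10, 10), 500.0))
        variety = make_grid(np.ones((10, 10)))
        resid, fit = elev_range_residuals(dem, variety)
        np.testing.assert_allclose(resid.values, 0.0, atol=1e-12)
        assert fit.degenerate  # constant variety: slope undefined

    def test_perfectly_linear_range_gives_zero_residuals(self, rng):
        # construct DEM-free: feed a synthetic "range" via a one-cell window trick
        variety_vals = rng.integers(1, 5, size=(12, 12)).astype(float)
        dem_vals = np.zeros((12, 12))
        dem = make_grid(dem_vals)
        variety = make_grid(variety_vals)
        resid, fit = elev_range_residuals(dem, variety)
        # flat DEM: range 0 everywhere; the fit through (v, 0) has slope 0
        np.testing.assert_allclose(resid.values, 0.0, atol=1e-12)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_residuals_match_hand_ols_on_toy_pairs(self):
        """Toy pairs (variety, range) = (1,0),(2,5),(2,7),(3,9),(4,15).

        Realized as five isolated two-cell blocks on a 1x14 grid (a
        radius-1 window inside a block sees exactly {0, y}, so its range
        is y at both cells); duplicating every pair leaves the OLS fit
        unchanged, so the closed-form residuals of the five pairs apply.
        """
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0])
        y = np.array([0.0, 5.0, 7.0, 9.0, 15.0])
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        intercept = y.mean() - slope * x.mean()
        expected = y - (slope * x + intercept)

        dem_vals = np.zeros((1, 14))
        var_vals = np.zeros((1, 14))
        mask = np.zeros((1, 14), dtype=bool)
        for k in range(5):
            p = 3 * k  # blocks at cells (p, p+1), nodata gap at p+2
            dem_vals[0, p + 1] = y[k]
            var_vals[0, p : p + 2] = x[k]
            if p + 2 < 14:
                mask[0, p + 2] = True
        dem = make_grid(dem_vals, mask=mask)
        variety = make_grid(var_vals, mask=mask)
        resid, fit = elev_range_residuals(dem, variety, NeighborhoodSpec(radius_px=1))
        assert fit.n == 10
        np.testing.assert_allclose([fit.slope, fit.intercept], [slope, intercept])
        got = resid.values[0, [3 * k for k in range(5)]]
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_residual_invariants(self, rng):
        dem = make_grid(rng.normal(300.0, 60.0, size=(20, 20)))
        variety = make_grid(rng.integers(1, 6, size=(20, 20)).astype(float))
        resid, fit = elev_range_residuals(dem, variety)
        assert not fit.degenerate
        r = resid.values[resid.valid]
        v = variety.values[resid.valid]
        assert abs(r.mean()) < 1e-8 * max(1.0, abs(r).max())
        assert abs(np.corrcoef(r, v)[0, 1]) < 1e-8


class TestWetlandComponents:
    def test_no_wetlands_all_zero(self):
        w = make_grid(np.zeros((20, 20)))
        ld, rd, patch = wetland_components(w)
        for layer in (ld, rd, patch):
            assert np.all(layer.values[layer.valid] == 0.0)

    def test_all_wetlands_density_one_single_patch(self):
        w = make_grid(np.ones((20, 20)))
        ld, rd, patch = wetland_components(w)
        np.testing.assert_allclose(ld.values, 1.0)
        np.testing.assert_allclose(rd.values, 1.0)
        assert np.all(patch.values == 1)

    def test_two_patches_counted_from_center(self):
        vals = np.zeros((30, 30))
        vals[14:16, 5:7] = 1.0  # patch A
        vals[14:16, 17:19] = 1.0  # patch B, 10 cells away
        w = make_grid(vals)
        ld, rd, patch = wetland_components(
            w, NeighborhoodSpec(radius_px=5), NeighborhoodSpec(radius_px=13)
        )
        center = (15, 11)
        assert patch.values[center] == 2  # regional window spans both
        # densities equal the window counts (oracle loop)
        slow = focal_apply_bruteforce(w, NeighborhoodSpec(radius_px=5), "mean")
        np.testing.assert_allclose(ld.values, slow.values, atol=1e-9)

    def test_non_binary_layer_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            wetland_components(make_grid(np.full((10, 10), 0.5)))

    def test_diagonal_cells_are_one_patch(self):
        vals = np.zeros((10, 10))
        vals[2, 2] = vals[3, 3] = 1.0  # 8-connected
        _, _, patch = wetland_components(make_grid(vals))
        assert patch.values[2, 2] == 1


class TestWetlandScore:
    @pytest.mark.parametrize(
        "ld, rd, pt, expected",
        [
            (0.5, 0.5, 0.2, 0.5),  # no patchiness upgrade: plain average
            (0.4, 0.2, 0.8, (2 * 0.4 + 0.2 + 0.8) / 4),  # upgrade fires (0.45 > 0.3)
            (1.0, 1.0, 1.0, 1.0),  # both branches agree
            (0.0, 0.0, 0.0, 0.0),
        ],
    )
    def test_score_formula(self, ld, rd, pt, expected):
        shape = (6, 6)
        # patchiness grid scaled so its max rescales to pt exactly
        patch_vals = np.zeros(shape)
        patch_vals[0, 0] = 1.0  # extent max 1 -> rescale is identity
        patch_vals[3, 3] = pt
        score = wetland_score(
            make_grid(np.full(shape, ld)),
            make_grid(np.full(shape, rd)),
            make_grid(patch_vals),
        )
        assert score.values[3, 3] == pytest.approx(expected)

    def test_all_zero_patchiness_defined(self):
        z = make_grid(np.zeros((5, 5)))
        score = wetland_score(
            make_grid(np.full((5, 5), 0.3)), make_grid(np.full((5, 5), 0.1)), z
        )
        np.testing.assert_allclose(score.values, 0.2)

    def test_bounded_in_unit_interval(self, rng):
        ld = make_grid(rng.random((15, 15)))
        rd = make_grid(rng.random((15, 15)))
        pt = make_grid(rng.integers(0, 9, size=(15, 15)).astype(float))
        s = wetland_score(ld, rd, pt).values
        assert np.all(s >= 0.0) and np.all(s <= 1.0)

    @settings(max_examples=200, deadline=None)
    @given(
        ld=st.floats(0, 1), rd=st.floats(0, 1), pt=st.floats(0, 1),
        bump=st.floats(0, 0.5), which=st.integers(0, 2),
    )
    def test_monotone_nondecreasing_in_each_input(self, ld, rd, pt, bump, which):
        def score(l, r, p):
            shape = (3, 3)
            pv = np.zeros(shape)
            pv[0, 0] = 1.0
            pv[1, 1] = p
            return wetland_score(
                make_grid(np.full(shape, l)),
                make_grid(np.full(shape, r)),
                make_grid(pv),
            ).values[1, 1]

        args = [ld, rd, pt]
        before = score(*args)
        args[which] = min(1.0, args[which] + bump)
        after = score(*args)
        assert after >= before - 1e-12


class TestSoilRichness:
    def test_single_type_is_one(self):
        out = soil_richness(make_grid(np.full((12, 12), 3.0)))
        assert np.all(out.values == 1)

    def test_mosaic_matches_oracle(self, rng):
        vals = rng.integers(1, 4, size=(18, 18)).astype(float)
        g = make_grid(vals)
        spec = NeighborhoodSpec(radius_px=5)
        fast = soil_richness(g, spec)
        slow = focal_apply_bruteforce(g, spec, "count_distinct")
        assert np.array_equal(fast.values, slow.values)

    def test_isolated_valid_cell_keeps_value_and_hole_stays_nodata(self):
        vals = np.full((9, 9), 2.0)
        mask = np.zeros((9, 9), dtype=bool)
        mask[4, 4] = True
        out = soil_richness(make_grid(vals, mask=mask), NeighborhoodSpec(radius_px=1))
        assert out.nodata_mask[4, 4]
        assert out.values[0, 0] == 1


class TestCombineHeterogeneity:
    def test_no_update_when_candidates_below_aggregate(self):
        h = combine_heterogeneity(
            _components(
                np.full((4, 4), 2.0), np.full((4, 4), 1.0),
                np.full((4, 4), 0.0), np.full((4, 4), -1.0),
            )
        )
        np.testing.assert_allclose(h.values, 2.0)

    def test_single_update_double_weighted(self):
        # z_lv = 0, z_er = 3 -> (2*0 + 3)/3 = 1
        h = combine_heterogeneity(
            _components(
                np.zeros((4, 4)), np.full((4, 4), 3.0),
                np.full((4, 4), -5.0), np.full((4, 4), -5.0),
            )
        )
        np.testing.assert_allclose(h.values, 1.0, atol=1e-12)

    def test_chained_updates(self):
        # z_lv=0, z_er=3 -> 1; then z_ws=4 -> (2*1+4)/3 = 2; z_sr<=1 no-op
        h = combine_heterogeneity(
            _components(
                np.zeros((4, 4)), np.full((4, 4), 3.0),
                np.full((4, 4), 4.0), np.full((4, 4), 1.0),
            )
        )
        np.testing.assert_allclose(h.values, 2.0, atol=1e-12)

    def test_result_never_below_landform_variety(self, rng):
        for _ in range(20):
            z = [rng.normal(size=(10, 10)) for _ in range(4)]
            h = combine_heterogeneity(_components(*z))
            assert np.all(h.values >= z[0] - 1e-12)

    def test_update_order_is_fixed(self):
        """Swapping the wetland and soil layers changes the output, pinning
        the elevation -> wetland -> soil evaluation order."""
        z_lv = np.zeros((4, 4))
        z_er = np.full((4, 4), -1.0)
        a = np.full((4, 4), 3.0)
        b = np.full((4, 4), 1.5)
        h_ab = combine_heterogeneity(_components(z_lv, z_er, a, b)).values
        h_ba = combine_heterogeneity(_components(z_lv, z_er, b, a)).values
        # a then b: (0->1) then b=1.5>1 -> (2+1.5)/3; b then a: (0->0.5) then (1+3)/3
        np.testing.assert_allclose(h_ab, (2 * 1.0 + 1.5) / 3)
        np.testing.assert_allclose(h_ba, (2 * 0.5 + 3.0) / 3)
        assert not np.allclose(h_ab, h_ba)
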