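"""Quartile breaks, bivariate classification, water masking, and zonal
percent-area accounting."""

import numpy as np
import pandas as pd
import pytest

from resilscape.resilience import (
    QUADRANTS,
    QuartileBreaks,
    bivariate_classify,
    mask_water,
    quadrant_of,
    quartile_breaks,
    round_percentages,
    zonal_summary,
)
from tests.conftest import make_grid


class TestQuartileBreaks:
    def test_values_1_to_16_linear_interpolation(self):
        g = make_grid(np.arange(1.0, 17.0).reshape(4, 4))
        b = quartile_breaks(g)
        assert (b.q25, b.q50, b.q75) == (4.75, 8.5, 12.25)

    def test_constant_grid_collapsed_breaks(self):
        b = quartile_breaks(make_grid(np.full((4, 4), 2.5)))
        assert b.q25 == b.q50 == b.q75 == 2.5

    def test_symmetric_distribution_median_equals_mean(self, rng):
        vals = rng.normal(size=(50, 50))
        vals = np.concatenate([vals, -vals]).reshape(100, 50) + 7.0
        b = quartile_breaks(make_grid(vals))
        assert b.q50 == pytest.approx(7.0, abs=1e-9)

    def test_too_few_valid_cells_rejected(self):
        g = make_grid([[1.0, 2.0], [np.nan, np.nan]])
        with pytest.raises(ValueError, match=">= 4"):
            quartile_breaks(g)

    def test_unordered_breaks_rejected(self):
        with pytest.raises(ValueError, match="ordered"):
            QuartileBreaks(2.0, 1.0, 3.0)


class TestQuadrants:
    def test_partition_of_all_16_codes(self):
        all_codes = sorted(c for codes in QUADRANTS.values() for c in codes)
        assert all_codes == [10 * i + j for i in range(1, 5) for j in range(1, 5)]
        assert QUADRANTS["Q1"] == (11, 12, 21, 22)
        assert QUADRANTS["Q2"] == (13, 14, 23, 24)
        assert QUADRANTS["Q3"] == (31, 32, 41, 42)
        assert QUADRANTS["Q4"] == (33, 34, 43, 44)

    def test_quadrant_lookup(self):
        assert quadrant_of(23) == "Q2"
        assert quadrant_of(42) == "Q3"
        with pytest.raises(ValueError):
            quadrant_of(45)


class TestBivariateClassify:
    def test_minimum_corner_is_code_11(self):
        het = make_grid(np.arange(16.0).reshape(4, 4))
        conn = make_grid(np.arange(16.0).reshape(4, 4).T)
        out = bivariate_classify(het, conn)
        assert out.values[0, 0] == 11

    def test_all_16_codes_appear_on_exhaustive_pair(self):
        # 4x4 layer pair covering every quartile combination
        het = make_grid(np.tile(np.arange(16.0).reshape(4, 4), (1, 1)))
        conn = make_grid(het.values.T.copy())
        out = bivariate_classify(het, conn)
        assert set(np.unique(out.values).astype(int)) == set(
            c for codes in QUADRANTS.values() for c in codes
        )

    def test_first_digit_is_connectedness_second_heterogeneity(self):
        het = make_grid(np.array([[0.0, 10.0], [0.0, 10.0]]))
        conn = make_grid(np.array([[0.0, 0.0], [10.0, 10.0]]))
        hb = QuartileBreaks(2.0, 5.0, 8.0)
        cb = QuartileBreaks(2.0, 5.0, 8.0)
        out = bivariate_classify(het, conn, hb, cb)
        assert out.values[0, 0] == 11  # low conn, low het
        assert out.values[0, 1] == 14  # low conn, high het
        assert out.values[1, 0] == 41  # high conn, low het
        assert out.values[1, 1] == 44

    def test_upper_edge_inclusive(self):
        hb = QuartileBreaks(1.0, 2.0, 3.0)
        assert list(hb.bin(np.array([1.0, 1.0000001, 2.0, 3.0, 3.1]))) == [1, 2, 2, 3, 4]

    def test_continuous_layers_balanced_bins(self):
        rng = np.random.default_rng(3)
        n = 10_000
        het = make_grid(rng.normal(size=(100, 100)))
        conn = make_grid(rng.random((100, 100)))
        out = bivariate_classify(het, conn)
        het_bins = quartile_breaks(het).bin(het.values)
        conn_bins = quartile_breaks(conn).bin(conn.values)
        for bins in (het_bins, conn_bins):
            counts = np.bincount(bins.ravel(), minlength=5)[1:]
            assert np.all(np.abs(counts - n / 4) <= 1)
        # digits of the class map agree with the marginal bins
        assert np.array_equal(out.values.astype(int) // 10, conn_bins)
        assert np.array_equal(out.values.astype(int) % 10, het_bins)

    def test_invariant_under_strictly_increasing_transform(self, rng):
        het = make_grid(rng.normal(size=(30, 30)))
        conn = make_grid(rng.random((30, 30)) + 1.0)
        base = bivariate_classify(het, conn)
        het2 = make_grid(np.exp(het.values))
        conn2 = make_grid(conn.values**3)
        out = bivariate_classify(het2, conn2)
        assert np.array_equal(base.values, out.values)

    def test_nodata_in_either_layer_propagates(self):
        het_vals = np.arange(16.0).reshape(4, 4)
        mask = np.zeros((4, 4), dtype=bool)
        mask[2, 2] = True
        het = make_grid(het_vals, mask=mask)
        conn = make_grid(het_vals.T.copy())
        out = bivariate_classify(het, conn)
        assert out.nodata_mask[2, 2] and out.valid.sum() == 15


class TestMaskWater:
    def test_water_everywhere_all_nodata(self):
        classes = make_grid(np.full((5, 5), 22.0))
        water = make_grid(np.ones((5, 5)))
        out = mask_water(classes, water)
        assert out.nodata_mask.all()

    def test_no_water_identity(self):
        classes = make_grid(np.full((5, 5), 22.0))
        out = mask_water(classes, make_grid(np.zeros((5, 5))))
        assert np.array_equal(out.values, classes.values)

    def test_river_strip_masked_exactly(self):
        classes = make_grid(np.full((8, 8), 33.0))
        water_vals = np.zeros((8, 8))
        water_vals[:, 3] = 1.0
        out = mask_water(classes, make_grid(water_vals))
        assert out.nodata_mask[:, 3].all()
        assert out.valid[:, [0, 1, 2, 4, 5, 6, 7]].all()


class TestRoundPercentages:
    def test_sums_hit_total_exactly(self, rng):
        for _ in range(50):
            raw = rng.random(rng.integers(2, 9))
            raw = 100.0 * raw / raw.sum()
            out = round_percentages(raw)
            assert round(out.sum(), 10) == 100.0
            assert np.all(np.abs(out - raw) < 0.1 + 1e-9)


class TestZonalSummary:
    def _classes(self, codes):
        return make_grid(np.asarray(codes, dtype=float))

    def test_quadrant_percents_from_counts(self):
        codes = np.concatenate(
            [np.full(25, 11.0), np.full(25, 22.0), np.full(25, 33.0), np.full(25, 44.0)]
        ).reshape(10, 10)
        classes = self._classes(codes)
        zones = make_grid(np.ones((10, 10)))
        df = zonal_summary(classes, zones)
        quad = df[df.level == "quadrant"].set_index("code")
        assert quad.loc["Q1", "pct_within"] == 50.0  # 11, 22
        assert quad.loc["Q4", "pct_within"] == 50.0  # 33, 44
        assert quad.loc["Q2", "pct_within"] == 0.0

    def test_within_zone_quadrant_percents_sum_to_100(self, rng):
        codes = rng.choice([11, 13, 24, 31, 42, 44], size=(20, 20)).astype(float)
        zones = make_grid((rng.random((20, 20)) > 0.5) + 1.0)
        df = zonal_summary(self._classes(codes), zones)
        for _, zdf in df[df.level == "quadrant"].groupby("zone"):
            assert zdf.pct_within.sum() == pytest.approx(100.0, abs=1e-9)

    def test_two_equal_zones_split_across_extent(self):
        codes = np.full((10, 10), 44.0)
        zones_vals = np.ones((10, 10))
        zones_vals[:, 5:] = 2.0
        df = zonal_summary(self._classes(codes), make_grid(zones_vals))
        quad = df[(df.level == "quadrant")].groupby("zone").pct_across.sum()
        assert quad.loc[1] == pytest.approx(50.0)
        assert quad.loc[2] == pytest.approx(50.0)

    def test_across_extent_sums_to_100_per_level(self, rng):
        codes = rng.choice([11, 12, 23, 34, 41, 44], size=(15, 15)).astype(float)
        zones = make_grid(rng.integers(1, 4, size=(15, 15)).astype(float))
        df = zonal_summary(self._classes(codes), zones)
        for level in ("class", "quadrant"):
            assert df[df.level == level].pct_across.sum() == pytest.approx(100.0)

    def test_masked_cells_appear_in_no_row(self):
        codes = np.full((6, 6), 33.0)
        mask = np.zeros((6, 6), dtype=bool)
        mask[:, 0] = True  # e.g. water-masked column
        classes = make_grid(codes, mask=mask)
        zones = make_grid(np.ones((6, 6)))
        df = zonal_summary(classes, zones)
        assert df["count"].loc[df.level == "class"].sum() == 30

    def test_zone_without_valid_cells_flagged_undefined(self):
        codes = np.full((4, 4), 22.0)
        mask = np.zeros((4, 4), dtype=bool)
        mask[:, 2:] = True
        classes = make_grid(codes, mask=mask)
        zones_vals = np.ones((4, 4))
        zones_vals[:, 2:] = 2.0
        df = zonal_summary(classes, make_grid(zones_vals))
        z2 = df[(df.zone == 2) & (df.level == "quadrant")]
        assert (z2["count"] == 0).all()
        assert z2.pct_within.isna().all()
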