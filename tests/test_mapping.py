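"""Natural breaks, classification, masking, change maps, and area accounting."""

import numpy as np
import pytest

import pestcast as pc
from pestcast.engine import EIGrid
from pestcast.mapping import (
    CLASS_NAMES,
    apply_mask,
    area_report,
    area_report_from_totals,
    cell_area,
    classify,
    difference_map,
    grid_cell_areas,
    host_mask,
    jenks_breaks,
    percent_change,
)
from oracles import dp_sse, exhaustive_jenks

EARTH_AREA_KM2 = 4 * np.pi * 6371.0**2


class TestJenks:
    def test_two_cluster_split(self):
        breaks = jenks_breaks([1, 2, 3, 10, 11, 12], k=2)
        assert breaks.tolist() == [10.0]

    def test_each_distinct_value_own_class(self):
        breaks = jenks_breaks([5.0, 1.0, 9.0, 3.0], k=4)
        assert breaks.tolist() == [3.0, 5.0, 9.0]

    @pytest.mark.parametrize("n,k,seed", [(12, 3, 0), (15, 4, 1), (20, 5, 2), (25, 4, 3)])
    def test_matches_exhaustive_partition_oracle(self, n, k, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0, 100, n)
        breaks = jenks_breaks(values, k=k)
        opt_sse, opt_breaks = exhaustive_jenks(values, k)
        assert dp_sse(values, breaks) == pytest.approx(opt_sse, abs=1e-9)
        assert tuple(breaks) == pytest.approx(opt_breaks)

    def test_subsampled_large_input_matches_oracle_on_subsample(self):
        rng = np.random.default_rng(4)
        values = rng.uniform(0, 1, 1000)
        breaks = jenks_breaks(values, k=5, max_n=50)
        x = np.sort(values)
        sub = x[np.linspace(0, 999, 50).round().astype(int)]
        opt_sse, _ = exhaustive_jenks(sub, 5)
        assert dp_sse(sub, breaks) == pytest.approx(opt_sse, abs=1e-9)

    def test_too_few_distinct_values(self):
        with pytest.raises(ValueError):
            jenks_breaks([1.0, 1.0, 2.0], k=3)


class TestClassify:
    def test_half_open_boundary_convention(self):
        breaks = [0.2, 0.4, 0.6, 0.8]
        vals = np.array([[0.1, 0.2, 0.39, 0.8, np.nan]])
        cr = classify(vals, breaks, lat_axis=[0.0], lon_axis=[0, 1, 2, 3, 4])
        assert cr.codes[0, :4].tolist() == [0, 1, 1, 4]
        assert cr.codes[0, 4] == -1  # nodata

    def test_class_histogram_hand_tally(self):
        vals = np.array([[0.05, 0.25, 0.45, 0.65, 0.85, 0.15, 0.95, 0.55]])
        cr = classify(vals, [0.2, 0.4, 0.6, 0.8], lat_axis=[0.0], lon_axis=list(range(8)))
        hist = np.bincount(cr.codes[cr.codes >= 0], minlength=5)
        assert hist.tolist() == [2, 1, 2, 1, 2]
        assert len(CLASS_NAMES) == 5

    def test_unordered_breaks_rejected(self):
        with pytest.raises(ValueError):
            classify(np.zeros((1, 1)), [0.5, 0.2, 0.7, 0.9], lat_axis=[0.0], lon_axis=[0.0])


class TestMasking:
    def _ei(self, values):
        arr = np.asarray(values, dtype=float)
        return EIGrid(
            lat_axis=np.arange(arr.shape[0], dtype=float),
            lon_axis=np.arange(arr.shape[1], dtype=float),
            ei=arr,
            valid=np.isfinite(arr),
        )

    def test_host_mask_strict_positivity(self):
        mask = host_mask(self._ei([[0.0, 0.001, 50.0, np.nan]]))
        assert mask[0, 0] == 0.0
        assert mask[0, 1] == 1.0
        assert mask[0, 2] == 1.0
        assert np.isnan(mask[0, 3])

    def test_apply_mask_identity_and_empty(self):
        suit = np.array([[0.3, 0.7], [0.9, 0.1]])
        np.testing.assert_array_equal(apply_mask(suit, np.ones((2, 2))), suit)
        assert np.all(apply_mask(suit, np.zeros((2, 2))) == 0.0)

    def test_checkerboard_mask_cellwise(self):
        rng = np.random.default_rng(5)
        suit = rng.random((6, 6))
        mask = np.indices((6, 6)).sum(axis=0) % 2
        out = apply_mask(suit, mask.astype(float))
        np.testing.assert_array_equal(out[mask == 1], suit[mask == 1])
        assert np.all(out[mask == 0] == 0.0)
        assert np.all(out <= suit)  # masking never increases suitability

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            apply_mask(np.zeros((2, 2)), np.zeros((3, 3)))


class TestDifferenceMap:
    def _classified(self, codes):
        codes = np.asarray(codes, dtype=int)
        return pc.ClassifiedRaster(
            lat_axis=np.arange(codes.shape[0], dtype=float),
            lon_axis=np.arange(codes.shape[1], dtype=float),
            codes=codes,
            breaks=np.array([1.0, 2.0, 3.0, 4.0]),
        )

    def test_identical_rasters_give_zero(self):
        cr = self._classified([[0, 2], [4, 1]])
        assert np.all(difference_map(cr, cr) == 0)

    def test_ordinal_extremes(self):
        cur = self._classified([[0]])
        fut = self._classified([[4]])
        assert difference_map(cur, fut)[0, 0] == 4
        assert difference_map(fut, cur)[0, 0] == -4

    def test_histogram_hand_tally(self):
        cur = self._classified([[0, 1, 2, 3]])
        fut = self._classified([[1, 1, 4, 1]])
        diff = difference_map(cur, fut)
        assert diff.tolist() == [[1, 0, 2, -2]]


class TestAreas:
    def test_global_one_degree_grid_sums_to_sphere(self):
        lat = np.arange(-89.5, 90.0, 1.0)
        lon = np.arange(-179.5, 180.0, 1.0)
        total = grid_cell_areas(lat, lon).sum()
        assert total == pytest.approx(EARTH_AREA_KM2, rel=1e-3)

    def test_degenerate_and_latitude_scaling(self):
        assert cell_area(45.0, 1.0, 0.0) == 0.0
        eq = cell_area(0.0, 0.5, 0.5)
        mid = cell_area(60.0, 0.5, 0.5)
        assert mid / eq == pytest.approx(0.5, abs=0.01)  # cos(60 deg)

    def test_percent_change_reciprocal_property(self):
        p1 = percent_change(590.59, 748.19)
        p2 = percent_change(748.19, 590.59)
        assert (1 + p1 / 100) * (1 + p2 / 100) == pytest.approx(1.0)

    def test_published_area_pairs_reproduce_printed_changes(self):
        pairs = {
            "South America": (590.59, 748.19),
            "Asia": (427.26, 531.14),
            "North America": (725.40, 770.38),
            "Europe": (646.95, 558.83),
            "Africa": (650.85, 577.58),
        }
        df = area_report_from_totals(pairs).set_index("region")
        assert df.loc["South America", "percent_change"] == 26.7
        assert df.loc["Asia", "percent_change"] == 24.3
        assert df.loc["North America", "percent_change"] == 6.2
        assert df.loc["Europe", "percent_change"] == -13.6
        assert df.loc["Africa", "percent_change"] == -11.3
        glob = area_report_from_totals({"global": (8616.0, 10165.0)}, decimals=2)
        assert glob["percent_change"].iloc[0] == 17.98

    def test_region_class_reconciliation(self):
        rng = np.random.default_rng(6)
        lat = np.arange(-44.0, 45.0, 2.0)
        lon = np.arange(-89.0, 90.0, 2.0)
        codes_c = rng.integers(0, 5, (lat.size, lon.size))
        codes_f = rng.integers(0, 5, (lat.size, lon.size))
        cur = pc.ClassifiedRaster(lat, lon, codes_c, np.array([1, 2, 3, 4.0]))
        fut = pc.ClassifiedRaster(lat, lon, codes_f, np.array([1, 2, 3, 4.0]))
        half = lon.size // 2
        masks = {
            "west": np.repeat([np.r_[np.ones(half), np.zeros(lon.size - half)]], lat.size, axis=0).astype(bool),
        }
        masks["east"] = ~masks["west"]
        report = area_report(cur, fut, masks)
        per_class = report.per_class
        totals = report.totals.set_index("region")
        for region in ("west", "east"):
            sub = per_class[per_class["region"] == region]
            suitable = sub[sub["class"] != "unsuitable"]["area_current"].sum()
            assert totals.loc[region, "suitable_current"] == pytest.approx(suitable)
        # disjoint regions reconcile to the global row
        assert totals.loc["global", "suitable_current"] == pytest.approx(
            totals.loc["west", "suitable_current"] + totals.loc["east", "suitable_current"]
        )
        # every cell is in some region and some class: full-area conservation
        all_area = grid_cell_areas(lat, lon).sum() / 1e4
        assert per_class["area_current"].sum() == pytest.approx(all_area)

    def test_overlapping_regions_rejected(self):
        lat = np.array([0.0, 2.0])
        lon = np.array([0.0, 2.0])
        cr = pc.ClassifiedRaster(lat, lon, np.ones((2, 2), int), np.array([1, 2, 3, 4.0]))
        masks = {"a": np.ones((2, 2), bool), "b": np.ones((2, 2), bool)}
        with pytest.raises(ValueError, match="overlap"):
            area_report(cr, cr, masks)
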