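import itertools

import numpy as np
import pytest

from covermap.errors import GridError
from covermap.grids import INT_NODATA
from covermap.landcover import ReclassMap, reclassify
from covermap.sequences import (
    COVER_LEGEND,
    combine,
    enumerate_patterns,
    rotation_report,
    tidy_tables,
)

PIXEL_ACRES = 0.22239


def brute_force_crosstab(rasters):
    """Independent oracle: nested per-pixel tally with Python loops."""
    counts = {}
    shape = rasters[0].shape
    for idx in itertools.product(*(range(s) for s in shape)):
        combo = tuple(int(r[idx]) for r in rasters)
        if INT_NODATA in combo:
            continue
        counts[combo] = counts.get(combo, 0) + 1
    return counts


def random_layers(rng, shape, n_layers, n_values, nodata_p=0.1):
    layers = []
    for _ in range(n_layers):
        layer = rng.integers(0, n_values, size=shape).astype(np.int32)
        layer[rng.random(shape) < nodata_p] = INT_NODATA
        layers.append(layer)
    return layers


class TestEnumeratePatterns:
    def test_two_way_seven_classes(self):
        assert enumerate_patterns(7, 2) == 14

    def test_three_way_seven_classes(self):
        assert enumerate_patterns(7, 2, 7) == 98

    def test_full_legend(self):
        assert enumerate_patterns(133, 2, 133) == 35_378

    def test_counts_must_be_positive(self):
        with pytest.raises(ValueError):
            enumerate_patterns(0, 2)


class TestCombine:
    def test_two_constant_rasters_single_pattern(self):
        a = np.full((5, 5), 2, dtype=np.int32)
        b = np.zeros((5, 5), dtype=np.int32)
        _, table = combine([a, b], [("A", "B", "C"), COVER_LEGEND], PIXEL_ACRES)
        assert len(table.table) == 1
        assert table.table["pixels"].iloc[0] == 25
        assert table.table["label"].iloc[0] == "C – None"

    def test_all_combos_present_gives_14_rows(self, rng):
        crop = rng.integers(0, 7, size=(40, 40)).astype(np.int32)
        cover = rng.integers(0, 2, size=(40, 40)).astype(np.int32)
        legend = tuple(ReclassMap().legend)
        _, table = combine([crop, cover], [legend, COVER_LEGEND], PIXEL_ACRES)
        assert len(table.table) == 14

    def test_arity_errors(self):
        a = np.zeros((2, 2), dtype=np.int32)
        with pytest.raises(ValueError):
            combine([a], [("x",)], PIXEL_ACRES)
        with pytest.raises(ValueError):
            combine([a] * 4, [("x",)] * 4, PIXEL_ACRES)

    def test_grid_mismatch(self):
        with pytest.raises(GridError):
            combine([np.zeros((2, 2), dtype=np.int32),
                     np.zeros((3, 3), dtype=np.int32)],
                    [("x",), ("x",)], PIXEL_ACRES)

    @pytest.mark.parametrize("n_layers", [2, 3])
    def test_matches_brute_force(self, rng, n_layers):
        for _ in range(20):
            layers = random_layers(rng, (15, 15), n_layers, 4)
            legends = [tuple("abcd")] * n_layers
            _, table = combine(layers, legends, PIXEL_ACRES)
            oracle = brute_force_crosstab(layers)
            got = {tuple("abcd".index(e) for e in row["elements"]): row["pixels"]
                   for _, row in table.table.iterrows()}
            assert got == oracle

    def test_area_conservation(self, rng):
        layers = random_layers(rng, (30, 30), 3, 5)
        _, table = combine(layers, [tuple("abcde")] * 3, PIXEL_ACRES)
        valid = np.ones((30, 30), dtype=bool)
        for layer in layers:
            valid &= layer != INT_NODATA
        assert table.table["pixels"].sum() == valid.sum()
        assert table.table["acres"].sum() == pytest.approx(table.total_acres)
        assert table.table["pct"].sum() == pytest.approx(100.0)

    def test_permutation_consistency(self, rng):
        layers = random_layers(rng, (20, 20), 3, 3)
        legends = [tuple("xyz")] * 3
        _, fwd = combine(layers, legends, PIXEL_ACRES)
        _, rev = combine(layers[::-1], legends, PIXEL_ACRES)
        fwd_counts = {row["elements"]: row["pixels"]
                      for _, row in fwd.table.iterrows()}
        rev_counts = {row["elements"][::-1]: row["pixels"]
                      for _, row in rev.table.iterrows()}
        assert fwd_counts == rev_counts

    def test_marginalizing_three_way_gives_two_way(self, rng):
        layers = random_layers(rng, (25, 25), 3, 4, nodata_p=0.0)
        legends = [tuple("abcd")] * 3
        _, three = combine(layers, legends, PIXEL_ACRES)
        _, two = combine(layers[:2], legends[:2], PIXEL_ACRES)
        marginal = {}
        for _, row in three.table.iterrows():
            key = row["elements"][:2]
            marginal[key] = marginal.get(key, 0) + row["pixels"]
        two_counts = {row["elements"]: row["pixels"]
                      for _, row in two.table.iterrows()}
        assert marginal == two_counts

    def test_sorted_by_acres_with_lexicographic_ties(self, rng):
        a = np.array([[0, 1], [2, 3]], dtype=np.int32)
        b = np.zeros((2, 2), dtype=np.int32)
        _, table = combine([a, b], [tuple("dcba"), COVER_LEGEND], PIXEL_ACRES)
        # All four patterns have one pixel; order must be label-lexicographic.
        labels = list(table.table["label"])
        assert labels == sorted(labels)

    def test_pattern_raster_maps_to_table_rows(self, rng):
        layers = random_layers(rng, (10, 10), 2, 3)
        raster, table = combine(layers, [tuple("pqr")] * 2, PIXEL_ACRES)
        for _, row in table.table.iterrows():
            assert (raster == row["pattern_id"]).sum() == row["pixels"]
        assert np.all((raster == INT_NODATA) | (raster >= 0))


class TestRotationReport:
    def _dominant_scene(self):
        """Soybean always follows soybean, always cover-cropped."""
        shape = (10, 10)
        crop = np.full(shape, 5, dtype=np.int32)  # soybean code
        crops = {2013: reclassify(crop, ReclassMap(), 2013),
                 2014: reclassify(crop, ReclassMap(), 2014)}
        cover = {2013: np.ones(shape, dtype=np.int32),
                 2014: np.ones(shape, dtype=np.int32)}
        return crops, cover

    def test_constructed_dominance(self):
        crops, cover = self._dominant_scene()
        report = rotation_report([2013, 2014], crops, cover, PIXEL_ACRES)
        top = report["crop_cc_crop"][2013].table.iloc[0]
        assert top["label"] == "Soybean – CC – Soybean"
        assert top["pct"] == pytest.approx(100.0)

    def test_top_k_all_equals_full_table(self, rng):
        crops, cover = self._dominant_scene()
        full = rotation_report([2013, 2014], crops, cover, PIXEL_ACRES)
        tbl = full["crop_cc"][2013]
        assert tbl.top(None).equals(tbl.table)
        assert tbl.top(100).equals(tbl.table)

    def test_missing_next_year_truncates(self, caplog):
        crops, cover = self._dominant_scene()
        del crops[2014]
        report = rotation_report([2013], crops, cover, PIXEL_ACRES)
        assert 2013 in report["crop_cc"]
        assert 2013 not in report["cc_crop"]
        assert 2013 not in report["crop_cc_crop"]

    def test_manual_tally_on_fixture(self):
        # 10x10 fixture with hand-computable shares: left half corn (code 1),
        # right half soybean (code 5); top half cover-cropped.
        crop = np.full((10, 10), 1, dtype=np.int32)
        crop[:, 5:] = 5
        cover = np.zeros((10, 10), dtype=np.int32)
        cover[:5, :] = 1
        cls = reclassify(crop, ReclassMap())
        _, table = combine([cls.grid, cover], [cls.legend, COVER_LEGEND],
                           PIXEL_ACRES)
        shares = {row["label"]: row["pct"] for _, row in table.table.iterrows()}
        assert shares == {
            "Corn – CC": pytest.approx(25.0),
            "Corn – None": pytest.approx(25.0),
            "Soybean – CC": pytest.approx(25.0),
            "Soybean – None": pytest.approx(25.0),
        }

    def test_tidy_stacking(self):
        crops, cover = self._dominant_scene()
        report = rotation_report([2013, 2014], crops, cover, PIXEL_ACRES)
        tidy = tidy_tables(report["crop_cc"])
        assert set(tidy["year"]) == {2013, 2014}
        assert set(tidy.columns) == {"year", "label", "pixels", "acres", "pct"}

    def test_suppression_keeps_denominator(self, rng):
        layers = random_layers(rng, (20, 20), 2, 5)
        _, table = combine(layers, [tuple("abcde")] * 2, PIXEL_ACRES)
        cut = table.table["acres"].median()
        suppressed = table.suppress(cut)
        assert suppressed.total_acres == table.total_acres
        assert len(suppressed.table) <= len(table.table)
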