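"""Densities, hotspots and the Morisita-Horn index against hand oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Polygon

from spatimm.quantify import (
    TileDistribution,
    hotspot_top3,
    mh_index,
    mh_pooled_immune_vs_ck,
    parameter_columns,
    parameter_vector,
    region_density,
    tile_densities,
    tile_distribution,
)
from spatimm.regions import RegionAnnotation, effective_tiles, make_tile_grid
from spatimm.registration import MarkerPointPattern

EXTENT = (0.0, 0.0, 2000.0, 2000.0)


def pattern(points, marker="CD3"):
    return MarkerPointPattern(marker, np.asarray(points, dtype=float), EXTENT)


class TestRegionDensity:
    def test_fifty_points_in_004mm2(self, rng):
        region = Polygon([(0, 0), (200, 0), (200, 200), (0, 200)])  # 0.04 mm^2
        pts = rng.uniform(1, 199, size=(50, 2))
        assert region_density(pattern(pts), region) == pytest.approx(1250.0)

    def test_empty_pattern_zero(self):
        region = Polygon([(0, 0), (200, 0), (200, 200), (0, 200)])
        assert region_density(pattern(np.empty((0, 2))), region) == 0.0

    def test_zero_area_region_rejected(self):
        degenerate = Polygon([(0, 0), (1, 0), (2, 0)])
        with pytest.raises(ValueError):
            region_density(pattern([[1, 1]]), degenerate)

    def test_union_density_between_disjoint_parts(self, rng):
        a = Polygon([(0, 0), (300, 0), (300, 300), (0, 300)])
        b = Polygon([(400, 0), (900, 0), (900, 500), (400, 500)])
        pts = np.vstack(
            [rng.uniform(0, 300, (80, 2)), rng.uniform((400, 0), (900, 500), (40, 2))]
        )
        pat = pattern(pts)
        da, db = region_density(pat, a), region_density(pat, b)
        du = region_density(pat, a.union(b))
        assert min(da, db) - 1e-9 <= du <= max(da, db) + 1e-9

    def test_invariant_to_rigid_motion_of_patient(self, rng):
        poly = Polygon([(500, 500), (1500, 500), (1500, 1500), (500, 1500)])
        pts = rng.uniform(400, 1600, size=(200, 2))
        shift = np.array([123.4, -56.7])
        d0 = region_density(pattern(pts), poly)
        moved_poly = Polygon(np.asarray(poly.exterior.coords) + shift)
        d1 = region_density(pattern(pts + shift), moved_poly)
        assert d0 == pytest.approx(d1)


class TestHotspots:
    def test_printed_example(self):
        d = np.array([5.0, 3.0, 9.0, 1.0])
        hs = hotspot_top3(d)
        assert hs.densities == (9.0, 5.0, 3.0)
        assert hs.tile_indices == (2, 0, 1)

    def test_all_equal(self):
        hs = hotspot_top3(np.full(6, 4.2))
        assert hs.densities == (4.2, 4.2, 4.2)
        assert hs.tile_indices == (0, 1, 2)  # ties by ascending tile index

    def test_fewer_than_three_tiles_padded(self):
        hs = hotspot_top3(np.array([7.0, np.nan, np.nan]))
        assert hs.densities[0] == 7.0
        assert np.isnan(hs.densities[1]) and np.isnan(hs.densities[2])

    def test_matches_bruteforce_sort_oracle(self):
        for trial in range(1000):
            r = np.random.default_rng(trial)
            n = r.integers(1, 40)
            d = np.round(r.uniform(0, 100, n), 1)  # rounding provokes ties
            hs = hotspot_top3(d)
            expected = sorted(zip(-d, range(n)))[:3]
            for k, (negv, idx) in enumerate(expected):
                assert hs.densities[k] == -negv
                assert hs.tile_indices[k] == idx

    def test_hotspot1_at_least_mean_tile_density(self, rng):
        grid = make_tile_grid(EXTENT, resolution=1.0, tile_side=500)
        region = Polygon([(0, 0), (2000, 0), (2000, 2000), (0, 2000)])
        eff = effective_tiles(grid, region)
        pts = rng.uniform(0, 2000, size=(500, 2))
        dens = tile_densities(pattern(pts), grid, eff)
        hs = hotspot_top3(dens)
        assert hs.densities[0] >= np.nanmean(dens) >= np.nanmin(dens)

    def test_single_tile_contains_all_points(self, rng):
        grid = make_tile_grid((0, 0, 400, 400), resolution=1.0, tile_side=200)
        eff = np.ones(grid.n_tiles, dtype=bool)
        pts = rng.uniform(0, 199, size=(30, 2))  # all in tile 0
        dens = tile_densities(pattern(pts), grid, eff)
        assert dens[0] == pytest.approx(30 / grid.tile_area_mm2)
        assert dens[1] == 0.0


class TestMorisitaHorn:
    def test_identical_distributions_give_one(self):
        a = TileDistribution("a", np.array([0.2, 0.3, 0.5]), 3)
        assert mh_index(a, a).value == pytest.approx(1.0)

    def test_disjoint_supports_give_zero(self):
        a = TileDistribution("a", np.array([1.0, 0.0]), 2)
        b = TileDistribution("b", np.array([0.0, 1.0]), 2)
        assert mh_index(a, b).value == 0.0

    def test_printed_hand_example(self):
        a = TileDistribution("a", np.array([1.0, 0.0]), 2)
        b = TileDistribution("b", np.array([0.5, 0.5]), 2)
        # 2*(0.5) / (1 + 0.5) = 0.6667
        assert mh_index(a, b).value == pytest.approx(2 / 3, abs=1e-4)

    def test_empty_side_undefined(self):
        a = TileDistribution("a", np.zeros(3), 3)
        b = TileDistribution("b", np.array([0.5, 0.25, 0.25]), 3)
        with pytest.warns(UserWarning):
            assert np.isnan(mh_index(a, b).value)

    def test_mismatched_grids_rejected(self):
        a = TileDistribution("a", np.array([1.0]), 1)
        b = TileDistribution("b", np.array([0.5, 0.5]), 2)
        with pytest.raises(ValueError):
            mh_index(a, b)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        counts_a=st.lists(st.integers(0, 50), min_size=2, max_size=20),
        scale=st.integers(1, 9),
        data=st.data(),
    )
    def test_symmetry_bounds_and_scale_invariance(self, counts_a, scale, data):
        counts_b = data.draw(
            st.lists(st.integers(0, 50), min_size=len(counts_a), max_size=len(counts_a))
        )
        if sum(counts_a) == 0 or sum(counts_b) == 0:
            return
        a = TileDistribution.from_counts(np.array(counts_a, float))
        b = TileDistribution.from_counts(np.array(counts_b, float))
        mh = mh_index(a, b).value
        assert 0.0 <= mh <= 1.0 + 1e-12
        assert mh == mh_index(b, a).value  # exact symmetry
        scaled = TileDistribution.from_counts(np.array(counts_a, float) * scale)
        assert mh_index(scaled, b).value == pytest.approx(mh, abs=1e-12)

    def test_pooled_equals_manual_concatenation(self, rng):
        grid = make_tile_grid(EXTENT, resolution=1.0, tile_side=400)
        eff = np.ones(grid.n_tiles, dtype=bool)
        immune = [
            pattern(rng.uniform(0, 2000, (60, 2)), "CD3"),
            pattern(rng.uniform(0, 2000, (40, 2)), "CD8"),
        ]
        ck = pattern(rng.uniform(0, 2000, (100, 2)), "CK")
        pooled = mh_pooled_immune_vs_ck(immune, ck, grid, eff)
        manual = pattern(np.vstack([immune[0].points, immune[1].points]), "manual")
        expected = mh_index(
            tile_distribution(manual, grid, eff), tile_distribution(ck, grid, eff)
        )
        assert pooled.value == pytest.approx(expected.value)

    def test_pooling_single_marker_equals_pairwise(self, rng):
        grid = make_tile_grid(EXTENT, resolution=1.0, tile_side=400)
        eff = np.ones(grid.n_tiles, dtype=bool)
        cd3 = pattern(rng.uniform(0, 2000, (60, 2)), "CD3")
        ck = pattern(rng.uniform(0, 2000, (100, 2)), "CK")
        pooled = mh_pooled_immune_vs_ck([cd3], ck, grid, eff)
        pairwise = mh_index(
            tile_distribution(cd3, grid, eff), tile_distribution(ck, grid, eff)
        )
        assert pooled.value == pytest.approx(pairwise.value)

    def test_identical_immune_and_ck_points_give_one(self):
        grid = make_tile_grid(EXTENT, resolution=1.0, tile_side=400)
        eff = np.ones(grid.n_tiles, dtype=bool)
        pts = np.random.default_rng(0).uniform(0, 2000, (80, 2))
        res = mh_pooled_immune_vs_ck([pattern(pts, "CD3")], pattern(pts, "CK"), grid, eff)
        assert res.value == pytest.approx(1.0)


class TestParameterVector:
    @pytest.fixture()
    def slides(self):
        r = np.random.default_rng(5)
        return {
            m: pattern(r.uniform(400, 1600, (n, 2)), m)
            for m, n in [("CD3", 300), ("CD4", 200), ("CD8", 150),
                         ("CD19", 80), ("CD163", 120), ("CK", 500)]
        }

    def test_vector_has_47_entries_in_table_order(self, slides, square_annotation):
        vec = parameter_vector(slides, square_annotation, EXTENT)
        cols = parameter_columns()
        assert len(cols) == 47
        assert list(vec) == cols
        # everything except the cohort-level Immunoscore is computed
        assert sum(np.isnan(v) for v in vec.values()) == 1
        assert np.isnan(vec["Immunoscore"])

    def test_empty_marker_slide_leaves_its_entries_missing(self, slides, square_annotation):
        broken = dict(slides)
        broken["CD19"] = pattern(np.empty((0, 2)), "CD19")
        vec = parameter_vector(broken, square_annotation, EXTENT)
        missing = [k for k, v in vec.items() if isinstance(v, float) and np.isnan(v)]
        assert set(missing) == {
            "TC-CD19", "IM-CD19", "TC+IM-CD19",
            "Hotspot1-CD19", "Hotspot2-CD19", "Hotspot3-CD19",
            "CD3-CD19", "CD4-CD19", "CD8-CD19", "CD19-CD163", "CK-CD19",
            "Immunoscore",
        }

    def test_46_column_layout_drops_pooled_index(self):
        cols47 = parameter_columns()
        cols46 = parameter_columns(include_pooled=False)
        assert len(cols46) == 46
        assert set(cols47) - set(cols46) == {"CK-Immune"}

    def test_disjoint_regions_flag_shrinks_tc_denominator(self, slides, square_annotation):
        vec = parameter_vector(slides, square_annotation, EXTENT)
        vec_dis = parameter_vector(slides, square_annotation, EXTENT, disjoint_regions=True)
        # same points divided by a smaller region: density differs, IM unchanged
        assert vec_dis["TC-CD3"] != vec["TC-CD3"]
        assert vec_dis["IM-CD3"] == vec["IM-CD3"]

    def test_mh_tile_side_sensitivity_knob(self, slides, square_annotation):
        vec = parameter_vector(slides, square_annotation, EXTENT)
        vec_fine = parameter_vector(slides, square_annotation, EXTENT, mh_tile_side=500)
        assert vec_fine["CD3-CD4"] != vec["CD3-CD4"]  # different dissection
        assert vec_fine["TC-CD3"] == vec["TC-CD3"]  # densities untouched

    def test_vector_matches_stagewise_computation(self, slides, square_annotation):
        from spatimm.regions import build_im_band

        vec = parameter_vector(slides, square_annotation, EXTENT)
        tc = square_annotation.tc_polygon
        band = build_im_band(square_annotation, extent=EXTENT)
        assert vec["TC-CD3"] == pytest.approx(region_density(slides["CD3"], tc))
        assert vec["IM-CD8"] == pytest.approx(region_density(slides["CD8"], band))
        grid = make_tile_grid(EXTENT)
        eff_tc = effective_tiles(grid, tc)
        hs = hotspot_top3(tile_densities(slides["CD4"], grid, eff_tc))
        assert vec["Hotspot2-CD4"] == pytest.approx(hs.densities[1])
        eff_u = effective_tiles(grid, tc.union(band))
        expected = mh_index(
            tile_distribution(slides["CD3"], grid, eff_u),
            tile_distribution(slides["CD4"], grid, eff_u),
        )
        assert vec["CD3-CD4"] == pytest.approx(expected.value)
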