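"""Biotemperature, zone classifiers, layer builders and point sampling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from climoccur import (GridDefinition, MonthlyTemperature, Raster,
                       biotemperature, build_holdridge_raster,
                       build_latitudinal_raster, ecoregion_simplify,
                       gen_monthly_climate, holdridge_classify,
                       koppen_aggregate, latitudinal_classify,
                       sample_regionalization)
from climoccur.regionalization import (HOLDRIDGE_ZONES, LATITUDINAL_ZONES,
                                       _VALID_KOPPEN, ECOREGION_BIOMES,
                                       KOPPEN_MAIN_CLASSES)

GRID1 = GridDefinition(xmin=0.0, ymin=0.0, cellsize=1.0, ncols=2, nrows=2)


def _monthly(values_per_month, grid=GRID1):
    return MonthlyTemperature(
        [Raster(grid, np.full((grid.nrows, grid.ncols), float(v)))
         for v in values_per_month])


class TestBiotemperature:
    @pytest.mark.parametrize("months,expected", [
        ([25.0] * 12, 25.0),              # within range: identity under clamp
        ([-5.0] * 6 + [20.0] * 6, 10.0),  # (6*0 + 6*20)/12
        ([35.0] * 12, 0.0),               # above 30 °C contributes 0
    ])
    def test_worked_monthly_vectors(self, months, expected):
        biot = biotemperature(_monthly(months))
        assert np.allclose(biot.values, expected)

    def test_wrong_month_count_or_misaligned_grids_error(self):
        with pytest.raises(ValueError, match="12"):
            _monthly([20.0] * 11)
        other = GridDefinition(0.0, 0.0, 1.0, 3, 2)
        months = [Raster(GRID1, np.zeros((2, 2)))] * 11 + [
            Raster(other, np.zeros((2, 3)))]
        with pytest.raises(ValueError, match="aligned"):
            MonthlyTemperature(months)

    @given(st.lists(st.floats(-60, 60), min_size=12, max_size=12))
    def test_bounded_in_0_30_for_any_input(self, months):
        biot = biotemperature(_monthly(months))
        assert np.all(biot.values >= 0.0) and np.all(biot.values <= 30.0)

    def test_nodata_propagates(self):
        vals = np.full((2, 2), 20.0)
        vals[0, 0] = np.nan
        months = [Raster(GRID1, vals.copy()) for _ in range(12)]
        biot = biotemperature(MonthlyTemperature(months))
        assert np.isnan(biot.values[0, 0]) and biot.values[1, 1] == 20.0


class TestHoldridgeClassifier:
    @pytest.mark.parametrize("biot,zone", [
        (25.0, "tropical"), (13.0, "warm temperate"), (24.0, "tropical"),
        (30.0, "tropical"), (0.0, "polar"),
    ])
    def test_printed_examples_and_boundary_convention(self, biot, zone):
        assert holdridge_classify(biot) == zone

    def test_partition_at_every_threshold(self):
        # each boundary value belongs to exactly one (the warmer) belt
        eps = 1e-9
        for label, lo, hi in HOLDRIDGE_ZONES:
            assert holdridge_classify(lo) == label
            if lo > 0.0:
                below = holdridge_classify(lo - eps)
                assert below != label  # the colder belt starts just below

    @given(st.floats(0.0, 30.0))
    def test_every_valid_value_maps_to_exactly_one_zone(self, biot):
        zone = holdridge_classify(biot)
        matches = [lbl for lbl, lo, hi in HOLDRIDGE_ZONES
                   if (lo <= biot < hi) or (lbl == "tropical" and biot == 30.0)]
        assert matches == [zone]

    def test_out_of_range_is_an_error(self):
        with pytest.raises(ValueError):
            holdridge_classify(31.0)
        with pytest.raises(ValueError):
            holdridge_classify(-0.5)


class TestLatitudinalClassifier:
    @pytest.mark.parametrize("lat,zone", [
        (0.0, "tropical"), (-30.0, "subtropical"), (70.0, "polar"),
        (23.5, "subtropical"), (-23.5, "subtropical"), (40.0, "temperate"),
        (66.5, "polar"), (90.0, "polar"), (-90.0, "polar"),
    ])
    def test_thresholds_and_hemispheric_symmetry(self, lat, zone):
        assert latitudinal_classify(lat) == zone

    @given(st.floats(-90.0, 90.0))
    def test_partition_and_symmetry(self, lat):
        zone = latitudinal_classify(lat)
        assert zone == latitudinal_classify(-lat)
        a = abs(lat)
        matches = [lbl for lbl, lo, hi in LATITUDINAL_ZONES
                   if lo <= a < hi or (lbl == "polar" and a == 90.0)]
        assert matches == [zone]

    def test_out_of_range_is_an_error(self):
        with pytest.raises(ValueError):
            latitudinal_classify(91.0)


class TestKoppenAggregate:
    @pytest.mark.parametrize("code,main", [
        ("Af", "tropical"), ("Cfb", "temperate"), ("ET", "tundra"),
        ("EF", "polar"), ("BWh", "dry"), ("Dfc", "continental"),
    ])
    def test_main_class_mapping(self, code, main):
        assert koppen_aggregate(code) == main

    def test_total_and_surjective_on_input_vocabulary(self):
        images = {koppen_aggregate(c) for c in _VALID_KOPPEN}
        assert images == set(KOPPEN_MAIN_CLASSES)

    def test_unknown_code_error_names_it(self):
        with pytest.raises(ValueError, match="Zz"):
            koppen_aggregate("Zz")


class TestEcoregionSimplify:
    @pytest.mark.parametrize("biome,category", [
        ("tropical and subtropical moist broadleaf forests",
         "tropical and subtropical"),
        ("temperate conifer forests", "temperate"),
        ("Mangroves", "mangroves"),  # pass-through
        ("tundra", "tundra"),
    ])
    def test_grouping(self, biome, category):
        assert ecoregion_simplify(biome) == category

    def test_total_on_14_biomes_and_yields_9_categories(self):
        images = {ecoregion_simplify(b) for b in ECOREGION_BIOMES}
        assert len(ECOREGION_BIOMES) == 14
        assert len(images) == 9

    def test_unknown_biome_is_an_error(self):
        with pytest.raises(ValueError, match="swamp"):
            ecoregion_simplify("swamp")


class TestLayerBuilders:
    def test_latitudinal_raster_equals_per_cell_oracle(self):
        grid = GridDefinition(xmin=-10.0, ymin=-90.0, cellsize=5.0,
                              ncols=4, nrows=36)
        layer = build_latitudinal_raster(grid)
        for row in range(grid.nrows):
            for col in range(grid.ncols):
                _, lat = grid.cell_center(row, col)
                assert layer.legend[layer.codes[row, col]] == \
                    latitudinal_classify(lat)

    def test_latitudinal_boundary_cells_and_equatorial_symmetry(self):
        grid = GridDefinition(xmin=0.0, ymin=-90.0, cellsize=1.0,
                              ncols=1, nrows=180)
        layer = build_latitudinal_raster(grid)

        def cat_at(lat):
            return layer.sample([0.5], [lat])[0]

        assert cat_at(0.5) == "tropical"
        assert cat_at(39.5) == "subtropical"
        assert cat_at(40.5) == "temperate"
        for lat in (10.5, 30.5, 50.5, 70.5):
            assert cat_at(lat) == cat_at(-lat)

    def test_uniform_25C_world_is_all_tropical(self):
        monthly = _monthly([25.0] * 12)
        layer = build_holdridge_raster(monthly)
        assert set(layer.sample([0.5, 1.5], [0.5, 1.5])) == {"tropical"}

    def test_gradient_zone_bands_at_closed_form_latitudes(self):
        # t = 28 − 0.5|φ|, all months equal, so BioT = t and the belt bound
        # at BioT = B sits at |φ| = (28 − B)/0.5
        grid = GridDefinition(xmin=0.0, ymin=0.0, cellsize=0.5,
                              ncols=1, nrows=120)
        monthly = gen_monthly_climate(grid, gradient=0.5, seasonality=0.0,
                                      intercept=28.0, noise_sd=0.0)
        layer = build_holdridge_raster(monthly)
        for b_lo, zone in [(24.0, "tropical"), (17.0, "subtropical"),
                           (12.0, "warm temperate"), (6.0, "cool temperate")]:
            lat_boundary = (28.0 - b_lo) / 0.5
            inside = layer.sample([0.25], [lat_boundary - 0.5])[0]
            outside = layer.sample([0.25], [lat_boundary + 0.5])[0]
            assert inside == zone and outside != zone

    def test_nodata_month_gives_nodata_cell(self):
        vals = np.full((2, 2), 20.0)
        vals[0, 1] = np.nan
        months = [Raster(GRID1, vals.copy()) for _ in range(12)]
        layer = build_holdridge_raster(MonthlyTemperature(months))
        # cell (0,1) has center (1.5, 1.5)
        assert layer.sample([1.5], [1.5])[0] == "unclassified"


class TestSampling:
    def test_point_conventions(self):
        grid = GridDefinition(xmin=0.0, ymin=0.0, cellsize=1.0, ncols=2, nrows=1)
        from climoccur import Regionalization
        layer = Regionalization("toy", grid, np.array([[0, 1]]),
                                {0: "west", 1: "east"})
        cats = sample_regionalization(
            [(0.5, 0.5),   # cell center
             (1.0, 0.5),   # shared edge -> half-open: belongs to east cell
             (5.0, 0.5)],  # outside the grid extent
            layer)
        assert cats == ["west", "east", "unclassified"]

    def test_nodata_cell_is_unclassified(self):
        grid = GridDefinition(xmin=0.0, ymin=0.0, cellsize=1.0, ncols=1, nrows=1)
        from climoccur import Regionalization
        layer = Regionalization("toy", grid, np.array([[-1]]), {0: "land"})
        assert layer.sample([0.5], [0.5]) == ["unclassified"]
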