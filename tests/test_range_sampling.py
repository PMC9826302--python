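"""Sampling-effort grids, Fisher–Jenks breaks vs brute force, hotspot rules,
AOO/EOO metrics, temporal series and richness tables."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from climoccur import (JenksClassification, OccurrenceRecord, aoo, eoo,
                       grid_counts, hotspot_categories, jenks_breaks,
                       range_size_class, richness_by_unit, temporal_series)


def _rec(genus, lon, lat, year=None, tdwg=None, rid=None):
    return OccurrenceRecord(
        record_id=rid or f"{genus}{lon}{lat}{year}", genus=genus,
        longitude_text=str(lon), latitude_text=str(lat), longitude=lon,
        latitude=lat, source="t", year=year, country_code_tdwg=tdwg)


class TestGridCounts:
    def test_counts_and_conservation(self):
        recs = [_rec("G", 5.2, 5.7), _rec("G", 5.9, 5.1), _rec("G", 5.5, 5.5),
                _rec("G", 7.1, 2.2)]
        gc = grid_counts(recs)
        assert gc.counts[(5, 5)] == 3 and gc.counts[(7, 2)] == 1
        assert gc.total == len(recs)

    def test_integer_corner_belongs_to_half_open_cell(self):
        gc = grid_counts([_rec("G", 5.0, 5.0)])
        assert gc.counts == {(5, 5): 1}

    def test_extent_window_counts_outside_records(self):
        gc = grid_counts([_rec("G", 5.5, 5.5), _rec("G", 50.0, 5.5)],
                         extent=(0, 0, 10, 10))
        assert gc.total == 1 and gc.n_outside == 1


def brute_force_jenks_ssd(values, k):
    """Exhaustive enumeration over all contiguous partitions of sorted values."""
    data = sorted(values)
    n = len(data)

    def ssd(seg):
        m = sum(seg) / len(seg)
        return sum((x - m) ** 2 for x in seg)

    best = np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = (0,) + cuts + (n,)
        total = sum(ssd(data[bounds[i]:bounds[i + 1]]) for i in range(k))
        best = min(best, total)
    return best


class TestJenks:
    def test_clear_two_cluster_split(self):
        j = jenks_breaks([1, 2, 3, 100, 101, 102], 2)
        assert j.classes == [[1, 2, 3], [100, 101, 102]]

    def test_k1_gives_total_ssd_and_kn_gives_zero(self):
        vals = [4, 8, 15, 16, 23, 42]
        j1 = jenks_breaks(vals, 1)
        assert j1.ssd == pytest.approx(brute_force_jenks_ssd(vals, 1))
        jn = jenks_breaks(vals, len(vals))
        assert jn.ssd == pytest.approx(0.0)

    def test_k_above_distinct_values_is_an_error(self):
        with pytest.raises(ValueError):
            jenks_breaks([1, 1, 2], 3)

    @given(st.lists(st.integers(0, 500), min_size=2, max_size=12),
           st.data())
    def test_dp_matches_exhaustive_enumeration(self, values, data):
        n_distinct = len(set(values))
        k = data.draw(st.integers(1, n_distinct))
        j = jenks_breaks(values, k)
        assert j.ssd == pytest.approx(brute_force_jenks_ssd(values, k), abs=1e-6)
        # classes partition the sorted data
        assert sorted(x for cls in j.classes for x in cls) == sorted(map(float, values))

    def test_ssd_equals_sum_of_class_deviations(self):
        j = jenks_breaks([3, 1, 4, 1, 5, 9, 2, 6], 3)
        manual = sum(sum((x - np.mean(c)) ** 2 for x in c) for c in j.classes)
        assert j.ssd == pytest.approx(manual)


class TestHotspots:
    def _classes(self, groups):
        return JenksClassification(
            k=len(groups), breaks=[g[-1] for g in groups[:-1]],
            classes=[sorted(g) for g in groups],
            ssd=0.0)

    def test_integer_threshold_is_ceiling_of_quarter_max(self):
        classes = self._classes([[10, 500], [1710, 2315], [6240, 8093]])
        flags, threshold, threshold_int = hotspot_categories(classes)
        assert threshold == pytest.approx(0.25 * 8093)
        assert threshold_int == 2024

    def test_class_reaching_threshold_is_flagged(self):
        classes = self._classes([[10, 500], [1710, 2315], [6240, 8093]])
        flags, _, _ = hotspot_categories(classes)
        assert flags == [False, True, True]

    def test_single_class_grid_is_its_own_hotspot(self):
        flags, _, _ = hotspot_categories(self._classes([[3, 7, 9]]))
        assert flags == [True]

    def test_flags_are_monotone_up_the_classes(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(1, 1000, size=40).tolist()
        j = jenks_breaks(vals, 5)
        flags, _, _ = hotspot_categories(j)
        first = flags.index(True)
        assert all(flags[first:])


class TestAOO:
    def test_single_point_is_one_4km2_cell(self):
        assert aoo([(5.0, 5.0)]) == 4.0

    def test_two_distant_points_occupy_two_cells(self):
        assert aoo([(5.0, 5.0), (6.0, 5.0)]) == 8.0  # ~111 km apart

    def test_close_points_straddling_a_grid_line_count_two_cells(self):
        # 2-km mesh anchored at (0,0): points 500 m apart on both sides of
        # the x = 0 grid line fall in different cells (origin dependence)
        from climoccur.geodesy import AUTHALIC_RADIUS_KM
        dlon = np.degrees(0.25 / AUTHALIC_RADIUS_KM)
        assert aoo([(-dlon, 0.0), (dlon, 0.0)]) == 8.0
        # same pair shifted 1 km away from the line: one cell
        shift = np.degrees(1.0 / AUTHALIC_RADIUS_KM)
        assert aoo([(shift - dlon, 0.0), (shift + dlon, 0.0)]) == 4.0

    def test_monotone_under_adding_points_and_order_invariant(self):
        rng = np.random.default_rng(1)
        pts = [(float(rng.uniform(0, 5)), float(rng.uniform(0, 5)))
               for _ in range(30)]
        areas = [aoo(pts[:n]) for n in range(1, 31)]
        assert all(a2 >= a1 for a1, a2 in zip(areas, areas[1:]))
        assert aoo(pts[::-1]) == aoo(pts)


class TestEOO:
    def test_fewer_than_three_points_give_zero(self):
        assert eoo([(0.0, 0.0)]) == 0.0
        assert eoo([(0.0, 0.0), (1.0, 1.0)]) == 0.0

    def test_collinear_points_give_zero(self):
        assert eoo([(0.0, 0.0), (1.0, 1.0), (2.0, 2.0)]) == 0.0

    def test_unit_square_matches_independent_geodesic_oracle(self):
        # 12308.778361 km²: 1°x1° equatorial quadrangle, computed once with
        # geosphere::areaPolygon on the WGS84 ellipsoid
        area = eoo([(0, 0), (1, 0), (1, 1), (0, 1)])
        assert area == pytest.approx(12308.778361, rel=0.005)

    def test_invariant_under_permutation_and_duplication(self):
        pts = [(0, 0), (2, 0), (2, 2), (0, 2), (1, 1)]
        base = eoo(pts)
        assert eoo(pts[::-1]) == pytest.approx(base)
        assert eoo(pts + pts) == pytest.approx(base)
        assert eoo(pts + [(1.0, 1.0)]) == pytest.approx(base)  # interior point

    def test_antimeridian_disjunction_uses_unwrapped_hull(self):
        # points straddling ±180°: hull spans ~2° of longitude, not ~358°
        area = eoo([(179.5, 0), (-179.5, 0), (179.5, 1), (-179.5, 1)])
        assert area < 2 * 12500.0


class TestRangeSizeClass:
    @pytest.mark.parametrize("aoo_km2,cls", [
        (88, "restricted"),        # well under the 2000 km² B2 bound
        (190564, "widespread"),
        (2000, "intermediate"),    # bound itself is not restricted (strict <)
        (10000, "intermediate"),   # bound itself is not widespread (strict >)
        (5000, "intermediate"),
    ])
    def test_thresholds(self, aoo_km2, cls):
        assert range_size_class(aoo_km2) == cls


class TestTemporalSeries:
    def test_uniform_one_record_per_year_quartiles(self):
        recs = [_rec("G", 1.0, 1.0, year=y, rid=str(y))
                for y in range(1900, 2000)]
        series, quartiles, n_excluded = temporal_series(
            recs, None, {"G": "temperate"})
        assert n_excluded == 0
        qs = quartiles[("all", "temperate")]
        assert qs == {25: 1924, 50: 1949, 75: 1974}
        cum = series["cumulative"].tolist()
        assert cum == sorted(cum)  # monotone nondecreasing

    def test_all_records_in_one_year_is_a_step(self):
        recs = [_rec("G", 1.0, 1.0, year=1950, rid=str(i)) for i in range(9)]
        _, quartiles, _ = temporal_series(recs, None, {"G": "tropical"})
        assert quartiles[("all", "tropical")] == {25: 1950, 50: 1950, 75: 1950}

    def test_pre_1900_and_missing_years_excluded_and_counted(self):
        recs = [_rec("G", 1.0, 1.0, year=1850, rid="a"),
                _rec("G", 1.0, 1.0, year=None, rid="b"),
                _rec("G", 1.0, 1.0, year=1950, rid="c")]
        series, _, n_excluded = temporal_series(recs, None, {"G": "tropical"})
        assert n_excluded == 2 and len(series) == 1


class TestRichness:
    def test_distinct_genus_counts_and_composition(self):
        recs = [_rec("A", 1, 1, tdwg="XX", rid="1"),
                _rec("A", 2, 2, tdwg="XX", rid="2"),  # duplicate genus
                _rec("B", 3, 3, tdwg="XX", rid="3"),
                _rec("B", 4, 4, tdwg="YY", rid="4")]
        table = richness_by_unit(recs, {"A": "tropical", "B": "temperate"},
                                 units=["XX", "YY", "ZZ"])
        rows = {r["unit"]: r for _, r in table.iterrows()}
        assert rows["XX"]["n_genera"] == 2 and rows["XX"]["composition"] == "both"
        assert rows["YY"]["n_genera"] == 1
        assert rows["YY"]["composition"] == "temperate-only"
        assert rows["ZZ"]["n_genera"] == 0 and rows["ZZ"]["composition"] == "none"
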