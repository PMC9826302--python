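"""Sampling-effort grids, Jenks natural breaks, hotspot detection, range-size
metrics (AOO/EOO), temporal accumulation series, and richness by spatial unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint

from .geodesy import equal_area_xy, polygon_area_km2
from .occurrences import PolygonLayer

# ---------------------------------------------------------------------------
# Sampling-effort grids


@dataclass
class GridCounts:
    """Occurrence counts on a cell grid anchored at integer degrees."""

    cell_size: float
    counts: dict  # (ix, iy) integer cell index -> count
    region: str = ""
    n_outside: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def max_count(self) -> int:
        return max(self.counts.values()) if self.counts else 0

    def nonzero_values(self):
        return sorted(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [{"lon_min": ix * self.cell_size, "lat_min": iy * self.cell_size,
                 "count": c} for (ix, iy), c in sorted(self.counts.items())]
        return pd.DataFrame(rows)


def grid_counts(records, cell_size: float = 1.0, extent=None,
                region: str = "") -> GridCounts:
    """Count records per half-open grid cell (cells anchored at 0°).

    ``extent`` is an optional (xmin, ymin, xmax, ymax) window; records outside
    it are counted in ``n_outside`` and excluded.
    """
    counts, n_outside = {}, 0
    for rec in records:
        lon, lat = rec.longitude, rec.latitude
        if extent is not None:
            xmin, ymin, xmax, ymax = extent
            if not (xmin <= lon < xmax and ymin <= lat < ymax):
                n_outside += 1
                continue
        key = (math.floor(lon / cell_size), math.floor(lat / cell_size))
        counts[key] = counts.get(key, 0) + 1
    return GridCounts(cell_size, counts, region, n_outside)


# ---------------------------------------------------------------------------
# Fisher–Jenks natural breaks


@dataclass
class JenksClassification:
    k: int
    breaks: list  # k-1 ascending boundaries (upper value of classes 1..k-1)
    classes: list  # k lists of sorted values
    ssd: float  # total within-class sum of squared deviations

    @property
    def class_ranges(self):
        return [(c[0], c[-1]) for c in self.classes]


def jenks_breaks(values, k: int) -> JenksClassification:
    """Optimal k-class natural-breaks partition (Fisher–Jenks).

    Exact dynamic program, O(k·n²): finds the contiguous partition of the
    sorted values minimizing the total within-class sum of squared deviations
    from class means. When several partitions tie, the one whose last class
    starts earliest (smallest last-class minimum) is returned.
    """
    data = np.sort(np.asarray(list(values), dtype=float))
    n = len(data)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(np.unique(data)):
        raise ValueError(f"k={k} exceeds the {len(np.unique(data))} distinct values")

    # prefix sums for O(1) segment SSD
    cs = np.concatenate(([0.0], np.cumsum(data)))
    cs2 = np.concatenate(([0.0], np.cumsum(data ** 2)))

    def seg_ssd(i, j):  # values data[i:j]
        m = j - i
        s = cs[j] - cs[i]
        return (cs2[j] - cs2[i]) - s * s / m

    INF = float("inf")
    cost = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, best_i = INF, -1
            for i in range(c - 1, j):
                if cost[c - 1, i] == INF:
                    continue
                v = cost[c - 1, i] + seg_ssd(i, j)
                # strict improvement keeps the earliest split on ties,
                # i.e. the smallest last-class minimum
                if v < best - 1e-12:
                    best, best_i = v, i
            cost[c, j] = best
            back[c, j] = best_i

    bounds = [n]
    j = n
    for c in range(k, 0, -1):
        j = back[c, j]
        bounds.append(j)
    bounds.reverse()
    classes = [data[bounds[i]:bounds[i + 1]].tolist() for i in range(k)]
    breaks = [c[-1] for c in classes[:-1]]
    return JenksClassification(k, breaks, classes, float(cost[k, n]))


# ---------------------------------------------------------------------------
# Hotspots


def hotspot_categories(classes: JenksClassification, max_count: Optional[float] = None,
                       frac: float = 0.25):
    """Flag natural-breaks classes that reach the hotspot band.

    The hotspot threshold is ``frac`` of the regional per-cell maximum
    (reported both raw and rounded up to the next integer record count); a
    class is a sampling hotspot when its class maximum reaches the threshold.
    Flags are monotone: every class above a flagged one is flagged.

    Returns ``(flags, threshold, threshold_int)``.
    """
    if not classes.classes or not classes.classes[-1]:
        raise ValueError("empty classification")
    if max_count is None:
        max_count = classes.classes[-1][-1]
    threshold = frac * max_count
    threshold_int = int(math.ceil(threshold))
    flags = [bool(cls[-1] >= threshold) for cls in classes.classes]
    return flags, threshold, threshold_int


# ---------------------------------------------------------------------------
# Range-size metrics


def aoo(points, cell_width_km: float = 2.0, origin=(0.0, 0.0)) -> float:
    """Area of occupancy: 4 km² per occupied cell of a fixed 2-km grid.

    Points are projected to a world cylindrical equal-area projection and
    binned into ``cell_width_km`` squares anchored at ``origin``; the result
    is (cell area) × (number of occupied cells). The grid origin is fixed for
    reproducibility and exposed because AOO is origin-dependent for points
    that straddle a grid line.
    """
    lons = np.array([p[0] for p in points], dtype=float)
    lats = np.array([p[1] for p in points], dtype=float)
    if lons.size == 0:
        raise ValueError("aoo needs at least one point")
    x, y = equal_area_xy(lons, lats)
    ix = np.floor((x - origin[0]) / cell_width_km).astype(int)
    iy = np.floor((y - origin[1]) / cell_width_km).astype(int)
    n_cells = len(set(zip(ix.tolist(), iy.tolist())))
    return cell_width_km ** 2 * n_cells


def _unwrap_longitudes(lons: np.ndarray) -> np.ndarray:
    """Shift longitudes by 360° where that makes the point spread < 180°.

    Handles ranges crossing the antimeridian (e.g., an Asia–Americas
    disjunction) without splitting the hull at ±180°.
    """
    lons = np.asarray(lons, dtype=float)
    if lons.max() - lons.min() <= 180.0:
        return lons
    shifted = np.where(lons < 0.0, lons + 360.0, lons)
    if shifted.max() - shifted.min() < lons.max() - lons.min():
        return shifted
    return lons


def eoo(points) -> float:
    """Extent of occurrence: geodesic area (km²) of the points' convex hull.

    Fewer than three non-collinear points give 0. Invariant under point
    permutation and duplication.
    """
    pts = list({(float(p[0]), float(p[1])) for p in points})
    if len(pts) < 3:
        return 0.0
    lons = _unwrap_longitudes(np.array([p[0] for p in pts]))
    lats = np.array([p[1] for p in pts])
    hull = MultiPoint(list(zip(lons, lats))).convex_hull
    if hull.geom_type != "Polygon":
        return 0.0  # all points collinear
    xs, ys = hull.exterior.coords.xy
    return polygon_area_km2(np.array(xs)[:-1], np.array(ys)[:-1])


def range_size_class(aoo_km2: float, restricted_max_km2: float = 2000.0,
                     widespread_min_km2: float = 10000.0) -> str:
    """Range-size class from AOO, after the IUCN B2 vulnerable threshold.

    Strictly below ``restricted_max_km2`` (the 2000 km² B2 bound) is
    "restricted"; strictly above ``widespread_min_km2`` is "widespread";
    everything else (both bounds included) is "intermediate". This is a
    range-size categorization only, not a threat assessment.
    """
    if aoo_km2 < restricted_max_km2:
        return "restricted"
    if aoo_km2 > widespread_min_km2:
        return "widespread"
    return "intermediate"


@dataclass
class RangeMetrics:
    genus: str
    aoo_km2: float
    eoo_km2: float
    size_class: str


def range_metrics(records_by_genus, **kwargs) -> pd.DataFrame:
    """AOO, EOO and size class per genus; ``records_by_genus`` maps genus
    to its cleaned records."""
    rows = []
    for genus in sorted(records_by_genus):
        pts = [(r.longitude, r.latitude) for r in records_by_genus[genus]]
        a = aoo(pts, **{k: v for k, v in kwargs.items()
                        if k in ("cell_width_km", "origin")})
        e = eoo(pts)
        rows.append({"genus": genus, "aoo_km2": a, "eoo_km2": e,
                     "size_class": range_size_class(a)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Temporal series and richness


def temporal_series(records, regions: Optional[PolygonLayer], labels,
                    start_year: int = 1900):
    """Cumulative occurrence counts per year × region × qualitative label.

    Records before ``start_year`` or without a year are excluded and counted.
    Returns ``(tidy DataFrame, quartile_years, n_excluded)`` where
    ``quartile_years`` maps (region, label) to the first years reaching 25,
    50 and 75% of that series' total.
    """
    rows, n_excluded = [], 0
    for rec in records:
        if rec.year is None or rec.year < start_year:
            n_excluded += 1
            continue
        region = (regions.lookup(rec.longitude, rec.latitude) or "none"
                  ) if regions is not None else "all"
        rows.append({"year": rec.year, "region": region,
                     "label": labels.get(rec.genus, "unlabeled")})
    if not rows:
        return pd.DataFrame(columns=["year", "region", "label", "cumulative"]), {}, n_excluded
    df = pd.DataFrame(rows)
    out, quartiles = [], {}
    for (region, label), sub in df.groupby(["region", "label"]):
        counts = sub.groupby("year").size().sort_index()
        cum = counts.cumsum()
        total = int(cum.iloc[-1])
        qs = {}
        for q in (0.25, 0.50, 0.75):
            qs[int(q * 100)] = int(cum.index[cum >= q * total][0])
        quartiles[(region, label)] = qs
        for year, c in cum.items():
            out.append({"year": int(year), "region": region, "label": label,
                        "cumulative": int(c)})
    return pd.DataFrame(out), quartiles, n_excluded


def richness_by_unit(records, labels, units=None) -> pd.DataFrame:
    """Distinct-genus count and composition per TDWG botanical country.

    Composition is "temperate-only", "tropical-only" or "both" from the
    qualitative labels; units with no records get count 0 and label "none".
    ``units`` optionally lists all unit codes so empty ones are reported.
    """
    genera_by_unit = {}
    for rec in records:
        code = rec.country_code_tdwg
        if code is None:
            continue
        genera_by_unit.setdefault(code, set()).add(rec.genus)
    all_units = set(genera_by_unit)
    if units is not None:
        all_units |= set(units)
    rows = []
    for code in sorted(all_units):
        genera = genera_by_unit.get(code, set())
        lbls = {labels.get(g, "unlabeled") for g in genera}
        if not genera:
            comp = "none"
        elif lbls == {"temperate"}:
            comp = "temperate-only"
        elif lbls == {"tropical"}:
            comp = "tropical-only"
        else:
            comp = "both"
        rows.append({"unit": code, "n_genera": len(genera), "composition": comp})
    return pd.DataFrame(rows)
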