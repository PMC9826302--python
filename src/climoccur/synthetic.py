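"""Seeded generators for every input the pipeline consumes.

The generators emulate a multi-source occurrence compilation over a
rectangular "continent" tiled by botanical-country polygons and surrounded by
sea: clean records inside each genus's native range, plus planted defect
records — byte-identical cross-source replicates, low-precision coordinates,
misplaced coastal points (≤ 10 km off land), erroneous offshore points
(> 10 km), cultivated-keyword localities, and records outside the native
range. Defect classes are disjoint (each record has at most one planted
defect) so every cleaning stage's removal count is identifiable, and the
withheld truth table lists each record's class.

Monthly temperature grids follow a latitudinal gradient with seasonal
amplitude, so Holdridge belt boundaries sit at analytically known latitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box

from .grids import GridDefinition, MonthlyTemperature, Raster
from .occurrences import NativeRangeMap, OccurrenceRecord, PolygonLayer

KM_PER_DEG_LAT = 111.195  # authalic-sphere degree of latitude

_CLEAN_LOCALITIES = (
    "montane forest", "ridge trail above the pass", "riverbank thicket",
    "valley slope", "old-growth stand", "limestone outcrop", "",
)
_CULTIVATED_LOCALITIES = (
    "Botanical garden of the university", "Parque municipal",
    "old farm terrace", "castillo viejo", "campo de golf",
    "cementerio municipal", "zoo enclosure", "cultivado en finca",
)
_SOURCES = ("GBIF", "BIEN", "HERB-A")
_BASES = ("PRESERVED_SPECIMEN", "HUMAN_OBSERVATION")


@dataclass
class SyntheticScenario:
    """Study conditions for one synthetic occurrence compilation."""

    seed: int = 0
    n_genera: int = 5
    n_clean_per_genus: int = 40
    # planted defect totals (disjoint record sets)
    n_duplicates: int = 10
    n_low_precision: int = 5
    n_coastal: int = 3      # ≤ 10 km off land: snapped, kept
    n_offshore: int = 3     # > 10 km off land: removed
    n_cultivated: int = 2
    n_out_of_range: int = 4
    # continent layout: lon/lat bounds and the botanical-country tiling
    block: tuple = (0.0, 10.0, 20.0, 30.0)
    nx: int = 2
    ny: int = 2
    mask_cellsize: float = 0.05  # ~5.5 km land-mask cells

    def genera(self):
        return [f"Genus{chr(65 + i)}" for i in range(self.n_genera)]


@dataclass
class SyntheticDataset:
    """Generated occurrence table plus the spatial context it lives in."""

    records: list
    truth: pd.DataFrame  # record_id, genus, error_class
    tdwg_layer: PolygonLayer
    iso_layer: PolygonLayer
    land_template: Raster
    native_ranges: NativeRangeMap
    genera: list

    def planted_counts(self) -> dict:
        counts = self.truth["error_class"].value_counts().to_dict()
        return {cls: int(counts.get(cls, 0)) for cls in
                ("clean", "duplicate", "low_precision", "coastal",
                 "offshore", "cultivated", "out_of_range")}


def gen_regions(block=(0.0, 10.0, 20.0, 30.0), nx: int = 2, ny: int = 2,
                mask_cellsize: float = 0.05, margin: float = 1.0):
    """Botanical-country and ISO polygon tilings plus a consistent land mask.

    The continent ``block`` is tiled by ``nx × ny`` rectangles; the land-mask
    raster marks exactly the cells whose centers fall inside the block (its
    extent extends ``margin`` degrees beyond the block, all NoData there).
    """
    xmin, ymin, xmax, ymax = block
    dx, dy = (xmax - xmin) / nx, (ymax - ymin) / ny
    tdwg, iso = [], []
    for i in range(nx):
        for j in range(ny):
            geom = box(xmin + i * dx, ymin + j * dy,
                       xmin + (i + 1) * dx, ymin + (j + 1) * dy)
            tdwg.append((f"{chr(65 + i)}{chr(65 + j)}A", geom))
            iso.append((f"{chr(65 + i)}{chr(65 + j)}", geom))

    ncols = int(round((xmax - xmin + 2 * margin) / mask_cellsize))
    nrows = int(round((ymax - ymin + 2 * margin) / mask_cellsize))
    grid = GridDefinition(xmin - margin, ymin - margin, mask_cellsize,
                          ncols, nrows)
    lon, lat = grid.centers()
    land = (lon > xmin) & (lon < xmax) & (lat > ymin) & (lat < ymax)
    values = np.where(land, 1.0, np.nan)
    return PolygonLayer(tdwg), PolygonLayer(iso), Raster(grid, values)


def gen_monthly_climate(grid: GridDefinition, gradient: float = 0.5,
                        seasonality: float = 0.0, intercept: float = 28.0,
                        noise_sd: float = 0.0, seed: int = 0,
                        nodata_mask=None) -> MonthlyTemperature:
    """Twelve monthly mean-temperature grids with a latitudinal gradient.

    Month m at latitude φ:
    ``t = intercept − gradient·|φ| + seasonality·cos(2π(m−7)/12)·s(φ)``
    with s = +1 in the northern hemisphere and −1 in the southern (July-warm
    north, January-warm south), plus optional seeded Gaussian noise. With
    zero noise, Holdridge belt boundaries invert in closed form:
    a belt bound at biotemperature B sits at ``|φ| = (intercept − B)/gradient``
    provided all months stay within 0–30 °C.
    """
    rng = np.random.default_rng(seed)
    _, lat = grid.centers()
    sign = np.where(lat >= 0.0, 1.0, -1.0)
    months = []
    for m in range(1, 13):
        t = (intercept - gradient * np.abs(lat)
             + seasonality * math.cos(2.0 * math.pi * (m - 7) / 12.0) * sign)
        if noise_sd > 0.0:
            t = t + rng.normal(0.0, noise_sd, size=t.shape)
        if nodata_mask is not None:
            t = np.where(nodata_mask, np.nan, t)
        months.append(Raster(grid, t))
    return MonthlyTemperature(months)


def _fmt(value: float, decimals: int) -> str:
    return f"{value:.{decimals}f}"


class _RecordFactory:
    def __init__(self, scenario, rng):
        self.s = scenario
        self.rng = rng
        self.counter = 0

    def make(self, genus, lon, lat, decimals=4, locality=None, source=None,
             rid=None):
        self.counter += 1
        rng = self.rng
        if locality is None:
            locality = _CLEAN_LOCALITIES[int(rng.integers(len(_CLEAN_LOCALITIES)))]
        if source is None:
            source = _SOURCES[int(rng.integers(len(_SOURCES)))]
        lon_text, lat_text = _fmt(lon, decimals), _fmt(lat, decimals)
        return OccurrenceRecord(
            record_id=rid or f"SYN{self.counter:06d}",
            genus=genus,
            species=f"{genus.lower()}ensis",
            year=int(rng.integers(1900, 2021)),
            locality=locality or None,
            longitude_text=lon_text, latitude_text=lat_text,
            longitude=float(lon_text), latitude=float(lat_text),
            elevation=float(rng.integers(0, 3000)),
            catalog_number=f"CAT{self.counter:06d}",
            basis_of_record=_BASES[int(rng.integers(len(_BASES)))],
            source=source,
        )


def _point_in(rng, geom, margin=0.05):
    x0, y0, x1, y1 = geom.bounds
    return (rng.uniform(x0 + margin, x1 - margin),
            rng.uniform(y0 + margin, y1 - margin))


def _offshore_point(rng, home_bounds, block, land: Raster, dist_km: float):
    """A sea point at ``dist_km`` from the nearest land-mask cell center,
    displaced perpendicularly off an outer edge of the home polygon."""
    x0, y0, x1, y1 = home_bounds
    bx0, by0, bx1, by1 = block
    cs = land.grid.cellsize
    sides = []
    if abs(x0 - bx0) < 1e-9:
        sides.append("W")
    if abs(x1 - bx1) < 1e-9:
        sides.append("E")
    if abs(y0 - by0) < 1e-9:
        sides.append("S")
    if abs(y1 - by1) < 1e-9:
        sides.append("N")
    if not sides:
        raise ValueError("home polygon has no coastline (interior polygon)")
    side = sides[int(rng.integers(len(sides)))]

    def snap_center(v, lo):
        # center of the mask cell containing v, along one axis
        return lo + (math.floor((v - lo) / cs) + 0.5) * cs

    if side in ("W", "E"):
        lat = snap_center(rng.uniform(y0 + 0.2 * (y1 - y0), y0 + 0.8 * (y1 - y0)),
                          land.grid.ymin)
        edge_lon = bx0 + cs / 2.0 if side == "W" else bx1 - cs / 2.0
        dlon = dist_km / (KM_PER_DEG_LAT * math.cos(math.radians(lat)))
        lon = edge_lon - dlon if side == "W" else edge_lon + dlon
        anchor = (edge_lon, lat)
    else:
        lon = snap_center(rng.uniform(x0 + 0.2 * (x1 - x0), x0 + 0.8 * (x1 - x0)),
                          land.grid.xmin)
        edge_lat = by0 + cs / 2.0 if side == "S" else by1 - cs / 2.0
        dlat = dist_km / KM_PER_DEG_LAT
        lat = edge_lat - dlat if side == "S" else edge_lat + dlat
        anchor = (lon, edge_lat)
    return lon, lat, anchor


def gen_occurrences(scenario: SyntheticScenario) -> SyntheticDataset:
    """Generate the occurrence table, truth table and spatial context."""
    s = scenario
    total_planted = (s.n_duplicates + s.n_low_precision + s.n_coastal
                     + s.n_offshore + s.n_cultivated + s.n_out_of_range)
    if s.n_duplicates > s.n_genera * s.n_clean_per_genus:
        raise ValueError("more duplicates requested than clean records")
    rng = np.random.default_rng(s.seed)
    tdwg, iso, land = gen_regions(s.block, s.nx, s.ny, s.mask_cellsize)
    genera = s.genera()
    polys = tdwg.features  # sorted by code
    if s.n_out_of_range > 0 and len(polys) < 2:
        raise ValueError("out-of-range planting needs at least two polygons")

    home = {g: polys[i % len(polys)] for i, g in enumerate(genera)}
    native = NativeRangeMap({g: {code} for g, (code, _) in home.items()})

    factory = _RecordFactory(s, rng)
    records, truth_rows = [], []

    def add(rec, cls):
        records.append(rec)
        truth_rows.append({"record_id": rec.record_id, "genus": rec.genus,
                           "error_class": cls})

    # clean records
    clean_by_genus = {}
    for g in genera:
        _, geom = home[g]
        for _ in range(s.n_clean_per_genus):
            lon, lat = _point_in(rng, geom)
            rec = factory.make(g, lon, lat)
            add(rec, "clean")
            clean_by_genus.setdefault(g, []).append(rec)

    def cycle_genus(i):
        return genera[i % len(genera)]

    # byte-identical replicates attributed to a different source
    all_clean = [r for g in genera for r in clean_by_genus[g]]
    dup_targets = rng.choice(len(all_clean), size=s.n_duplicates, replace=False)
    for j in dup_targets:
        orig = all_clean[int(j)]
        dup = orig.copy()
        factory.counter += 1
        dup.record_id = f"SYN{factory.counter:06d}"
        dup.source = next(src for src in _SOURCES if src != orig.source)
        add(dup, "duplicate")

    # low-precision coordinates (≤ 1 decimal in the text form)
    for i in range(s.n_low_precision):
        g = cycle_genus(i)
        lon, lat = _point_in(rng, home[g][1], margin=0.3)
        add(factory.make(g, lon, lat, decimals=1), "low_precision")

    # misplaced coastal (≤ 10 km) and erroneous offshore (> 10 km) records
    from .geodesy import haversine_km
    clon, clat = land.data_cell_centers()
    for i in range(s.n_coastal):
        g = cycle_genus(i)
        d = float(rng.uniform(3.5, 8.0))
        lon, lat, _ = _offshore_point(rng, home[g][1].bounds, s.block, land, d)
        rec = factory.make(g, lon, lat)
        dmin = float(haversine_km(rec.longitude, rec.latitude, clon, clat).min())
        assert dmin <= 9.5, f"coastal plant failed: {dmin:.2f} km"
        add(rec, "coastal")
    for i in range(s.n_offshore):
        g = cycle_genus(i + s.n_coastal)
        d = float(rng.uniform(20.0, 60.0))
        lon, lat, _ = _offshore_point(rng, home[g][1].bounds, s.block, land, d)
        rec = factory.make(g, lon, lat)
        dmin = float(haversine_km(rec.longitude, rec.latitude, clon, clat).min())
        assert dmin > 12.0, f"offshore plant failed: {dmin:.2f} km"
        add(rec, "offshore")

    # cultivated-keyword localities
    for i in range(s.n_cultivated):
        g = cycle_genus(i)
        lon, lat = _point_in(rng, home[g][1])
        loc = _CULTIVATED_LOCALITIES[int(rng.integers(len(_CULTIVATED_LOCALITIES)))]
        add(factory.make(g, lon, lat, locality=loc), "cultivated")

    # records outside the native range
    for i in range(s.n_out_of_range):
        g = cycle_genus(i)
        home_code = home[g][0]
        others = [p for p in polys if p[0] != home_code]
        code, geom = others[int(rng.integers(len(others)))]
        lon, lat = _point_in(rng, geom)
        add(factory.make(g, lon, lat), "out_of_range")

    # interleave defect records among the clean ones, deterministically
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    truth = pd.DataFrame([truth_rows[i] for i in order])
    return SyntheticDataset(records, truth, tdwg, iso, land, native, genera)
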