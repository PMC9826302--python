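"""Categorical bioclimatic regionalizations of a study grid.

Five classification systems are supported: a latitudinal zonation (fixed
parallels), Holdridge life-zone belts from biotemperature, Köppen–Geiger
main classes (aggregation of an existing coded layer), GEnS broad biomes
(consumed as a supplied categorical layer), and simplified ecoregion biomes.
"""

from __future__ import annotations

import numpy as np

from .grids import GridDefinition, MonthlyTemperature, Raster, Regionalization

# ---------------------------------------------------------------------------
# Biotemperature and Holdridge life-zone belts

#: Holdridge belts as (label, lower, upper) on biotemperature, °C.
#: Intervals are half-open, closed at the lower bound of the warmer class:
#: tropical is [24, 30] (closed top, BioT cannot exceed 30).
#: The printed subpolar bound 3.5 overlaps the boreal interval 6–3; the belts
#: here use a contiguous 3 °C boundary, treating the 3.5 as a typographical
#: slip — a partition requires contiguous intervals.
HOLDRIDGE_ZONES = (
    ("tropical", 24.0, 30.0),
    ("subtropical", 17.0, 24.0),
    ("warm temperate", 12.0, 17.0),
    ("cool temperate", 6.0, 12.0),
    ("boreal", 3.0, 6.0),
    ("subpolar", 1.5, 3.0),
    ("polar", 0.0, 1.5),
)

LATITUDINAL_ZONES = (
    ("tropical", 0.0, 23.5),
    ("subtropical", 23.5, 40.0),
    ("temperate", 40.0, 66.5),
    ("polar", 66.5, 90.0),
)


def biotemperature(monthly: MonthlyTemperature) -> Raster:
    """Mean biotemperature from 12 monthly mean-temperature grids.

    Biotemperature is the temperature range in which plants grow efficiently:
    each monthly value is replaced by 0 when below 0 °C or above 30 °C and
    kept otherwise; the 12 adjusted months are averaged. NoData propagates.
    """
    stack = monthly.stack()
    clamped = np.where((stack >= 0.0) & (stack <= 30.0), stack, 0.0)
    clamped = np.where(np.isnan(stack), np.nan, clamped)
    return Raster(monthly.grid, clamped.mean(axis=0))


def holdridge_classify(biot: float) -> str:
    """Holdridge life-zone belt for a biotemperature value in [0, 30]."""
    if np.isnan(biot) or not (0.0 <= biot <= 30.0):
        raise ValueError(f"biotemperature {biot!r} outside [0, 30]")
    for label, lo, hi in HOLDRIDGE_ZONES:
        if biot >= lo:
            return label
    return HOLDRIDGE_ZONES[-1][0]  # biot == 0.0


def latitudinal_classify(latitude: float) -> str:
    """Latitudinal climate zone, symmetric about the equator.

    Boundaries at 23.5° (tropical/subtropical), 40° (subtropical/temperate)
    and 66.5° (temperate/polar); each boundary belongs to the poleward zone.
    """
    if np.isnan(latitude) or not (-90.0 <= latitude <= 90.0):
        raise ValueError(f"latitude {latitude!r} outside [-90, 90]")
    a = abs(latitude)
    for label, lo, hi in LATITUDINAL_ZONES:
        if lo <= a < hi:
            return label
    return "polar"  # a == 90


# ---------------------------------------------------------------------------
# Köppen–Geiger main-class aggregation

_KOPPEN_FIRST_LETTER = {"A": "tropical", "B": "dry", "C": "temperate",
                        "D": "continental"}

#: The six main classes. Köppen–Geiger layers encode the polar group as E
#: with subtypes ET (tundra) and EF (frost); the six-class scheme splits
#: these into tundra and polar.
KOPPEN_MAIN_CLASSES = ("tropical", "dry", "temperate", "continental",
                       "tundra", "polar")

_VALID_KOPPEN = {
    "Af", "Am", "Aw", "As",
    "BWh", "BWk", "BSh", "BSk",
    "Csa", "Csb", "Csc", "Cwa", "Cwb", "Cwc", "Cfa", "Cfb", "Cfc",
    "Dsa", "Dsb", "Dsc", "Dsd", "Dwa", "Dwb", "Dwc", "Dwd",
    "Dfa", "Dfb", "Dfc", "Dfd",
    "ET", "EF",
}


def koppen_aggregate(code: str) -> str:
    """Aggregate a full Köppen–Geiger class code to its main class."""
    if code not in _VALID_KOPPEN:
        raise ValueError(f"unknown Köppen–Geiger code {code!r}")
    if code == "ET":
        return "tundra"
    if code == "EF":
        return "polar"
    return _KOPPEN_FIRST_LETTER[code[0]]


# ---------------------------------------------------------------------------
# Simplified ecoregion biomes

_TROPICAL_BIOMES = {
    "tropical and subtropical moist broadleaf forests",
    "tropical and subtropical dry broadleaf forests",
    "tropical and subtropical coniferous forests",
    "tropical and subtropical grasslands, savannas, and shrublands",
}
_TEMPERATE_BIOMES = {
    "temperate broadleaf and mixed forests",
    "temperate conifer forests",
    "temperate grasslands, savannas, and shrublands",
}

#: The 14 terrestrial ecoregion biomes (input vocabulary).
ECOREGION_BIOMES = tuple(sorted(_TROPICAL_BIOMES | _TEMPERATE_BIOMES)) + (
    "boreal forests/taiga",
    "flooded grasslands and savannas",
    "montane grasslands and shrublands",
    "tundra",
    "mediterranean forests, woodlands, and scrub",
    "deserts and xeric shrublands",
    "mangroves",
)


def _norm_biome(name: str) -> str:
    return (name.strip().casefold().replace("&", "and")
            .replace(" and shrublands", ", and shrublands")
            .replace(",, and", ", and"))


_CANON = {_norm_biome(b): b for b in ECOREGION_BIOMES}


def ecoregion_simplify(biome_name: str) -> str:
    """Merge ecoregion biomes into broader climate categories.

    Four tropical/subtropical biomes collapse to "tropical and subtropical",
    three temperate biomes collapse to "temperate"; the remaining seven
    biomes pass through unchanged.
    """
    key = _norm_biome(biome_name)
    if key not in _CANON:
        raise ValueError(f"unknown ecoregion biome {biome_name!r}")
    canon = _CANON[key]
    if canon in _TROPICAL_BIOMES:
        return "tropical and subtropical"
    if canon in _TEMPERATE_BIOMES:
        return "temperate"
    return canon


# ---------------------------------------------------------------------------
# Layer builders and sampling


def build_latitudinal_raster(grid: GridDefinition) -> Regionalization:
    """Latitudinal-zonation layer: each cell classified by its center latitude."""
    labels = [z[0] for z in LATITUDINAL_ZONES]
    legend = {i: lbl for i, lbl in enumerate(labels)}
    inv = {lbl: i for i, lbl in legend.items()}
    _, lats = grid.centers()
    codes = np.vectorize(lambda la: inv[latitudinal_classify(la)])(lats)
    return Regionalization("latitudinal", grid, codes, legend)


def build_holdridge_raster(monthly: MonthlyTemperature) -> Regionalization:
    """Holdridge life-zone layer: belt of the per-cell mean biotemperature."""
    biot = biotemperature(monthly)
    labels = [z[0] for z in HOLDRIDGE_ZONES]
    legend = {i: lbl for i, lbl in enumerate(labels)}
    inv = {lbl: i for i, lbl in legend.items()}
    codes = np.full(biot.values.shape, Regionalization.NODATA_CODE, dtype=int)
    valid = ~np.isnan(biot.values)
    flat = biot.values[valid]
    codes[valid] = [inv[holdridge_classify(v)] for v in flat]
    return Regionalization("holdridge", monthly.grid, codes, legend)


def aggregate_layer(layer: Regionalization, mapping, name: str) -> Regionalization:
    """Re-legend a categorical layer through a label-aggregation function.

    Used to turn a full Köppen–Geiger coded layer into the six main classes,
    or a 14-biome ecoregion layer into the simplified grouping.
    """
    out_labels = []
    code_map = {}
    for code, label in layer.legend.items():
        new_label = mapping(label)
        if new_label not in out_labels:
            out_labels.append(new_label)
        code_map[code] = out_labels.index(new_label)
    legend = {i: lbl for i, lbl in enumerate(out_labels)}
    codes = np.full(layer.codes.shape, Regionalization.NODATA_CODE, dtype=int)
    for old, new in code_map.items():
        codes[layer.codes == old] = new
    return Regionalization(name, layer.grid, codes, legend)


def sample_regionalization(points, layer: Regionalization):
    """Category label per (lon, lat) point; off-grid or NoData -> 'unclassified'."""
    lons = [p[0] for p in points]
    lats = [p[1] for p in points]
    return layer.sample(lons, lats)
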