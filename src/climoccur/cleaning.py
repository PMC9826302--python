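"""Occurrence-record cleaning pipeline.

Stages, in order: administrative harmonization, replicate removal,
coordinate-precision filter, land/coastal filter (10-km rule), cultivated
flagging, native-range filter. Every stage conserves records
(input = kept + removed) and the pipeline is deterministic given input order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .geodesy import haversine_km
from .grids import Raster
from .occurrences import (NativeRangeMap, PolygonLayer, fold_text,
                          harmonize_country_codes)

#: Locality keywords marking probable cultivated, non-wild records.
CULTIVATED_KEYWORDS = (
    "cultivated", "cultivado", "park", "parque", "garden", "jardín",
    "castel", "castillo", "golf", "cementerio", "zoo", "farm",
)


def loss_percent(n_input: int, n_kept: int) -> float:
    """Percentage of records lost during cleaning, rounded to 2 decimals."""
    if n_input == 0:
        return 0.0
    return round(100.0 * (n_input - n_kept) / n_input, 2)


def representation_percent(n: int, total: int) -> float:
    """Share of a genus in the whole database, in percent (2 decimals)."""
    return round(100.0 * n / total, 2)


def _dedup_key(rec):
    # Replicate key: the fields listed for replicate identification
    # (species, year, country code, locality, longitude, latitude, elevation,
    # catalog number, basis of record). Text is whitespace-trimmed, case- and
    # diacritic-folded; coordinates compare by their textual form; missing
    # fields compare equal as empty strings.
    return (
        fold_text(f"{rec.genus} {rec.species or ''}".strip()),
        str(rec.year or ""),
        fold_text(rec.country_code_tdwg or "").strip(),
        fold_text(rec.locality or "").strip(),
        rec.longitude_text.strip(),
        rec.latitude_text.strip(),
        "" if rec.elevation is None else repr(rec.elevation),
        fold_text(rec.catalog_number or ""),
        fold_text(rec.basis_of_record or ""),
    )


def deduplicate(records):
    """Collapse replicate records to one, keeping the first in input order.

    Returns ``(kept, removed)`` with kept + removed == input.
    """
    seen, kept, removed = set(), [], []
    for rec in records:
        key = _dedup_key(rec)
        if key in seen:
            removed.append(rec)
        else:
            seen.add(key)
            kept.append(rec)
    return kept, removed


def _n_decimals(text: str) -> int:
    text = text.strip()
    if "." not in text:
        return 0
    return len(text.split(".", 1)[1].rstrip())


def filter_coordinate_precision(records, min_decimals: int = 2):
    """Drop records whose coordinate text has fewer than two decimals.

    The rule operates on the textual representation: trailing zeros count,
    so "12.30" has two decimals while the numerically identical "12.3" has
    one. Both longitude and latitude must satisfy the minimum.
    """
    kept, removed = [], []
    for rec in records:
        if (_n_decimals(rec.longitude_text) >= min_decimals
                and _n_decimals(rec.latitude_text) >= min_decimals):
            kept.append(rec)
        else:
            removed.append(rec)
    return kept, removed


def classify_by_land_distance(records, land_template: Raster,
                              threshold_km: float = 10.0):
    """Split records into on-land / coastal-snapped / erroneous-offshore.

    The template raster's data cells define the land surface. Records inside
    a data cell pass unchanged. Records off land but within ``threshold_km``
    (great-circle distance to the nearest data-cell center) are treated as
    misplaced coastal records: they are kept, with coordinates moved to that
    nearest cell center. Records farther than the threshold are erroneous
    and removed.

    Returns ``(on_land, snapped, removed)``.
    """
    centers_lon, centers_lat = land_template.data_cell_centers()
    if centers_lon.size == 0:
        raise ValueError("land template has no data cells")
    on_land, snapped, removed = [], [], []
    for rec in records:
        idx = land_template.grid.cell_index(rec.longitude, rec.latitude)
        if idx is not None and not np.isnan(land_template.values[idx]):
            on_land.append(rec)
            continue
        d = haversine_km(rec.longitude, rec.latitude, centers_lon, centers_lat)
        j = int(np.argmin(d))
        if d[j] <= threshold_km:
            rec.longitude = float(centers_lon[j])
            rec.latitude = float(centers_lat[j])
            rec.longitude_text = f"{rec.longitude:.6f}"
            rec.latitude_text = f"{rec.latitude:.6f}"
            snapped.append(rec)
        else:
            removed.append(rec)
    return on_land, snapped, removed


def flag_cultivated(records, keywords=CULTIVATED_KEYWORDS):
    """Flag records whose locality mentions a cultivation keyword.

    Matching is substring-based, case- and diacritic-insensitive ("jardin"
    matches "jardín"). Flagged records are returned for review — whether they
    are removed is a separate, configurable pipeline step, because localities
    like "Parque Nacional ..." can be native stands (false positives that the
    original protocol re-checked manually).
    """
    folded = [fold_text(k) for k in keywords]
    flagged, unflagged = [], []
    for rec in records:
        loc = fold_text(rec.locality) if rec.locality else ""
        (flagged if loc and any(k in loc for k in folded) else unflagged).append(rec)
    return flagged, unflagged


def filter_native_range(records, native: NativeRangeMap):
    """Keep records whose TDWG code lies in the genus's native range.

    Returns ``(kept, removed_outside, removed_missing_code)``; a genus absent
    from the native-range map raises.
    """
    kept, removed_outside, removed_missing = [], [], []
    for rec in records:
        codes = native[rec.genus]
        if rec.country_code_tdwg is None:
            removed_missing.append(rec)
        elif rec.country_code_tdwg in codes:
            kept.append(rec)
        else:
            removed_outside.append(rec)
    return kept, removed_outside, removed_missing


@dataclass
class CleaningConfig:
    """Configuration of the cleaning pipeline."""

    tdwg_layer: Optional[PolygonLayer] = None
    iso_layer: Optional[PolygonLayer] = None
    land_template: Optional[Raster] = None
    native_ranges: Optional[NativeRangeMap] = None
    threshold_km: float = 10.0
    min_decimals: int = 2
    cultivated_keywords: tuple = CULTIVATED_KEYWORDS
    remove_flagged_cultivated: bool = True
    # stage toggles
    do_harmonize: bool = True
    do_deduplicate: bool = True
    do_precision: bool = True
    do_land: bool = True
    do_cultivated: bool = True
    do_native_range: bool = True


@dataclass
class CleaningReport:
    """Per-stage and per-genus accounting of a cleaning run."""

    n_input: int = 0
    stages: dict = field(default_factory=dict)  # stage -> counts dict
    per_genus: dict = field(default_factory=dict)  # genus -> {input, kept, loss}
    n_kept: int = 0

    def add_stage(self, name, n_in, n_removed, **extra):
        counts = {"input": n_in, "removed": n_removed, "kept": n_in - n_removed}
        counts.update(extra)
        self.stages[name] = counts

    def finalize(self, records_in, records_out):
        self.n_kept = len(records_out)
        genera_in, genera_out = {}, {}
        for r in records_in:
            genera_in[r.genus] = genera_in.get(r.genus, 0) + 1
        for r in records_out:
            genera_out[r.genus] = genera_out.get(r.genus, 0) + 1
        for genus in sorted(genera_in):
            n_in = genera_in[genus]
            n_kept = genera_out.get(genus, 0)
            self.per_genus[genus] = {
                "input": n_in, "kept": n_kept,
                "loss_percent": loss_percent(n_in, n_kept),
            }

    def to_dict(self):
        return {"n_input": self.n_input, "n_kept": self.n_kept,
                "stages": self.stages, "per_genus": self.per_genus}

    def to_json(self, path=None):
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def per_genus_frame(self) -> pd.DataFrame:
        rows = [{"genus": g, **c} for g, c in self.per_genus.items()]
        return pd.DataFrame(rows)


def run_cleaning(records, config: CleaningConfig):
    """Run the full cleaning pipeline; returns ``(clean_records, report)``.

    Stage order: harmonize -> deduplicate -> precision -> land/coastal ->
    cultivated -> native range. Coastal-snapped records are re-harmonized
    after snapping (their pre-snap coordinates were off land, so the first
    lookup left their codes empty).
    """
    report = CleaningReport(n_input=len(records))
    records_in = list(records)
    current = list(records)

    if config.do_harmonize:
        if config.tdwg_layer is None or config.iso_layer is None:
            raise ValueError("harmonization requires tdwg_layer and iso_layer")
        current, flagged = harmonize_country_codes(
            current, config.tdwg_layer, config.iso_layer)
        report.add_stage("harmonize", len(current), 0, flagged_no_polygon=len(flagged))

    if config.do_deduplicate:
        n_in = len(current)
        current, removed = deduplicate(current)
        report.add_stage("deduplicate", n_in, len(removed))

    if config.do_precision:
        n_in = len(current)
        current, removed = filter_coordinate_precision(current, config.min_decimals)
        report.add_stage("precision", n_in, len(removed))

    if config.do_land:
        if config.land_template is None:
            raise ValueError("land stage requires land_template")
        n_in = len(current)
        on_land, snapped, removed = classify_by_land_distance(
            current, config.land_template, config.threshold_km)
        if snapped and config.do_harmonize:
            harmonize_country_codes(snapped, config.tdwg_layer, config.iso_layer)
        current = on_land + snapped
        report.add_stage("land", n_in, len(removed), snapped=len(snapped))

    if config.do_cultivated:
        n_in = len(current)
        flagged, unflagged = flag_cultivated(current, config.cultivated_keywords)
        if config.remove_flagged_cultivated:
            current = unflagged
            report.add_stage("cultivated", n_in, len(flagged), flagged=len(flagged))
        else:
            report.add_stage("cultivated", n_in, 0, flagged=len(flagged))

    if config.do_native_range:
        if config.native_ranges is None:
            raise ValueError("native-range stage requires native_ranges")
        n_in = len(current)
        current, removed_out, removed_missing = filter_native_range(
            current, config.native_ranges)
        report.add_stage("native_range", n_in,
                         len(removed_out) + len(removed_missing),
                         removed_outside=len(removed_out),
                         removed_missing_code=len(removed_missing))

    report.finalize(records_in, current)
    return current, report
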