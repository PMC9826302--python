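"""Occurrence-record data model, delimited-text I/O and administrative
harmonization for multi-source occurrence tables.

Coordinates are kept both as the original text (the coordinate-precision
filter is defined on the textual form: "12.30" has two decimals, 12.3 does
not) and as parsed WGS84 decimal degrees.
"""

from __future__ import annotations

import json
import unicodedata
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd
from shapely.geometry import Point, shape, mapping

STANDARD_COLUMNS = {
    "genus": "genus",
    "species": "species",
    "year": "year",
    "country_code_iso": "country_code_iso",
    "country_code_tdwg": "country_code_tdwg",
    "locality": "locality",
    "longitude": "longitude",
    "latitude": "latitude",
    "elevation": "elevation",
    "catalog_number": "catalog_number",
    "basis_of_record": "basis_of_record",
}


@dataclass
class OccurrenceRecord:
    """One georeferenced specimen or observation with provenance."""

    record_id: str
    genus: str
    longitude_text: str
    latitude_text: str
    longitude: float
    latitude: float
    source: str
    species: Optional[str] = None
    year: Optional[int] = None
    country_code_iso: Optional[str] = None
    country_code_tdwg: Optional[str] = None
    locality: Optional[str] = None
    elevation: Optional[float] = None
    catalog_number: Optional[str] = None
    basis_of_record: Optional[str] = None

    def copy(self) -> "OccurrenceRecord":
        return OccurrenceRecord(**asdict(self))


def _parse_coord(text: str, lo: float, hi: float) -> Optional[float]:
    try:
        value = float(text)
    except (TypeError, ValueError):
        return None
    if not (lo <= value <= hi):
        return None
    return value


def read_occurrences(path, source_label, column_map=None, delimiter=None):
    """Read a delimited occurrence table into records.

    Parameters
    ----------
    path : str or Path
        CSV/TSV file with a header row.
    source_label : str
        Origin-database label stamped on every record.
    column_map : dict, optional
        field name -> column name in the file; defaults to standard names.
    delimiter : str, optional
        Inferred from the extension (``.tsv`` -> tab) when omitted.

    Returns
    -------
    (records, n_rejected)
        Rows with unparsable or out-of-range coordinates are rejected and
        counted, never fatal. Missing genus or coordinate columns raise.
    """
    path = Path(path)
    cmap = dict(STANDARD_COLUMNS)
    if column_map:
        cmap.update(column_map)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)

    for mandatory in ("genus", "longitude", "latitude"):
        if cmap[mandatory] not in df.columns:
            raise ValueError(
                f"mandatory column {cmap[mandatory]!r} (field {mandatory}) "
                f"missing from {path.name}")

    records, n_rejected = [], 0
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))

        def get(fld):
            col = cmap[fld]
            val = row.get(col, "")
            return val.strip() if isinstance(val, str) else val

        # prefer verbatim text columns when the file carries them (as the
        # package's own output format does), so text precision round-trips
        lon_text = (row.get("longitude_text") or get("longitude")).strip()
        lat_text = (row.get("latitude_text") or get("latitude")).strip()
        lon = _parse_coord(lon_text, -180.0, 180.0)
        lat = _parse_coord(lat_text, -90.0, 90.0)
        if lon is None or lat is None:
            n_rejected += 1
            continue
        year = get("year")
        elev = get("elevation")
        records.append(OccurrenceRecord(
            record_id=f"{source_label}:{i}",
            genus=get("genus"),
            species=get("species") or None,
            year=int(float(year)) if year else None,
            country_code_iso=get("country_code_iso") or None,
            country_code_tdwg=get("country_code_tdwg") or None,
            locality=get("locality") or None,
            longitude_text=lon_text,
            latitude_text=lat_text,
            longitude=lon,
            latitude=lat,
            elevation=float(elev) if elev else None,
            catalog_number=get("catalog_number") or None,
            basis_of_record=get("basis_of_record") or None,
            source=source_label,
        ))
    return records, n_rejected


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def write_occurrences(records, path, delimiter=None):
    """Write records back out as delimited text (same dialect conventions)."""
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df = records_to_frame(records)
    df.to_csv(path, sep=delimiter, index=False)


class PolygonLayer:
    """A labeled polygon set (e.g., TDWG level-3 botanical countries).

    Point-in-polygon lookup includes boundaries; a point on a shared edge is
    assigned to the polygon with the lexicographically smallest code, so
    assignment is deterministic.
    """

    def __init__(self, features):
        # features: iterable of (code, shapely geometry)
        feats = sorted(features, key=lambda cg: cg[0])
        if not feats:
            raise ValueError("polygon layer is empty")
        self.features = feats

    def lookup(self, lon: float, lat: float) -> Optional[str]:
        pt = Point(lon, lat)
        for code, geom in self.features:
            if geom.covers(pt):
                return code
        return None

    @property
    def codes(self):
        return [c for c, _ in self.features]

    @classmethod
    def from_geojson(cls, path, code_property: str):
        data = json.loads(Path(path).read_text())
        feats = [(f["properties"][code_property], shape(f["geometry"]))
                 for f in data["features"]]
        return cls(feats)

    def to_geojson(self, path, code_property: str = "code"):
        fc = {"type": "FeatureCollection", "features": [
            {"type": "Feature", "properties": {code_property: code},
             "geometry": mapping(geom)}
            for code, geom in self.features]}
        Path(path).write_text(json.dumps(fc))


def harmonize_country_codes(records, tdwg_layer: PolygonLayer,
                            iso_layer: PolygonLayer):
    """Fill/overwrite TDWG level-3 and ISO country codes by spatial lookup.

    Existing codes are always replaced by the point-in-polygon result — this
    also corrects typographical country errors in the source data. Points
    falling in no polygon get a missing code and are reported as flagged.

    Returns ``(records, flagged_ids)``; records are modified in place and the
    operation is idempotent.
    """
    flagged = []
    for rec in records:
        tdwg = tdwg_layer.lookup(rec.longitude, rec.latitude)
        iso = iso_layer.lookup(rec.longitude, rec.latitude)
        rec.country_code_tdwg = tdwg
        rec.country_code_iso = iso
        if tdwg is None:
            flagged.append(rec.record_id)
    return records, flagged


def apply_synonym_table(records, synonyms):
    """Rewrite outdated binomials to accepted (genus, species) pairs.

    ``synonyms`` maps old binomial -> (accepted genus, accepted species).
    Unmatched names are untouched. Returns the number of rewrites.
    """
    n = 0
    for rec in records:
        binomial = f"{rec.genus} {rec.species}" if rec.species else rec.genus
        if binomial in synonyms:
            rec.genus, rec.species = synonyms[binomial]
            n += 1
    return n


class NativeRangeMap:
    """Per-genus native range as a set of TDWG level-3 codes."""

    def __init__(self, mapping):
        self._map = {}
        for genus, codes in mapping.items():
            codes = set(codes)
            if not codes or any(not c or c != c.upper() for c in codes):
                raise ValueError(
                    f"native range for {genus!r} must be non-empty uppercase codes")
            self._map[genus] = codes

    def __contains__(self, genus):
        return genus in self._map

    def __getitem__(self, genus):
        if genus not in self._map:
            raise KeyError(f"genus {genus!r} has no declared native range")
        return self._map[genus]

    def items(self):
        return self._map.items()


def fold_text(text: str) -> str:
    """Case-fold and strip diacritics, for keyword and key comparison."""
    if text is None:
        return ""
    norm = unicodedata.normalize("NFKD", text)
    return "".join(c for c in norm if not unicodedata.combining(c)).casefold()
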