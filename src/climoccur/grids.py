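"""Regular geographic grids, rasters and categorical regionalizations.

Rasters are stored as plain-text ESRI ASCII grids (``.asc``); categorical
layers carry their legend (integer code -> category label) in a JSON sidecar
file ``<name>.legend.json``. Grid cells are half-open intervals
``[x, x+dx) x [y, y+dy)`` so every point belongs to at most one cell.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass(frozen=True)
class GridDefinition:
    """A regular WGS84 lon/lat grid. ``(xmin, ymin)`` is the lower-left corner."""

    xmin: float
    ymin: float
    cellsize: float
    ncols: int
    nrows: int

    @property
    def xmax(self) -> float:
        return self.xmin + self.cellsize * self.ncols

    @property
    def ymax(self) -> float:
        return self.ymin + self.cellsize * self.nrows

    def cell_index(self, lon: float, lat: float):
        """(row, col) of the half-open cell containing the point, or None.

        Rows are numbered from the top (north), matching array storage.
        """
        col = math.floor((lon - self.xmin) / self.cellsize + 1e-12)
        row_from_bottom = math.floor((lat - self.ymin) / self.cellsize + 1e-12)
        if not (0 <= col < self.ncols and 0 <= row_from_bottom < self.nrows):
            return None
        return self.nrows - 1 - row_from_bottom, col

    def cell_center(self, row: int, col: int):
        lon = self.xmin + (col + 0.5) * self.cellsize
        lat = self.ymin + (self.nrows - row - 0.5) * self.cellsize
        return lon, lat

    def centers(self):
        """(lon, lat) arrays of all cell centers, shaped (nrows, ncols)."""
        lons = self.xmin + (np.arange(self.ncols) + 0.5) * self.cellsize
        lats = self.ymin + (self.nrows - np.arange(self.nrows) - 0.5) * self.cellsize
        return np.meshgrid(lons, lats)


@dataclass
class Raster:
    """A single-band float grid; NaN marks NoData cells."""

    grid: GridDefinition
    values: np.ndarray  # shape (nrows, ncols), float, NaN = NoData

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.nrows, self.grid.ncols):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.grid.nrows}, {self.grid.ncols})"
            )

    def aligned_with(self, other: "Raster") -> bool:
        return self.grid == other.grid

    def value_at(self, lon: float, lat: float) -> float:
        idx = self.grid.cell_index(lon, lat)
        if idx is None:
            return float("nan")
        return float(self.values[idx])

    def data_cell_centers(self):
        """(lon, lat) arrays of the centers of non-NoData cells."""
        lon, lat = self.grid.centers()
        mask = ~np.isnan(self.values)
        return lon[mask], lat[mask]

    def write_ascii(self, path):
        _write_ascii(path, self.grid, self.values)

    @classmethod
    def read_ascii(cls, path):
        grid, values = _read_ascii(path)
        return cls(grid, values)


@dataclass
class Regionalization:
    """A categorical raster: integer codes plus a legend code -> label."""

    name: str
    grid: GridDefinition
    codes: np.ndarray  # int array, shape (nrows, ncols); NODATA_CODE = NoData
    legend: dict  # int code -> label

    NODATA_CODE = -1
    UNCLASSIFIED = "unclassified"

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=int)
        if self.codes.shape != (self.grid.nrows, self.grid.ncols):
            raise ValueError("codes shape does not match grid")
        present = set(np.unique(self.codes)) - {self.NODATA_CODE}
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"codes without legend entry: {sorted(missing)}")

    @property
    def categories(self):
        return [self.legend[c] for c in sorted(self.legend)]

    def sample(self, lons, lats):
        """Category label per point; 'unclassified' for NoData or off-grid."""
        out = []
        for lon, lat in zip(np.atleast_1d(lons), np.atleast_1d(lats)):
            idx = self.grid.cell_index(float(lon), float(lat))
            if idx is None:
                out.append(self.UNCLASSIFIED)
                continue
            code = int(self.codes[idx])
            out.append(self.legend.get(code, self.UNCLASSIFIED)
                       if code != self.NODATA_CODE else self.UNCLASSIFIED)
        return out

    def write(self, path):
        path = Path(path)
        vals = self.codes.astype(float)
        vals[self.codes == self.NODATA_CODE] = np.nan
        _write_ascii(path, self.grid, vals)
        sidecar = path.with_suffix(".legend.json")
        sidecar.write_text(json.dumps(
            {"name": self.name, "legend": {str(k): v for k, v in self.legend.items()}},
            indent=2))

    @classmethod
    def read(cls, path):
        path = Path(path)
        grid, vals = _read_ascii(path)
        meta = json.loads(path.with_suffix(".legend.json").read_text())
        codes = np.where(np.isnan(vals), cls.NODATA_CODE, vals).astype(int)
        legend = {int(k): v for k, v in meta["legend"].items()}
        return cls(meta["name"], grid, codes, legend)


class MonthlyTemperature:
    """Twelve co-registered mean monthly temperature grids (°C)."""

    def __init__(self, months):
        months = list(months)
        if len(months) != 12:
            raise ValueError(f"expected 12 monthly grids, got {len(months)}")
        first = months[0]
        for i, m in enumerate(months[1:], start=2):
            if not m.aligned_with(first):
                raise ValueError(f"monthly grid {i} is not aligned with month 1")
        # NoData must coincide across months
        nan0 = np.isnan(first.values)
        for i, m in enumerate(months[1:], start=2):
            if not np.array_equal(np.isnan(m.values), nan0):
                raise ValueError(f"NoData mask of month {i} differs from month 1")
        self.months = months

    @property
    def grid(self) -> GridDefinition:
        return self.months[0].grid

    def stack(self) -> np.ndarray:
        return np.stack([m.values for m in self.months])


def _write_ascii(path, grid: GridDefinition, values: np.ndarray):
    path = Path(path)
    lines = [
        f"ncols {grid.ncols}",
        f"nrows {grid.nrows}",
        f"xllcorner {grid.xmin!r}",
        f"yllcorner {grid.ymin!r}",
        f"cellsize {grid.cellsize!r}",
        f"NODATA_value {NODATA}",
    ]
    vals = np.where(np.isnan(values), NODATA, values)
    for row in vals:
        lines.append(" ".join(repr(float(v)) for v in row))
    path.write_text("\n".join(lines) + "\n")


def _read_ascii(path):
    lines = Path(path).read_text().splitlines()
    header = {}
    for line in lines[:6]:
        key, val = line.split()
        header[key.lower()] = float(val)
    grid = GridDefinition(
        xmin=header["xllcorner"], ymin=header["yllcorner"],
        cellsize=header["cellsize"],
        ncols=int(header["ncols"]), nrows=int(header["nrows"]),
    )
    nodata = header["nodata_value"]
    values = np.array([[float(v) for v in line.split()] for line in lines[6:]])
    values[values == nodata] = np.nan
    return grid, values
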