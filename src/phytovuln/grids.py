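"""Gridded climate data containers and plain-text raster I/O.

A :class:`ClimateGrid` holds one 2-D array per climate variable on a shared
lon/lat rectangle, together with a boolean land mask.  Rasters are exchanged
as ESRI ASCII grids (``.asc``), a plain-text single-band format readable by
any GIS; multi-band data is written as one ``.asc`` file per variable.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

#: canonical variable set used throughout: annual mean temperature [degC],
#: mean diurnal temperature range [degC], temperature seasonality (SD of
#: monthly means, unitless), annual precipitation [mm], precipitation
#: seasonality (CV, %).
CLIMATE_VARIABLES = ("tmean", "tdiurnal", "tseason", "precip", "pseason")

#: variables that are physically non-negative
NONNEGATIVE_VARIABLES = ("precip", "pseason")

SCENARIOS = ("present", "future_moderate", "future_severe")

_ASC_NODATA = -9999.0


@dataclass
class GridSpec:
    """Geometry of a regular lon/lat grid (cell size in decimal degrees)."""

    xmin: float
    ymin: float
    nrows: int
    ncols: int
    resolution: float

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError(f"resolution must be positive, got {self.resolution}")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def xmax(self) -> float:
        return self.xmin + self.ncols * self.resolution

    @property
    def ymax(self) -> float:
        return self.ymin + self.nrows * self.resolution

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return (self.xmin, self.ymin, self.xmax, self.ymax)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def cell_index(self, lon, lat):
        """Map coordinates to (row, col).

        Cells are half-open ``[lower, upper)``; points exactly on the upper
        extent edge fall in the last cell.  Row 0 is the *top* (max latitude)
        row, matching raster conventions.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.xmin) / self.resolution).astype(int)
        row_from_bottom = np.floor((lat - self.ymin) / self.resolution).astype(int)
        # upper-edge coordinates belong to the last cell
        col = np.where((lon == self.xmax), self.ncols - 1, col)
        row_from_bottom = np.where(lat == self.ymax, self.nrows - 1, row_from_bottom)
        bad = (col < 0) | (col >= self.ncols) | (row_from_bottom < 0) | (row_from_bottom >= self.nrows)
        if np.any(bad):
            offenders = np.column_stack([np.atleast_1d(lon)[np.atleast_1d(bad)],
                                         np.atleast_1d(lat)[np.atleast_1d(bad)]])
            raise ValueError(f"coordinates outside grid extent {self.extent}: {offenders.tolist()[:10]}")
        row = self.nrows - 1 - row_from_bottom
        return row, col

    def cell_center(self, row, col):
        """Inverse of :meth:`cell_index` (cell centers)."""
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.xmin + (col + 0.5) * self.resolution
        lat = self.ymin + (self.nrows - 1 - row + 0.5) * self.resolution
        return lon, lat


@dataclass
class ClimateGrid:
    """Multi-variable climate raster for one scenario.

    All variable arrays share ``spec.shape``; values outside ``mask`` are
    undefined (NaN-filled on write).
    """

    spec: GridSpec
    values: dict[str, np.ndarray]
    mask: np.ndarray
    scenario_label: str = "present"
    elevation: np.ndarray | None = None
    km_per_cell: float = 5.0

    def __post_init__(self) -> None:
        for name, arr in self.values.items():
            if arr.shape != self.spec.shape:
                raise ValueError(f"variable {name!r} has shape {arr.shape}, expected {self.spec.shape}")
        if self.mask.shape != self.spec.shape:
            raise ValueError("mask shape mismatch")

    @property
    def variables(self) -> list[str]:
        return list(self.values)

    @property
    def n_land(self) -> int:
        return int(self.mask.sum())

    def validate(self) -> None:
        """Check container invariants; raise ValueError on violation."""
        for name, arr in self.values.items():
            if not np.all(np.isfinite(arr[self.mask])):
                raise ValueError(f"non-finite values inside land mask for {name!r}")
            if name in NONNEGATIVE_VARIABLES and np.any(arr[self.mask] < 0):
                raise ValueError(f"negative values in non-negative variable {name!r}")

    def subset(self, variables: list[str]) -> "ClimateGrid":
        """View restricted to the given variables (arrays shared, not copied)."""
        missing = [v for v in variables if v not in self.values]
        if missing:
            raise KeyError(f"variables not in grid: {missing}")
        return ClimateGrid(
            spec=self.spec, values={v: self.values[v] for v in variables},
            mask=self.mask, scenario_label=self.scenario_label,
            elevation=self.elevation, km_per_cell=self.km_per_cell,
        )

    def table(self, rows, cols) -> np.ndarray:
        """Stack variable values at given cells into an (n, n_vars) array."""
        return np.column_stack([self.values[v][rows, cols] for v in self.variables])

    def land_table(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(rows, cols, values) for every land cell, row-major order."""
        rows, cols = np.nonzero(self.mask)
        return rows, cols, self.table(rows, cols)


def write_ascii_grid(path: str, array: np.ndarray, spec: GridSpec,
                     mask: np.ndarray | None = None) -> None:
    """Write a single band as an ESRI ASCII grid (text) raster."""
    arr = np.array(array, dtype=float)
    if mask is not None:
        arr = np.where(mask, arr, _ASC_NODATA)
    arr = np.where(np.isfinite(arr), arr, _ASC_NODATA)
    header = (
        f"ncols {spec.ncols}\n"
        f"nrows {spec.nrows}\n"
        f"xllcorner {spec.xmin}\n"
        f"yllcorner {spec.ymin}\n"
        f"cellsize {spec.resolution}\n"
        f"NODATA_value {_ASC_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, arr, fmt="%.6g")


def read_ascii_grid(path: str) -> tuple[np.ndarray, GridSpec, np.ndarray]:
    """Read an ESRI ASCII grid; returns (array, spec, mask)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        arr = np.loadtxt(fh)
    spec = GridSpec(
        xmin=header["xllcorner"],
        ymin=header["yllcorner"],
        nrows=int(header["nrows"]),
        ncols=int(header["ncols"]),
        resolution=header["cellsize"],
    )
    arr = arr.reshape(spec.shape)
    nodata = header.get("nodata_value", _ASC_NODATA)
    mask = arr != nodata
    out = np.where(mask, arr, np.nan)
    return out, spec, mask


def write_climate_grid(grid: ClimateGrid, directory: str) -> list[str]:
    """Write one .asc file per variable into *directory* (band order =
    variable list order, encoded in the file names)."""
    os.makedirs(directory, exist_ok=True)
    paths = []
    for i, name in enumerate(grid.variables, start=1):
        path = os.path.join(directory, f"{grid.scenario_label}_b{i:02d}_{name}.asc")
        write_ascii_grid(path, grid.values[name], grid.spec, grid.mask)
        paths.append(path)
    if grid.elevation is not None:
        path = os.path.join(directory, f"{grid.scenario_label}_elevation.asc")
        write_ascii_grid(path, grid.elevation, grid.spec, grid.mask)
        paths.append(path)
    return paths
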