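"""Projected single-band raster container and plain-text grid I/O.

All grids in this package share one convention: projected coordinates in
metres, row 0 at the north edge, cell centres at half-cell offsets from the
grid origin.  Nodata is represented as NaN in memory and as the value
``-9999`` in ESRI ASCII grid files.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

ASCII_NODATA = -9999.0


@dataclass
class Raster:
    """A single-band raster on a projected grid.

    Parameters
    ----------
    data
        2-D float array; NaN marks nodata cells.
    cell_size
        Edge length of a (square) cell, metres.
    x_origin, y_origin
        West and *north* edge of the grid, projected metres.
    crs
        Free-form identifier of the projected coordinate reference; the
        package never reprojects, it only checks that rasters agree.
    """

    data: np.ndarray
    cell_size: float
    x_origin: float = 0.0
    y_origin: float = 0.0
    crs: str = "local-projected-metres"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    # -- geometry ---------------------------------------------------------
    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def centre_of(self, row: int | np.ndarray, col: int | np.ndarray):
        """Projected coordinates of a cell centre."""
        x = self.x_origin + (np.asarray(col) + 0.5) * self.cell_size
        y = self.y_origin - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def cell_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing projected point(s) (x, y)."""
        col = np.floor((np.asarray(x) - self.x_origin) / self.cell_size).astype(int)
        row = np.floor((self.y_origin - np.asarray(y)) / self.cell_size).astype(int)
        return row, col

    def contains(self, x, y) -> np.ndarray:
        row, col = self.cell_of(x, y)
        return (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)

    def centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrids (X, Y) of all cell-centre coordinates."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = self.x_origin + (cols + 0.5) * self.cell_size
        y = self.y_origin - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def aligned_with(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.cell_size, other.cell_size)
            and math.isclose(self.x_origin, other.x_origin)
            and math.isclose(self.y_origin, other.y_origin)
        )

    def copy(self) -> "Raster":
        return replace(self, data=self.data.copy())

    def like(self, data: np.ndarray) -> "Raster":
        """New raster on this grid with different data."""
        if np.shape(data) != self.shape:
            raise ValueError("data shape does not match grid")
        return replace(self, data=np.asarray(data, dtype=float))

    def values_at(self, x, y) -> np.ndarray:
        """Cell value under each point; NaN for points off the grid."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.full(x.shape, np.nan)
        ok = self.contains(x, y)
        row, col = self.cell_of(x[ok], y[ok])
        out[ok] = self.data[row, col]
        return out

    # -- I/O --------------------------------------------------------------
    def write_ascii(self, path: str | Path) -> None:
        """Write as an ESRI ASCII grid (plus the CRS on a trailing comment)."""
        path = Path(path)
        y_ll = self.y_origin - self.nrows * self.cell_size
        with open(path, "w") as fh:
            fh.write(f"ncols {self.ncols}\n")
            fh.write(f"nrows {self.nrows}\n")
            fh.write(f"xllcorner {self.x_origin!r}\n")
            fh.write(f"yllcorner {y_ll!r}\n")
            fh.write(f"cellsize {self.cell_size!r}\n")
            fh.write(f"NODATA_value {ASCII_NODATA!r}\n")
            filled = np.where(np.isfinite(self.data), self.data, ASCII_NODATA)
            np.savetxt(fh, filled, fmt="%.10g")
        path.with_suffix(path.suffix + ".crs").write_text(self.crs + "\n")

    @classmethod
    def read_ascii(cls, path: str | Path) -> "Raster":
        path = Path(path)
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            data = np.loadtxt(fh)
        data = np.atleast_2d(data)
        nodata = header.get("nodata_value", ASCII_NODATA)
        data[data == nodata] = np.nan
        cell = header["cellsize"]
        crs_path = path.with_suffix(path.suffix + ".crs")
        crs = crs_path.read_text().strip() if crs_path.exists() else "local-projected-metres"
        return cls(
            data=data,
            cell_size=cell,
            x_origin=header["xllcorner"],
            y_origin=header["yllcorner"] + header["nrows"] * cell,
            crs=crs,
        )


@dataclass
class CovariateStack:
    """Named covariate rasters sharing one grid, with an optional ocean mask.

    The ocean mask is 1 on ocean cells and 0 on land; covariates are defined
    everywhere so that the conductance surface can be filled seamlessly.
    """

    layers: dict[str, Raster]
    ocean: Raster | None = None

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("stack needs at least one layer")
        rasters = list(self.layers.values())
        for r in rasters[1:]:
            if not r.aligned_with(rasters[0]):
                raise ValueError("covariate rasters are not aligned")
        if self.ocean is not None and not self.ocean.aligned_with(rasters[0]):
            raise ValueError("ocean mask is not aligned with the covariates")

    @property
    def grid(self) -> Raster:
        return next(iter(self.layers.values()))

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def subset(self, names) -> "CovariateStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"covariates not in stack: {missing}")
        return CovariateStack({n: self.layers[n] for n in names}, ocean=self.ocean)

    def as_array(self, names=None) -> np.ndarray:
        """(n_layers, nrows, ncols) array in the given (or stack) order."""
        names = self.names if names is None else list(names)
        return np.stack([self.layers[n].data for n in names])

    def values_at(self, x, y, names=None) -> np.ndarray:
        """(n_points, n_layers) covariate values under each point."""
        names = self.names if names is None else list(names)
        return np.column_stack([self.layers[n].values_at(x, y) for n in names])

    def is_land(self) -> np.ndarray:
        if self.ocean is None:
            return np.ones(self.grid.shape, dtype=bool)
        return ~(self.ocean.data > 0)

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, r in self.layers.items():
            r.write_ascii(directory / f"{name}.asc")
        if self.ocean is not None:
            self.ocean.write_ascii(directory / "ocean.asc")

    @classmethod
    def read(cls, directory: str | Path, names) -> "CovariateStack":
        directory = Path(directory)
        layers = {n: Raster.read_ascii(directory / f"{n}.asc") for n in names}
        ocean_path = directory / "ocean.asc"
        ocean = Raster.read_ascii(ocean_path) if ocean_path.exists() else None
        return cls(layers, ocean=ocean)
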