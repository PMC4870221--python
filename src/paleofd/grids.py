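"""Gridded climate surfaces on a projected, equal-area plane.

A :class:`ClimateGrid` is a single-variable 2D raster (row 0 = northernmost
row) with square cells measured in km, an optional nodata mask (NaN), and
epoch / variable / month tags. Surfaces are read and written as ESRI ASCII
grids, a plain-text format every GIS stack understands.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["ClimateGrid", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class ClimateGrid:
    """One variable, one epoch, on a regular square grid.

    ``values`` uses NaN for nodata. Row index increases southward so that
    ``values[0]`` is the northern (high-latitude) edge, matching the
    conventional top-down raster layout. ``x0``/``y0`` are the coordinates
    (km) of the lower-left *corner* of the grid.
    """

    values: np.ndarray
    cell_size_km: float
    x0: float = 0.0
    y0: float = 0.0
    variable: str = "temperature"
    epoch: str = "present"
    month: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2D")
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nodata_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def same_georeference(self, other: "ClimateGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size_km, other.cell_size_km)
            and np.isclose(self.x0, other.x0)
            and np.isclose(self.y0, other.y0)
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrids (X, Y) of cell-center coordinates in km."""
        nrows, ncols = self.shape
        xs = self.x0 + (np.arange(ncols) + 0.5) * self.cell_size_km
        ys = self.y0 + (nrows - 1 - np.arange(nrows) + 0.5) * self.cell_size_km
        return np.meshgrid(xs, ys)

    def centroids(self) -> np.ndarray:
        """(n_cells, 2) array of centers in row-major order."""
        X, Y = self.cell_centers()
        return np.column_stack([X.ravel(), Y.ravel()])

    def with_values(self, values: np.ndarray, **tags) -> "ClimateGrid":
        """Copy of this grid carrying new values (and optionally new tags)."""
        return replace(self, values=np.asarray(values, dtype=float), **tags)


def write_ascii_grid(grid: ClimateGrid, path: str | Path, nodata: float = -9999.0) -> None:
    nrows, ncols = grid.shape
    vals = np.where(np.isnan(grid.values), nodata, grid.values)
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {grid.x0}\n"
        f"yllcorner {grid.y0}\n"
        f"cellsize {grid.cell_size_km}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.8g")


def read_ascii_grid(path: str | Path, **tags) -> ClimateGrid:
    with open(path) as fh:
        header: dict[str, float] = {}
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:  # data started early; optional NODATA line absent
                fh.seek(pos)
                break
        values = np.loadtxt(fh, ndmin=2)
    nodata = header.get("nodata_value")
    if nodata is not None:
        values = np.where(values == nodata, np.nan, values)
    expected = (int(header["nrows"]), int(header["ncols"]))
    if values.shape != expected:
        raise ValueError(f"grid shape {values.shape} does not match header {expected}")
    return ClimateGrid(
        values=values,
        cell_size_km=header["cellsize"],
        x0=header.get("xllcorner", 0.0),
        y0=header.get("yllcorner", 0.0),
        **tags,
    )


def _is_number(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return True
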