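"""Gridded climate data: the geographic-space (G-space) substrate.

A :class:`ClimateStack` holds one 2-D layer per climate predictor on a
shared plate-carree (unprojected lon/lat) grid.  Cells are addressed by
row (north to south) and column (west to east); NoData is represented by
NaN.  Rasters are serialized as ESRI ASCII grids (one text file per
variable) with a JSON sidecar carrying the variable list and provenance,
so a stack round-trips through plain text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Kilometres per degree of arc on the reference sphere (used for the
#: occurrence-buffer geometry; no other projection math is performed).
KM_PER_DEGREE = 111.32


@dataclass
class ClimateStack:
    """Multi-variable raster over one rectangular region.

    Parameters
    ----------
    variables:
        Ordered predictor names, e.g. ``["bio2", "bio5", ...]``.
    data:
        Array of shape ``(n_variables, n_rows, n_cols)``; NaN marks NoData.
    west, north:
        Outer edge coordinates (decimal degrees) of the top-left cell.
    cell_size:
        Cell edge length in decimal degrees (square cells).
    region:
        Optional region label carried through the pipeline.
    """

    variables: list[str]
    data: np.ndarray
    west: float
    north: float
    cell_size: float
    region: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_variables, n_rows, n_cols)")
        if self.data.shape[0] != len(self.variables):
            raise ValueError("one layer per variable required")
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("variable names must be unique")
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")

    # -- geometry ----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def south(self) -> float:
        return self.north - self.shape[0] * self.cell_size

    @property
    def east(self) -> float:
        return self.west + self.shape[1] * self.cell_size

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of shape (n_rows, n_cols) at cell centres."""
        ny, nx = self.shape
        lon = self.west + (np.arange(nx) + 0.5) * self.cell_size
        lat = self.north - (np.arange(ny) + 0.5) * self.cell_size
        return np.meshgrid(lon, lat)

    def index_of(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Row/column of the cell containing each point.

        Cells are half-open intervals ``[edge, edge + cell_size)`` in lon
        and ``(edge - cell_size, edge]`` going south in lat, so boundary
        points are assigned deterministically.  Out-of-extent points get
        index -1.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.west) / self.cell_size).astype(int)
        row = np.floor((self.north - lat) / self.cell_size).astype(int)
        ny, nx = self.shape
        bad = (col < 0) | (col >= nx) | (row < 0) | (row >= ny)
        col = np.where(bad, -1, col)
        row = np.where(bad, -1, row)
        return row, col

    def values_at(self, lon, lat) -> np.ndarray:
        """Climate vectors (n_points, n_variables) at point locations.

        Out-of-extent points get all-NaN rows.
        """
        row, col = self.index_of(lon, lat)
        out = np.full((len(np.atleast_1d(row)), len(self.variables)), np.nan)
        row = np.atleast_1d(row)
        col = np.atleast_1d(col)
        ok = row >= 0
        out[ok] = self.data[:, row[ok], col[ok]].T
        return out

    def land_mask(self) -> np.ndarray:
        """Boolean (n_rows, n_cols): cells with data in every layer."""
        return ~np.isnan(self.data).any(axis=0)

    def table(self) -> np.ndarray:
        """Climate vectors of all valid cells, shape (n_cells, n_vars)."""
        mask = self.land_mask()
        return self.data[:, mask].T

    # -- serialization -----------------------------------------------------
    def write(self, directory: str | Path) -> None:
        """Write one ASCII grid per variable plus a JSON sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, name in enumerate(self.variables):
            write_ascii_grid(
                directory / f"{name}.asc",
                self.data[i],
                west=self.west,
                south=self.south,
                cell_size=self.cell_size,
            )
        sidecar = {
            "region": self.region,
            "variables": self.variables,
            "west": self.west,
            "north": self.north,
            "cell_size": self.cell_size,
            "meta": self.meta,
        }
        (directory / "stack.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def read(cls, directory: str | Path) -> "ClimateStack":
        directory = Path(directory)
        sidecar = json.loads((directory / "stack.json").read_text())
        layers = [read_ascii_grid(directory / f"{v}.asc")[0] for v in sidecar["variables"]]
        return cls(
            variables=sidecar["variables"],
            data=np.stack(layers),
            west=sidecar["west"],
            north=sidecar["north"],
            cell_size=sidecar["cell_size"],
            region=sidecar.get("region", ""),
            meta=sidecar.get("meta", {}),
        )


NODATA = -9999.0


def write_ascii_grid(path: str | Path, grid: np.ndarray, *, west: float,
                     south: float, cell_size: float) -> None:
    """Write a single layer as an ESRI ASCII grid (NaN -> -9999)."""
    grid = np.asarray(grid, dtype=float)
    ny, nx = grid.shape
    header = (
        f"ncols {nx}\nnrows {ny}\nxllcorner {west!r}\nyllcorner {south!r}\n"
        f"cellsize {cell_size!r}\nNODATA_value {NODATA}\n"
    )
    body = np.where(np.isnan(grid), NODATA, grid)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid; returns (array with NaN NoData, header)."""
    header: dict = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        grid = np.loadtxt(fh)
    grid = np.atleast_2d(grid)
    nodata = header.get("nodata_value", NODATA)
    grid[grid == nodata] = np.nan
    return grid, header
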