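"""Regular-grid raster containers and ESRI ASCII grid I/O.

Rasters are stored row-major with row 0 at the top (north), matching the
ESRI ASCII on-disk layout. ``origin`` is the (x, y) of the lower-left
corner in meters; cell centers are at ``origin + (col + 0.5) * cell_size``
horizontally and ``origin_y + (n_rows - row - 0.5) * cell_size`` vertically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Raster", "SuitabilitySurface", "ResistanceSurface"]

_NODATA = -9999.0


@dataclass
class Raster:
    """A single-band raster on a square-cell regular grid."""

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("raster grid must be 2-D and non-empty")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster footprint in meters."""
        x0, y0 = self.origin
        return (x0, y0, x0 + self.n_cols * self.cell_size, y0 + self.n_rows * self.cell_size)

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.extent
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)

    def xy_to_rowcol(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map point coordinates to the (row, col) of the containing cell."""
        x0, y0 = self.origin
        col = np.floor((np.asarray(x, dtype=float) - x0) / self.cell_size).astype(int)
        row = self.n_rows - 1 - np.floor((np.asarray(y, dtype=float) - y0) / self.cell_size).astype(int)
        if np.any((row < 0) | (row >= self.n_rows) | (col < 0) | (col >= self.n_cols)):
            raise ValueError("coordinates fall outside the raster extent")
        return row, col

    def rowcol_to_xy(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Cell-center coordinates of (row, col)."""
        x0, y0 = self.origin
        x = x0 + (np.asarray(col) + 0.5) * self.cell_size
        y = y0 + (self.n_rows - np.asarray(row) - 0.5) * self.cell_size
        return x, y

    def write_ascii(self, path: str | Path, nodata: float = _NODATA) -> None:
        """Write as an ESRI ASCII grid; NaN cells become the nodata value."""
        vals = np.where(np.isnan(self.values), nodata, self.values)
        header = (
            f"ncols {self.n_cols}\n"
            f"nrows {self.n_rows}\n"
            f"xllcorner {self.origin[0]:.6f}\n"
            f"yllcorner {self.origin[1]:.6f}\n"
            f"cellsize {self.cell_size:.6f}\n"
            f"NODATA_value {nodata:g}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt="%.8g")

    @classmethod
    def read_ascii(cls, path: str | Path) -> "Raster":
        with open(path) as fh:
            header: dict[str, float] = {}
            pos = fh.tell()
            for _ in range(6):
                pos = fh.tell()
                line = fh.readline()
                key, _, val = line.strip().partition(" ")
                key = key.lower()
                if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                    header[key] = float(val)
                else:
                    fh.seek(pos)
                    break
            vals = np.loadtxt(fh, ndmin=2)
        nodata = header.get("nodata_value", _NODATA)
        vals = np.where(vals == nodata, np.nan, vals)
        if vals.shape != (int(header["nrows"]), int(header["ncols"])):
            raise ValueError("ESRI ASCII grid body does not match its header dimensions")
        return cls(vals, header["cellsize"], (header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)))


@dataclass
class SuitabilitySurface(Raster):
    """Habitat suitability in [0, 1]."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.nanmin(self.values) < 0 or np.nanmax(self.values) > 1:
            raise ValueError("suitability values must lie in [0, 1]")


@dataclass
class ResistanceSurface(Raster):
    """Movement resistance, a dimensionless per-meter cost multiplier.

    Bounded in [r_min, r_max] (default [1, 10]); a uniform surface of 1
    represents the isolation-by-distance null landscape.
    """

    r_min: float = 1.0
    r_max: float = 10.0

    def __post_init__(self) -> None:
        super().__post_init__()
        eps = 1e-9
        if np.nanmin(self.values) < self.r_min - eps or np.nanmax(self.values) > self.r_max + eps:
            raise ValueError(f"resistance values must lie in [{self.r_min}, {self.r_max}]")
        if np.isnan(self.values).any():
            raise ValueError("resistance surface must not contain NaN")

    @classmethod
    def uniform(cls, like: Raster, value: float = 1.0) -> "ResistanceSurface":
        """Uniform-resistance surface with the geometry of ``like``."""
        return cls(np.full((like.n_rows, like.n_cols), float(value)), like.cell_size, like.origin)
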