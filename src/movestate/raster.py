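"""Minimal single-band raster grid with plain-text (ESRI ASCII grid) I/O.

Coordinates are projected meters. Values are looked up with nearest-cell
(piecewise-constant) semantics: the value at (x, y) is the value of the cell
whose square contains the point. Row 0 of ``values`` is the northernmost row,
matching the ASCII-grid convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["Raster"]


@dataclass
class Raster:
    values: np.ndarray  # shape (nrow, ncol); row 0 = north
    x0: float  # west edge (xllcorner)
    y0: float  # south edge (yllcorner)
    res: float  # cell size, meters

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.res <= 0:
            raise ValueError("cell size must be positive")

    @property
    def nrow(self) -> int:
        return self.values.shape[0]

    @property
    def ncol(self) -> int:
        return self.values.shape[1]

    @property
    def x1(self) -> float:
        return self.x0 + self.ncol * self.res

    @property
    def y1(self) -> float:
        return self.y0 + self.nrow * self.res

    def cell_index(self, x, y):
        """Row/col of the cell containing each point; no bounds check."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.res).astype(int)
        row = self.nrow - 1 - np.floor((y - self.y0) / self.res).astype(int)
        # points exactly on the east/north edge belong to the last cell
        col = np.clip(col, None, self.ncol - 1)
        row = np.clip(row, 0, None)
        return row, col

    def contains(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= self.x0) & (x <= self.x1) & (y >= self.y0) & (y <= self.y1)

    def value_at(self, x, y):
        inside = self.contains(x, y)
        if not np.all(inside):
            raise ValueError(
                f"{int(np.sum(~inside))} point(s) outside raster extent "
                f"[{self.x0}, {self.x1}] x [{self.y0}, {self.y1}]"
            )
        row, col = self.cell_index(x, y)
        return self.values[row, col]

    def cell_centers(self):
        """(X, Y) meshgrid of cell-center coordinates, same shape as values."""
        xs = self.x0 + (np.arange(self.ncol) + 0.5) * self.res
        ys = self.y1 - (np.arange(self.nrow) + 0.5) * self.res
        return np.meshgrid(xs, ys)

    # -- text I/O ---------------------------------------------------------

    def write_ascii(self, path) -> None:
        header = (
            f"ncols {self.ncol}\n"
            f"nrows {self.nrow}\n"
            f"xllcorner {self.x0!r}\n"
            f"yllcorner {self.y0!r}\n"
            f"cellsize {self.res!r}\n"
            f"NODATA_value -9999\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.values, fmt="%.6f")

    @classmethod
    def read_ascii(cls, path) -> "Raster":
        path = Path(path)
        meta: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                meta[key.lower()] = float(val)
            values = np.loadtxt(fh)
        values = np.atleast_2d(values)
        if values.shape != (int(meta["nrows"]), int(meta["ncols"])):
            raise ValueError(f"grid shape mismatch in {path}")
        return cls(
            values=values,
            x0=meta["xllcorner"],
            y0=meta["yllcorner"],
            res=meta["cellsize"],
        )
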