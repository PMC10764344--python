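"""Minimal single-band raster container with plain-text (ESRI ASCII grid) I/O.

Grids live in a projected metric CRS with km units throughout the package:
``x = xll + (col + 0.5) * cellsize`` gives cell-center coordinates, row 0 is
the *top* row (standard ASCII-grid row order).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NODATA = -9999.0


@dataclass
class Raster:
    """A single-band float raster on a regular square grid.

    Parameters
    ----------
    data
        2-D float array; NaN marks nodata in memory.
    xll, yll
        Coordinates of the lower-left corner of the grid (km).
    cellsize
        Cell edge length (km).
    """

    data: np.ndarray
    xll: float = 0.0
    yll: float = 0.0
    cellsize: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) arrays of cell-center coordinates, same shape as data."""
        nrows, ncols = self.data.shape
        x = self.xll + (np.arange(ncols) + 0.5) * self.cellsize
        y = self.yll + (nrows - np.arange(nrows) - 0.5) * self.cellsize
        return np.meshgrid(x, y)

    def same_grid(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.xll, other.xll)
            and np.isclose(self.yll, other.yll)
            and np.isclose(self.cellsize, other.cellsize)
        )

    def copy(self) -> "Raster":
        return Raster(self.data.copy(), self.xll, self.yll, self.cellsize)


def write_ascii(raster: Raster, path) -> None:
    """Write an ESRI ASCII grid; NaN cells become the nodata sentinel.

    Values are formatted with %.17g so float64 round-trips bitwise.
    """
    nrows, ncols = raster.shape
    body = raster.data.copy()
    body[np.isnan(body)] = NODATA
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {raster.xll!r}\n")
        fh.write(f"yllcorner {raster.yll!r}\n")
        fh.write(f"cellsize {raster.cellsize!r}\n")
        fh.write(f"NODATA_value {NODATA!r}\n")
        for row in body:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def read_ascii(path) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii` (or compatible)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines[:6]:
        key, val = line.split()
        header[key.lower()] = float(val)
    data = np.loadtxt(lines[6:], dtype=float)
    data = np.atleast_2d(data)
    nodata = header.get("nodata_value", NODATA)
    data[data == nodata] = np.nan
    return Raster(
        data,
        xll=header.get("xllcorner", 0.0),
        yll=header.get("yllcorner", 0.0),
        cellsize=header.get("cellsize", 1.0),
    )
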