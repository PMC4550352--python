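"""Minimal elevation-raster support: ESRI ASCII grid I/O and line relief.

The only raster operation the analysis needs is the relief (max minus min
elevation) along the straight line between two sites, which feeds the
overland altitudinal distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = ["ElevationRaster", "line_relief", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class ElevationRaster:
    """Regular elevation grid.

    ``grid`` is stored with row 0 at the *north* (top), as in ESRI ASCII
    files; ``x0``/``y0`` are the coordinates of the lower-left corner.
    """

    x0: float
    y0: float
    cellsize: float
    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2-D")
        if not self.cellsize > 0:
            raise ValueError("cell size must be positive")

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the cell-center lattice."""
        nrows, ncols = self.grid.shape
        half = self.cellsize / 2.0
        return (
            self.x0 + half,
            self.x0 + half + (ncols - 1) * self.cellsize,
            self.y0 + half,
            self.y0 + half + (nrows - 1) * self.cellsize,
        )

    def interpolator(self) -> RegularGridInterpolator:
        nrows, ncols = self.grid.shape
        half = self.cellsize / 2.0
        xs = self.x0 + half + np.arange(ncols) * self.cellsize
        ys = self.y0 + half + np.arange(nrows) * self.cellsize
        # grid row 0 is north: flip so ys ascend with row index
        return RegularGridInterpolator(
            (ys, xs), self.grid[::-1, :], method="linear", bounds_error=True
        )


def line_relief(raster: ElevationRaster, p_start, p_end, step: float | None = None) -> float:
    """Relief along the straight segment from ``p_start`` to ``p_end``.

    Elevations are sampled by bilinear interpolation at points spaced at
    most ``step`` apart (endpoints always included; ``step`` defaults to
    the raster cell size); the relief is max minus min of the samples.

    Raises
    ------
    ValueError
        If either endpoint falls outside the raster's interpolable extent.
    """
    if step is None:
        step = raster.cellsize
    if not step > 0:
        raise ValueError("step must be positive")
    p0 = np.asarray(p_start, dtype=float)
    p1 = np.asarray(p_end, dtype=float)
    length = float(np.hypot(*(p1 - p0)))
    n = max(1, int(np.ceil(length / step)))
    t = np.linspace(0.0, 1.0, n + 1)
    pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    interp = raster.interpolator()
    try:
        z = interp(pts[:, ::-1])  # interpolator wants (y, x)
    except ValueError as exc:
        raise ValueError(f"sample point outside raster extent: {exc}") from None
    return float(z.max() - z.min())


def read_ascii_grid(path) -> ElevationRaster:
    """Read an ESRI ASCII grid (.asc)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    data = np.loadtxt(lines[i:].__iter__())
    grid = np.asarray(data, dtype=float).reshape(
        int(header["nrows"]), int(header["ncols"])
    )
    return ElevationRaster(
        x0=header["xllcorner"], y0=header["yllcorner"],
        cellsize=header["cellsize"], grid=grid,
    )


def write_ascii_grid(raster: ElevationRaster, path) -> None:
    nrows, ncols = raster.grid.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {raster.x0}\n")
        fh.write(f"yllcorner {raster.y0}\n")
        fh.write(f"cellsize {raster.cellsize}\n")
        fh.write("NODATA_value -9999\n")
        np.savetxt(fh, raster.grid, fmt="%.3f")
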