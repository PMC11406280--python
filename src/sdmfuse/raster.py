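"""Minimal georeferenced raster container and TIFF + JSON-sidecar I/O.

Rasters are stored band-major ``(bands, rows, cols)`` with a six-parameter
affine geotransform mapping fractional pixel indices to projected
coordinates.  The convention is the usual north-up raster one: row-major,
origin at the top-left corner, 0-based indices, half-open pixel cells
``[x_lo, x_hi)`` so every point belongs to exactly one pixel.

Pixel data are written with :mod:`tifffile`; the geotransform, CRS, nodata
value and band names travel in a ``.json`` sidecar next to the TIFF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


@dataclass(frozen=True)
class GridTransform:
    """Affine geotransform ``(x, y) = origin + indices * pixel size``.

    ``x0, y0`` locate the outer corner of pixel (0, 0); ``dx > 0`` and
    ``dy < 0`` for the common north-up case.
    """

    x0: float
    y0: float
    dx: float
    dy: float

    def xy(self, row, col):
        """Projected coordinates of fractional pixel indices.

        Integer indices give the pixel's top-left corner; add 0.5 to each
        index for the pixel center.
        """
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        return self.x0 + col * self.dx, self.y0 + row * self.dy

    def rowcol(self, x, y):
        """Integer pixel indices of the half-open cell containing (x, y)."""
        col = np.floor((np.asarray(x, dtype=float) - self.x0) / self.dx)
        row = np.floor((np.asarray(y, dtype=float) - self.y0) / self.dy)
        return row.astype(int), col.astype(int)

    def to_list(self) -> list[float]:
        return [self.x0, self.y0, self.dx, self.dy]


@dataclass
class Raster:
    """A stack of co-registered bands with a geotransform and CRS id."""

    data: np.ndarray  # (bands, rows, cols)
    transform: GridTransform
    crs: str
    nodata: float | None = None
    band_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError("raster data must be (bands, rows, cols)")

    @property
    def n_bands(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    @property
    def resolution(self) -> float:
        return abs(self.transform.dx)

    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full grid."""
        rows, cols = self.shape
        xs = (self.transform.x0, self.transform.x0 + cols * self.transform.dx)
        ys = (self.transform.y0, self.transform.y0 + rows * self.transform.dy)
        return min(xs), min(ys), max(xs), max(ys)

    def contains(self, x, y) -> np.ndarray:
        """True where (x, y) falls inside the grid and on valid data."""
        row, col = self.transform.rowcol(x, y)
        rows, cols = self.shape
        ok = (row >= 0) & (row < rows) & (col >= 0) & (col < cols)
        if self.nodata is not None and np.any(ok):
            r = np.where(ok, row, 0)
            c = np.where(ok, col, 0)
            valid = ~np.any(self.data[:, r, c] == self.nodata, axis=0)
            ok = ok & valid
        return ok

    def sample(self, x, y) -> np.ndarray:
        """Band values of the pixel containing each point, shape (n, bands)."""
        row, col = self.transform.rowcol(x, y)
        return np.moveaxis(self.data[:, row, col], 0, -1)


def write_raster(path: str | Path, raster: Raster) -> None:
    """Write pixel data as TIFF plus a JSON georeferencing sidecar."""
    path = Path(path)
    tifffile.imwrite(path, raster.data, photometric="minisblack")
    meta = {
        "transform": raster.transform.to_list(),
        "crs": raster.crs,
        "nodata": raster.nodata,
        "band_names": raster.band_names,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_raster(path: str | Path) -> Raster:
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"georeferencing sidecar missing: {sidecar}")
    meta = json.loads(sidecar.read_text())
    x0, y0, dx, dy = meta["transform"]
    return Raster(
        data=data,
        transform=GridTransform(x0, y0, dx, dy),
        crs=meta["crs"],
        nodata=meta.get("nodata"),
        band_names=meta.get("band_names") or [],
    )


def block_average(data: np.ndarray, block: int) -> np.ndarray:
    """Mean over non-overlapping ``block`` x ``block`` pixel tiles.

    Trailing rows/cols that do not fill a whole tile are trimmed.
    """
    if block < 1:
        raise ValueError("block must be >= 1")
    b, rows, cols = data.shape
    r = (rows // block) * block
    c = (cols // block) * block
    trimmed = data[:, :r, :c].astype(float)
    return trimmed.reshape(b, r // block, block, c // block, block).mean(axis=(2, 4))
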