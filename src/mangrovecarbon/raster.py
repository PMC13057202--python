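"""Lightweight georeferenced raster container and TIFF-based I/O.

A :class:`Raster` is a single-band grid of float values with an affine
transform mapping (col, row) pixel indices to projected coordinates, a
nodata sentinel, and an opaque CRS tag.  Rasters are row-major with the
origin at the top-left corner; coordinates are in metres.

Files are written as plain TIFF (via :mod:`tifffile`) with the transform,
nodata value and CRS tag in a ``.json`` sidecar next to the image, so
every layer round-trips without a GIS stack.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

NODATA = -9999.0


@dataclass(frozen=True)
class Affine:
    """Affine transform ``x = a*col + c``, ``y = e*row + f`` (axis-aligned).

    ``a`` is the pixel width (m), ``e`` the pixel height (negative for the
    usual north-up raster), ``(c, f)`` the coordinates of the top-left
    corner of the top-left pixel.
    """

    a: float
    c: float
    e: float
    f: float

    @classmethod
    def from_origin(cls, west: float, north: float, pixel_size: float) -> "Affine":
        return cls(a=pixel_size, c=west, e=-pixel_size, f=north)

    def xy(self, row, col, offset: str = "center"):
        """Projected coordinates of a pixel (default: its centre)."""
        shift = 0.5 if offset == "center" else 0.0
        x = self.c + (np.asarray(col) + shift) * self.a
        y = self.f + (np.asarray(row) + shift) * self.e
        return x, y

    def rowcol(self, x, y):
        """Pixel indices containing projected coordinates (floor rule)."""
        col = np.floor((np.asarray(x) - self.c) / self.a).astype(int)
        row = np.floor((np.asarray(y) - self.f) / self.e).astype(int)
        return row, col

    def to_list(self) -> list[float]:
        return [self.a, 0.0, self.c, 0.0, self.e, self.f]

    @classmethod
    def from_list(cls, v) -> "Affine":
        return cls(a=v[0], c=v[2], e=v[4], f=v[5])


@dataclass
class Raster:
    """Single-band raster: float array + transform + nodata mask."""

    values: np.ndarray
    transform: Affine
    nodata: float = NODATA
    crs_tag: str = "local-metric"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def pixel_size(self) -> float:
        return abs(self.transform.a)

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of valid (non-nodata, finite) pixels."""
        v = self.values
        return np.isfinite(v) & (v != self.nodata)

    def masked(self) -> np.ndarray:
        """Values with nodata replaced by NaN."""
        out = self.values.copy()
        out[~self.mask] = np.nan
        return out

    def like(self, values: np.ndarray) -> "Raster":
        """New raster sharing this one's grid."""
        values = np.asarray(values, dtype=np.float64)
        if values.shape != self.shape:
            raise ValueError(
                f"shape mismatch: {values.shape} vs {self.shape}"
            )
        return Raster(values, self.transform, self.nodata, self.crs_tag)

    def same_grid(self, other: "Raster") -> bool:
        return self.shape == other.shape and self.transform == other.transform

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of every pixel centre."""
        rows, cols = np.indices(self.shape)
        return self.transform.xy(rows, cols)


def write_raster(path: str | Path, raster: Raster) -> None:
    """Write a raster as float32 TIFF plus a JSON georeferencing sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, raster.values.astype(np.float32))
    meta = {
        "transform": raster.transform.to_list(),
        "nodata": raster.nodata,
        "crs_tag": raster.crs_tag,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=1) + "\n"
    )


def read_raster(path: str | Path) -> Raster:
    path = Path(path)
    values = np.asarray(tifffile.imread(path), dtype=np.float64)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return Raster(
        values,
        Affine.from_list(meta["transform"]),
        nodata=meta["nodata"],
        crs_tag=meta["crs_tag"],
    )


def write_multiband(path: str | Path, rasters: dict[str, Raster]) -> None:
    """Write co-registered rasters as a multi-band TIFF (band order = dict order)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    names = list(rasters)
    first = rasters[names[0]]
    for r in rasters.values():
        if not first.same_grid(r):
            raise ValueError("all bands must share grid")
    stack = np.stack([rasters[n].values for n in names]).astype(np.float32)
    tifffile.imwrite(path, stack, photometric="minisblack")
    meta = {
        "bands": names,
        "transform": first.transform.to_list(),
        "nodata": first.nodata,
        "crs_tag": first.crs_tag,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=1) + "\n"
    )


def read_multiband(path: str | Path) -> dict[str, Raster]:
    path = Path(path)
    stack = np.asarray(tifffile.imread(path), dtype=np.float64)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    tr = Affine.from_list(meta["transform"])
    return {
        name: Raster(stack[i], tr, nodata=meta["nodata"], crs_tag=meta["crs_tag"])
        for i, name in enumerate(meta["bands"])
    }
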