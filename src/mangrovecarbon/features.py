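"""Spectral, structural and textural feature layers.

Three feature families feed species classification and carbon modelling:

* **spectral** — the five reflectance bands plus nine vegetation indices
  (NDVI/GNDVI/NDRE/OSAVI/LCI and the ratio family RVI/MACI/VREI/SR);
* **structural** — canopy height (``H_Mean``), the difference between the
  digital surface model and a terrain model interpolated from ground
  control points by inverse distance weighting (IDW);
* **textural** — eight grey-level co-occurrence matrix (GLCM) metrics
  (Con, Cor, Dis, Ent, Hom, Mean, Asm, Var) per band, from a moving
  window over the globally quantized image.

All 55 canonical layer names live in :data:`CANONICAL_FEATURES`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree

from .raster import Affine, Raster
from .synthetic import BANDS, Scene

GLCM_METRICS = ("Con", "Cor", "Dis", "Ent", "Hom", "Mean", "Asm", "Var")

#: Index formulas over band arrays; every formula is config-overridable.
INDEX_FORMULAS: dict[str, Callable[..., np.ndarray]] = {
    "NDVI": lambda B, G, R, RE, NIR: (NIR - R) / (NIR + R),
    "GNDVI": lambda B, G, R, RE, NIR: (NIR - G) / (NIR + G),
    "NDRE": lambda B, G, R, RE, NIR: (NIR - RE) / (NIR + RE),
    "OSAVI": lambda B, G, R, RE, NIR: (NIR - R) / (NIR + R + 0.16),
    "LCI": lambda B, G, R, RE, NIR: (NIR - RE) / (NIR + R),
    "RVI": lambda B, G, R, RE, NIR: NIR / R,
    "MACI": lambda B, G, R, RE, NIR: NIR / G,
    "VREI": lambda B, G, R, RE, NIR: NIR / RE,
    "SR": lambda B, G, R, RE, NIR: NIR / B,
}

VEGETATION_INDICES = tuple(INDEX_FORMULAS)

CANONICAL_FEATURES: tuple[str, ...] = (
    BANDS
    + VEGETATION_INDICES
    + ("H_Mean",)
    + tuple(f"{band}_{metric}" for band in BANDS for metric in GLCM_METRICS)
)


# --------------------------------------------------------------------------
# resampling

def resample(raster: Raster, target_pixel_size: float) -> Raster:
    """Block-mean aggregation to a coarser grid.

    The target must be an integer multiple of the native pixel size
    (upsampling is out of scope).  A coarse pixel becomes nodata when
    more than half of its contributing pixels are nodata.
    """
    native = raster.pixel_size
    ratio = target_pixel_size / native
    factor = int(round(ratio))
    if target_pixel_size < native - 1e-12:
        raise ValueError("upsampling not supported: target finer than native")
    if abs(ratio - factor) > 1e-6:
        raise ValueError(
            f"target pixel size must be an integer multiple of native "
            f"({target_pixel_size} / {native})"
        )
    if factor == 1:
        return raster.like(raster.values.copy())
    rows, cols = raster.shape
    nr, nc = rows // factor, cols // factor
    v = raster.values[: nr * factor, : nc * factor]
    m = raster.mask[: nr * factor, : nc * factor]
    vb = np.where(m, v, 0.0).reshape(nr, factor, nc, factor)
    mb = m.reshape(nr, factor, nc, factor)
    nvalid = mb.sum(axis=(1, 3))
    with np.errstate(invalid="ignore"):
        mean = vb.sum(axis=(1, 3)) / nvalid
    out = np.where(nvalid >= factor * factor / 2, mean, raster.nodata)
    tr = raster.transform
    new_tr = Affine(a=tr.a * factor, c=tr.c, e=tr.e * factor, f=tr.f)
    return Raster(out, new_tr, raster.nodata, raster.crs_tag)


# --------------------------------------------------------------------------
# spectral indices

def compute_index(
    scene: Scene,
    index_name: str,
    formulas: dict[str, Callable] | None = None,
) -> Raster:
    """Pixel-wise vegetation index; division-by-zero pixels become nodata."""
    formulas = INDEX_FORMULAS if formulas is None else formulas
    if index_name not in formulas:
        raise ValueError(f"unknown index {index_name!r}")
    arrays = {b: scene.bands[b].values for b in BANDS}
    with np.errstate(divide="ignore", invalid="ignore"):
        out = formulas[index_name](**arrays)
    ref = scene.bands["B"]
    bad = ~np.isfinite(out)
    for b in BANDS:
        bad |= ~scene.bands[b].mask
    out = np.where(bad, ref.nodata, out)
    return ref.like(out)


# --------------------------------------------------------------------------
# IDW terrain interpolation

class GCPTable:
    """Ground-control-point table: surveyed (x, y, z) triples."""

    def __init__(self, df: pd.DataFrame):
        missing = {"x", "y", "z"} - set(df.columns)
        if missing:
            raise ValueError(f"GCP table missing columns {sorted(missing)}")
        if len(df) < 4:
            raise ValueError("need at least 4 GCPs")
        if df.duplicated(subset=["x", "y"]).any():
            raise ValueError("duplicate (x, y) GCP locations")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def xy(self) -> np.ndarray:
        return self.df[["x", "y"]].to_numpy(float)

    @property
    def z(self) -> np.ndarray:
        return self.df["z"].to_numpy(float)


def idw_at_points(
    gcps: GCPTable, points: np.ndarray, power: float, n_points: int
) -> np.ndarray:
    """IDW prediction ẑ = Σ wᵢzᵢ / Σ wᵢ, wᵢ = dᵢ⁻ᵖ over the n nearest GCPs.

    A query closer than 1e-9 to a GCP returns that GCP's z exactly.
    """
    if power <= 0:
        raise ValueError("power must be positive")
    if not 1 <= n_points <= len(gcps):
        raise ValueError("n_points must be in [1, number of GCPs]")
    tree = cKDTree(gcps.xy)
    pts = np.atleast_2d(points)
    d, idx = tree.query(pts, k=n_points)
    d = np.asarray(d, dtype=float).reshape(len(pts), n_points)
    idx = np.asarray(idx).reshape(len(pts), n_points)
    zn = gcps.z[idx]
    exact = d[:, 0] < 1e-9
    with np.errstate(divide="ignore"):
        w = d ** (-power)
    w[~np.isfinite(w)] = 0.0
    denom = w.sum(axis=1)
    denom[denom == 0] = 1.0
    zhat = (w * zn).sum(axis=1) / denom
    zhat[exact] = zn[exact, 0]
    return zhat


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned target grid: top-left corner and size in pixels."""

    west: float
    north: float
    rows: int
    cols: int


def idw_interpolate(
    gcps: GCPTable,
    grid: GridSpec,
    power: float = 3.0,
    n_points: int = 3,
    pixel_size: float = 3.5,
) -> Raster:
    """Interpolate a DTM raster from GCP elevations."""
    tr = Affine.from_origin(grid.west, grid.north, pixel_size)
    rows, cols = np.indices((grid.rows, grid.cols))
    x, y = tr.xy(rows, cols)
    pts = np.column_stack([x.ravel(), y.ravel()])
    z = idw_at_points(gcps, pts, power, n_points)
    return Raster(z.reshape(grid.rows, grid.cols), tr)


def select_idw_params(
    gcps: GCPTable,
    pixel_sizes: Sequence[float],
    powers: Sequence[float],
    n_points_options: Sequence[int],
) -> tuple[dict, pd.DataFrame]:
    """Leave-one-GCP-out RMSE over a candidate grid; returns argmin + table.

    Each held-out GCP is predicted from the remaining ones at the centre
    of its cell in a grid of the candidate pixel size (how pixel size
    enters the DTM accuracy).  Ties break toward smaller power, then
    fewer points, then finer pixels.
    """
    if len(gcps) < 5:
        raise ValueError("need at least 5 GCPs for leave-one-out selection")
    if not (len(pixel_sizes) and len(powers) and len(n_points_options)):
        raise ValueError("candidate grid is empty")
    xy, z = gcps.xy, gcps.z
    if np.allclose(np.linalg.matrix_rank(xy - xy.mean(0)), 1):
        raise ValueError("degenerate GCP geometry: all points collinear")
    records = []
    for ps in pixel_sizes:
        # snap each query to its cell centre at this pixel size
        snapped = (np.floor(xy / ps) + 0.5) * ps
        for power in powers:
            for npts in n_points_options:
                if npts > len(gcps) - 1:
                    continue
                errs = np.empty(len(gcps))
                for i in range(len(gcps)):
                    rest = GCPTable(
                        gcps.df.drop(index=i).reset_index(drop=True)
                    )
                    zhat = idw_at_points(rest, snapped[i], power, npts)
                    errs[i] = zhat[0] - z[i]
                records.append(
                    dict(pixel_size=ps, power=power, n_points=npts,
                         rmse=float(np.sqrt(np.mean(errs**2))))
                )
    table = pd.DataFrame(records)
    best = table.sort_values(
        ["rmse", "power", "n_points", "pixel_size"], kind="stable"
    ).iloc[0]
    params = dict(pixel_size=float(best.pixel_size), power=float(best.power),
                  n_points=int(best.n_points), rmse=float(best.rmse))
    return params, table


# --------------------------------------------------------------------------
# canopy height

def compute_chm(dsm: Raster, dtm: Raster) -> tuple[Raster, int]:
    """CHM = DSM − DTM, negatives clamped to 0; returns (raster, clamp count)."""
    if dsm.shape != dtm.shape:
        raise ValueError(f"shape mismatch: {dsm.shape} vs {dtm.shape}")
    diff = dsm.values - dtm.values
    valid = dsm.mask & dtm.mask
    clamped = int(np.sum(valid & (diff < 0)))
    out = np.where(valid, np.clip(diff, 0.0, None), dsm.nodata)
    return dsm.like(out), clamped


# --------------------------------------------------------------------------
# GLCM textures

DEFAULT_OFFSETS = ((0, 1), (1, 1), (1, 0), (1, -1))


def quantize(values: np.ndarray, levels: int) -> np.ndarray:
    """Global min–max quantization to integer grey levels 0..levels−1."""
    if levels < 2:
        raise ValueError("levels must be ≥ 2")
    lo = np.nanmin(values)
    hi = np.nanmax(values)
    if not np.isfinite(lo) or hi <= lo:
        return np.zeros(values.shape, dtype=np.int32)
    scaled = np.nan_to_num((values - lo) / (hi - lo), nan=0.0)
    q = np.floor(scaled * levels).astype(np.int32)
    return np.clip(q, 0, levels - 1)


def _window_glcm_kernel(q, half, levels, offsets, symmetric, out):
    H, W = q.shape
    nof = offsets.shape[0]
    counts = np.zeros((levels, levels), dtype=np.float64)
    pi = np.zeros(levels, dtype=np.float64)
    pj = np.zeros(levels, dtype=np.float64)
    for r in range(H):
        for c in range(W):
            r0 = max(0, r - half)
            r1 = min(H, r + half + 1)
            c0 = max(0, c - half)
            c1 = min(W, c + half + 1)
            for a in range(levels):
                for b in range(levels):
                    counts[a, b] = 0.0
            total = 0.0
            for k in range(nof):
                dr = offsets[k, 0]
                dc = offsets[k, 1]
                for i in range(r0, r1):
                    i2 = i + dr
                    if i2 < r0 or i2 >= r1:
                        continue
                    for j in range(c0, c1):
                        j2 = j + dc
                        if j2 < c0 or j2 >= c1:
                            continue
                        a = q[i, j]
                        b = q[i2, j2]
                        counts[a, b] += 1.0
                        total += 1.0
                        if symmetric:
                            counts[b, a] += 1.0
                            total += 1.0
            if total <= 0.0:
                for m in range(8):
                    out[m, r, c] = 0.0
                continue
            con = 0.0
            dis = 0.0
            hom = 0.0
            asm_ = 0.0
            ent = 0.0
            for a in range(levels):
                pi[a] = 0.0
                pj[a] = 0.0
            for a in range(levels):
                for b in range(levels):
                    p = counts[a, b] / total
                    if p > 0.0:
                        d = a - b
                        con += p * d * d
                        dis += p * abs(d)
                        hom += p / (1.0 + d * d)
                        asm_ += p * p
                        ent -= p * math.log(p)
                        pi[a] += p
                        pj[b] += p
            mui = 0.0
            muj = 0.0
            for a in range(levels):
                mui += a * pi[a]
                muj += a * pj[a]
            vari = 0.0
            varj = 0.0
            for a in range(levels):
                vari += (a - mui) * (a - mui) * pi[a]
                varj += (a - muj) * (a - muj) * pj[a]
            cov = 0.0
            for a in range(levels):
                for b in range(levels):
                    if counts[a, b] > 0.0:
                        cov += (a - mui) * (b - muj) * counts[a, b] / total
            sig = math.sqrt(vari * varj)
            cor = cov / sig if sig > 0.0 else 0.0
            out[0, r, c] = con
            out[1, r, c] = cor
            out[2, r, c] = dis
            out[3, r, c] = ent
            out[4, r, c] = hom
            out[5, r, c] = mui
            out[6, r, c] = asm_
            out[7, r, c] = vari


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _window_glcm = njit(cache=True)(_window_glcm_kernel)
except Exception:  # pragma: no cover
    _window_glcm = _window_glcm_kernel


def glcm_metrics(
    band_raster: Raster,
    window: int = 3,
    levels: int = 64,
    offsets: Iterable[tuple[int, int]] = DEFAULT_OFFSETS,
    symmetric: bool = True,
) -> dict[str, Raster]:
    """Per-pixel GLCM metrics over a moving window.

    The raster is quantized globally (min–max over the scene) so texture
    is on one scale everywhere; co-occurrence counts are pooled over all
    offsets (and their transposes when symmetric) within the window,
    normalized, and summarized by the eight Haralick-style metrics.
    Windows are truncated at the image edge.
    """
    offsets = np.asarray(list(offsets), dtype=np.int64)
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and ≥ 3")
    if offsets.size == 0:
        raise ValueError("need at least one offset")
    rows, cols = band_raster.shape
    if window > rows or window > cols:
        raise ValueError("window larger than raster")
    q = quantize(band_raster.masked(), levels)
    out = np.empty((8, rows, cols), dtype=np.float64)
    _window_glcm(q, window // 2, levels, offsets, symmetric, out)
    return {
        metric: band_raster.like(out[m])
        for m, metric in enumerate(GLCM_METRICS)
    }


def glcm_summary(
    image: np.ndarray,
    levels: int,
    offsets: Iterable[tuple[int, int]] = ((0, 1),),
    symmetric: bool = True,
    quantize_input: bool = True,
) -> dict[str, float]:
    """The eight GLCM metrics of a whole image (single co-occurrence matrix)."""
    image = np.asarray(image)
    q = quantize(image.astype(float), levels) if quantize_input else image.astype(np.int64)
    offs = np.asarray(list(offsets), dtype=np.int64)
    counts = np.zeros((levels, levels))
    H, W = q.shape
    for dr, dc in offs:
        for i in range(H):
            i2 = i + dr
            if not 0 <= i2 < H:
                continue
            for j in range(W):
                j2 = j + dc
                if not 0 <= j2 < W:
                    continue
                counts[q[i, j], q[i2, j2]] += 1
                if symmetric:
                    counts[q[i2, j2], q[i, j]] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no co-occurring pairs for the given offsets")
    p = counts / total
    ii, jj = np.indices(p.shape)
    d = ii - jj
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    lv = np.arange(levels)
    mui = float(lv @ pi)
    muj = float(lv @ pj)
    vari = float(((lv - mui) ** 2) @ pi)
    varj = float(((lv - muj) ** 2) @ pj)
    nz = p > 0
    sig = math.sqrt(vari * varj)
    cov = float(((ii - mui) * (jj - muj) * p).sum())
    return {
        "Con": float((p * d**2).sum()),
        "Cor": cov / sig if sig > 0 else 0.0,
        "Dis": float((p * np.abs(d)).sum()),
        "Ent": float(-(p[nz] * np.log(p[nz])).sum()),
        "Hom": float((p / (1.0 + d**2)).sum()),
        "Mean": mui,
        "Asm": float((p**2).sum()),
        "Var": vari,
    }


# --------------------------------------------------------------------------
# feature stack and plot aggregation

@dataclass
class FeatureStack:
    """Named, co-registered feature layers (subset of the canonical 55)."""

    layers: dict[str, Raster]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("empty feature stack")
        bad = [n for n in self.layers if n not in CANONICAL_FEATURES]
        if bad:
            raise ValueError(f"non-canonical layer names: {bad}")
        ref = next(iter(self.layers.values()))
        for name, r in self.layers.items():
            if not ref.same_grid(r):
                raise ValueError(f"layer {name!r} not co-registered")

    def __getitem__(self, name: str) -> Raster:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    def pixel_table(self, names: Sequence[str] | None = None) -> np.ndarray:
        """(n_pixels × n_features) array in row-major pixel order."""
        names = self.names if names is None else list(names)
        return np.column_stack([self.layers[n].values.ravel() for n in names])


def build_feature_stack(
    scene: Scene,
    dtm: Raster | None = None,
    include_textures: bool = True,
    glcm_window: int = 3,
    glcm_levels: int = 64,
    glcm_offsets: Iterable[tuple[int, int]] = DEFAULT_OFFSETS,
) -> FeatureStack:
    """All feature layers for a scene: bands, indices, H_Mean, textures.

    ``dtm`` defaults to the scene's true terrain (synthetic scenes); pass
    an IDW-interpolated DTM to emulate the survey workflow.
    """
    layers: dict[str, Raster] = {b: scene.bands[b] for b in BANDS}
    for idx in VEGETATION_INDICES:
        layers[idx] = compute_index(scene, idx)
    if dtm is None:
        dtm = scene.dtm_true
    chm, _ = compute_chm(scene.dsm, dtm)
    layers["H_Mean"] = chm
    if include_textures:
        for b in BANDS:
            metrics = glcm_metrics(
                scene.bands[b], window=glcm_window, levels=glcm_levels,
                offsets=glcm_offsets,
            )
            for metric, r in metrics.items():
                layers[f"{b}_{metric}"] = r
    return FeatureStack(layers)


def aggregate_to_plots(stack: FeatureStack, plots) -> pd.DataFrame:
    """Plot-level feature table: mean of pixels whose centres fall inside.

    Membership is half-open: pixel centres on the right/top boundary of a
    plot are excluded, so adjacent plots partition pixels.  A plot that
    captures no pixel centre is an error (named).
    """
    ref = next(iter(stack.layers.values()))
    xs, ys = ref.pixel_centers()
    rows = []
    for plot in plots:
        minx, miny, maxx, maxy = plot.polygon.bounds
        inbox = (xs >= minx) & (xs < maxx) & (ys >= miny) & (ys < maxy)
        sel_r, sel_c = np.nonzero(inbox)
        if sel_r.size:
            keep = shapely.intersects_xy(
                plot.polygon, xs[sel_r, sel_c], ys[sel_r, sel_c]
            )
            sel_r, sel_c = sel_r[keep], sel_c[keep]
        if sel_r.size == 0:
            raise ValueError(
                f"plot {plot.plot_id!r} captures no pixel centres"
            )
        row = dict(plot_id=plot.plot_id, species=plot.species_id,
                   pixel_count=int(sel_r.size))
        for name, layer in stack.layers.items():
            vals = layer.values[sel_r, sel_c]
            valid = layer.mask[sel_r, sel_c]
            row[name] = float(vals[valid].mean()) if valid.any() else np.nan
        row["AGC"] = plot.agc
        row["BGC"] = plot.bgc
        rows.append(row)
    return pd.DataFrame(rows)
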