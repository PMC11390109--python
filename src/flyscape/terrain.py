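"""Uplift-proxy terrain metrics derived from a digital elevation model.

Two layers feed the step-selection model:

* **TRI** (terrain ruggedness index): per cell, the mean absolute elevation
  difference to the up-to-8 adjacent cells.  Rugged terrain generates
  mechanical turbulence and orographic lift.
* **Distance to ridge lines**: ridges are extracted from the topographic
  position index (TPI) by Weiss's landform convention (standardized TPI
  above +1 SD), then each cell gets the Euclidean distance to the nearest
  ridge cell (a proximity raster).  Ridges deflect horizontal wind upward,
  so proximity to them proxies predictable orographic uplift.

Both layers are block-averaged to a coarser analysis grid (100 m by default)
before entering the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .raster import RasterGrid

log = logging.getLogger(__name__)

_NEIGHBOR_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def compute_tri(dem: RasterGrid) -> RasterGrid:
    """Mean absolute elevation difference between each cell and its neighbors.

    Edge cells use the neighbors that exist; nodata cells propagate and are
    excluded from their neighbors' means.
    """
    z = dem.values
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("TRI needs at least a 3x3 raster")
    if not np.isfinite(z).any():
        raise ValueError("all-nodata DEM")
    nr, nc = z.shape
    acc = np.zeros_like(z)
    cnt = np.zeros_like(z)
    for dr, dc in _NEIGHBOR_OFFSETS:
        shifted = np.full_like(z, np.nan)
        rs = slice(max(dr, 0), nr + min(dr, 0))
        rt = slice(max(-dr, 0), nr + min(-dr, 0))
        cs = slice(max(dc, 0), nc + min(dc, 0))
        ct = slice(max(-dc, 0), nc + min(-dc, 0))
        shifted[rt, ct] = z[rs, cs]
        diff = np.abs(shifted - z)
        ok = np.isfinite(diff)
        acc[ok] += diff[ok]
        cnt += ok
    with np.errstate(invalid="ignore"):
        tri = np.where((cnt > 0) & np.isfinite(z), acc / np.maximum(cnt, 1), np.nan)
    return dem.like(tri)


def _annulus_offsets(cell: float, inner_m: float, outer_m: float) -> np.ndarray:
    reach = int(np.floor(outer_m / cell))
    offs = []
    for dr in range(-reach, reach + 1):
        for dc in range(-reach, reach + 1):
            d = cell * float(np.hypot(dr, dc))
            if inner_m < d <= outer_m:
                offs.append((dr, dc))
    return np.asarray(offs, dtype=int)


def compute_tpi(dem: RasterGrid, inner_radius_m: float = 10.0, outer_radius_m: float = 200.0) -> RasterGrid:
    """Topographic position index: focal elevation minus the mean elevation of
    cells whose center distance d satisfies ``inner < d <= outer``.

    Positive on locally elevated terrain (ridges, peaks), negative in valleys.
    Cells with an empty annulus (all neighbors missing) become nodata.
    """
    if not 0 <= inner_radius_m < outer_radius_m:
        raise ValueError("need 0 <= inner_radius_m < outer_radius_m")
    offs = _annulus_offsets(dem.cell_size, inner_radius_m, outer_radius_m)
    if offs.size == 0:
        raise ValueError(
            f"outer radius {outer_radius_m} m captures no neighbor at cell size {dem.cell_size} m"
        )
    reach = int(np.abs(offs).max())
    kernel = np.zeros((2 * reach + 1, 2 * reach + 1))
    kernel[offs[:, 0] + reach, offs[:, 1] + reach] = 1.0
    z = dem.values
    valid = np.isfinite(z)
    filled = np.where(valid, z, 0.0)
    sums = ndimage.convolve(filled, kernel, mode="constant", cval=0.0)
    counts = ndimage.convolve(valid.astype(float), kernel, mode="constant", cval=0.0)
    counts = np.round(counts)  # convolution of indicator values is integral
    with np.errstate(invalid="ignore", divide="ignore"):
        tpi = np.where(valid & (counts > 0), z - sums / np.maximum(counts, 1), np.nan)
    return dem.like(tpi)


def extract_ridge_mask(tpi: RasterGrid, sd_threshold: float = 1.0) -> RasterGrid:
    """Weiss landform ridge class: standardized TPI above ``sd_threshold``.

    Returns a 0/1 mask (nodata propagates).  Raises on zero-variance TPI,
    where no landform is definable.
    """
    v = tpi.values
    valid = np.isfinite(v)
    if not valid.any():
        raise ValueError("all-nodata TPI")
    mu = v[valid].mean()
    sd = v[valid].std()
    if sd < 1e-12:
        raise ValueError("TPI has zero variance; landforms are undefined")
    mask = np.where(valid, ((v - mu) / sd > sd_threshold).astype(float), np.nan)
    return tpi.like(mask)


def distance_to_ridge(ridge_mask: RasterGrid) -> RasterGrid:
    """Euclidean distance (m) from each cell center to the nearest ridge-cell center."""
    m = ridge_mask.values
    ridge = np.isfinite(m) & (m == 1.0)
    if not ridge.any():
        raise ValueError("no ridge cells in mask")
    dist = ndimage.distance_transform_edt(~ridge) * ridge_mask.cell_size
    dist = np.where(np.isfinite(m), dist, np.nan)
    return ridge_mask.like(dist)


def aggregate_to_grid(layer: RasterGrid, target_cell_m: float = 100.0) -> RasterGrid:
    """Block-mean aggregation to a coarser grid.

    ``target_cell_m`` must be an integer multiple of the source cell size.
    Partial blocks at the south/east edges average the cells they do have;
    nodata cells are excluded from block means.
    """
    ratio = target_cell_m / layer.cell_size
    k = int(round(ratio))
    if target_cell_m <= 0 or abs(ratio - k) > 1e-9 or k < 1:
        raise ValueError(
            f"target cell {target_cell_m} m is not a positive multiple of {layer.cell_size} m"
        )
    if k == 1:
        return layer.like(layer.values.copy())
    nr, nc = layer.values.shape
    pr = (-nr) % k
    pc = (-nc) % k
    padded = np.pad(layer.values, ((0, pr), (0, pc)), constant_values=np.nan)
    blocks = padded.reshape(padded.shape[0] // k, k, padded.shape[1] // k, k)
    with np.errstate(invalid="ignore"):
        sums = np.nansum(blocks, axis=(1, 3))
        cnts = np.isfinite(blocks).sum(axis=(1, 3))
    coarse = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    return RasterGrid(layer.origin_x, layer.origin_y, target_cell_m, coarse, layer.nodata)


@dataclass
class TerrainLayers:
    """All derived terrain layers of one world, native and analysis resolution."""

    tri: RasterGrid
    tpi: RasterGrid
    ridge_mask: RasterGrid
    dist_ridge: RasterGrid
    tri_100: RasterGrid
    dist_ridge_100: RasterGrid


def compute_terrain_layers(
    dem: RasterGrid,
    inner_radius_m: float = 10.0,
    outer_radius_m: float = 200.0,
    ridge_sd_threshold: float = 1.0,
    target_cell_m: float = 100.0,
) -> TerrainLayers:
    """The full terrain stage: TRI, TPI, ridge mask, ridge distance, and the
    block-averaged analysis-resolution copies of TRI and ridge distance."""
    tri = compute_tri(dem)
    tpi = compute_tpi(dem, inner_radius_m, outer_radius_m)
    ridge = extract_ridge_mask(tpi, ridge_sd_threshold)
    dist = distance_to_ridge(ridge)
    tri_100 = aggregate_to_grid(tri, target_cell_m)
    dist_100 = aggregate_to_grid(dist, target_cell_m)
    log.info(
        "terrain: %d ridge cells (%.2f%% of valid)",
        int(np.nansum(ridge.values)),
        100.0 * np.nansum(ridge.values) / max(np.isfinite(ridge.values).sum(), 1),
    )
    return TerrainLayers(tri, tpi, ridge, dist, tri_100, dist_100)
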