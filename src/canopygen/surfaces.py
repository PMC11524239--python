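"""Ground classification and DTM / DSM / CHM raster construction.

The ground filter is a per-cell lowest-point rule with a robust (MAD)
height band, a desk-scale equivalent of cloth-simulation filtering on the
gently sloped terrain this pipeline targets.  The MAD is computed about
the cell's lowest point, over points within 0.5 m of it, so canopy points
in mixed cells cannot inflate the ground band.
"""
from __future__ import annotations

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import cKDTree

from .datatypes import GROUND, NOISE, NONGROUND, PointCloud, RasterGrid
from .io import log_kv

_BASE_BAND = 0.5  # m above cell minimum used to estimate the ground MAD


def _grid_geometry(cloud: PointCloud, cell: float):
    x0 = np.floor(cloud.x.min() / cell) * cell
    y0 = np.floor(cloud.y.min() / cell) * cell
    nx = int(np.floor((cloud.x.max() - x0) / cell)) + 1
    ny = int(np.floor((cloud.y.max() - y0) / cell)) + 1
    ix = np.floor((cloud.x - x0) / cell).astype(int)
    iy = np.floor((cloud.y - y0) / cell).astype(int)
    return x0, y0, nx, ny, iy * nx + ix


def classify_ground(cloud: PointCloud, cell: float = 1.0,
                    k_mad: float = 3.0) -> PointCloud:
    """Label each point ground / non-ground; nothing is removed.

    Per cell, points within ``k_mad`` median-absolute-deviations of the
    cell's lowest point are ground.  The MAD (terrain roughness) is
    pooled: the median over cells of the per-cell MAD about the lowest
    point, so cells dominated by trunk or crown returns cannot widen
    their own ground band.  With ``k_mad=0`` (or noise-free terrain)
    only points at the exact cell minimum are ground.
    """
    cloud.require_nonempty("classify_ground")
    if cell <= 0:
        raise ValueError("cell must be > 0")
    x0, y0, nx, ny, flat = _grid_geometry(cloud, cell)
    order = np.argsort(flat, kind="stable")
    labels = np.full(len(cloud), NONGROUND)
    z = cloud.z
    bounds = np.searchsorted(flat[order], np.arange(nx * ny + 1))
    occupied = np.unique(flat)
    cell_mads = []
    dz_all = np.empty(len(cloud))
    for c in occupied:
        idx = order[bounds[c]:bounds[c + 1]]
        dz = z[idx] - z[idx].min()
        dz_all[idx] = dz
        base = dz[dz <= _BASE_BAND]
        cell_mads.append(np.median(np.abs(base)))
    pooled_mad = float(np.median(cell_mads))
    labels[dz_all <= k_mad * pooled_mad] = GROUND
    out = PointCloud(cloud.xyz, labels, cloud.tree_id)
    log_kv("classify_ground", n_ground=int((labels == GROUND).sum()),
           n_nonground=int((labels == NONGROUND).sum()))
    return out


def _fill_nodata_idw(grid: RasterGrid, k: int = 8) -> None:
    """Fill nodata cells in place by inverse-distance weighting from the
    nearest (<= k) valid cells."""
    vals = grid.values
    mask = np.isfinite(vals)
    if mask.all():
        return
    if not mask.any():
        raise ValueError("raster has no valid cells to interpolate from")
    iy, ix = np.nonzero(mask)
    tree = cKDTree(np.column_stack([ix, iy]))
    miss_iy, miss_ix = np.nonzero(~mask)
    kq = min(k, mask.sum())
    dist, nn = tree.query(np.column_stack([miss_ix, miss_iy]), k=kq)
    dist = np.atleast_2d(dist.T).T
    nn = np.atleast_2d(nn.T).T
    w = 1.0 / np.maximum(dist, 1e-12)
    src = vals[iy[nn], ix[nn]]
    vals[miss_iy, miss_ix] = (w * src).sum(axis=1) / w.sum(axis=1)


def _rasterize(cloud: PointCloud, cell: float, stat: str) -> RasterGrid:
    x0, y0, nx, ny, flat = _grid_geometry(cloud, cell)
    vals = np.full(nx * ny, np.nan)
    if stat == "max":
        np.maximum.at(vals := np.full(nx * ny, -np.inf), flat, cloud.z)
        vals[np.isinf(vals)] = np.nan
    elif stat == "mean":
        s = np.zeros(nx * ny)
        c = np.zeros(nx * ny)
        np.add.at(s, flat, cloud.z)
        np.add.at(c, flat, 1.0)
        with np.errstate(invalid="ignore"):
            vals = s / np.where(c > 0, c, np.nan)
    else:  # pragma: no cover
        raise ValueError(stat)
    return RasterGrid(x0, y0, cell, vals.reshape(ny, nx))


def build_dtm(cloud: PointCloud, cell: float = 0.25) -> RasterGrid:
    """Mean ground elevation per cell; nodata filled by IDW."""
    if cloud.class_label is None or not np.any(cloud.class_label == GROUND):
        raise ValueError("no ground points (run classify_ground first)")
    ground = cloud.subset(cloud.class_label == GROUND)
    grid = _rasterize(ground, cell, "mean")
    n_nodata = int(grid.nodata_mask.sum())
    _fill_nodata_idw(grid)
    log_kv("build_dtm", cell=cell, shape=grid.shape, filled=n_nodata)
    return grid


def build_dsm(cloud: PointCloud, cell: float = 0.25) -> RasterGrid:
    """Point-to-raster surface model: max elevation per cell, IDW-filled."""
    cloud.require_nonempty("build_dsm")
    grid = _rasterize(cloud, cell, "max")
    n_nodata = int(grid.nodata_mask.sum())
    _fill_nodata_idw(grid)
    log_kv("build_dsm", cell=cell, shape=grid.shape, filled=n_nodata)
    return grid


def build_chm(dsm: RasterGrid, dtm: RasterGrid) -> RasterGrid:
    """Canopy height model = DSM - DTM, negative values clamped to 0."""
    if not dsm.aligned_with(dtm):
        raise ValueError("DSM and DTM grids are not aligned")
    return RasterGrid(dsm.x0, dsm.y0, dsm.cell,
                      np.clip(dsm.values - dtm.values, 0.0, None))


def _dtm_interpolator(dtm: RasterGrid) -> RegularGridInterpolator:
    xs, ys = dtm.cell_centers()
    return RegularGridInterpolator((ys, xs), dtm.values, method="linear",
                                   bounds_error=False, fill_value=None)


def normalize_heights(cloud: PointCloud, dtm: RasterGrid,
                      noise_floor: float = -0.5) -> PointCloud:
    """Convert absolute elevations to height above ground.

    z is replaced by z - DTM(x, y) with bilinear interpolation between
    cell centers (nearest-edge extension inside the outermost half-cell).
    Points outside the DTM extent raise; points more than ``-noise_floor``
    below ground are flagged noise.
    """
    cloud.require_nonempty("normalize_heights")
    ny, nx = dtm.shape
    outside = ((cloud.x < dtm.x0) | (cloud.x > dtm.x0 + nx * dtm.cell)
               | (cloud.y < dtm.y0) | (cloud.y > dtm.y0 + ny * dtm.cell))
    if outside.any():
        raise ValueError(f"{int(outside.sum())} points outside the DTM extent")
    xs, ys = dtm.cell_centers()
    xq = np.clip(cloud.x, xs[0], xs[-1])
    yq = np.clip(cloud.y, ys[0], ys[-1])
    zg = _dtm_interpolator(dtm)(np.column_stack([yq, xq]))
    heights = cloud.z - zg
    labels = (cloud.class_label.copy() if cloud.class_label is not None
              else np.full(len(cloud), 0))
    n_noise = int((heights < noise_floor).sum())
    labels[heights < noise_floor] = NOISE
    out = PointCloud(np.column_stack([cloud.x, cloud.y, heights]),
                     labels, cloud.tree_id)
    log_kv("normalize_heights", n_points=len(out), n_noise=n_noise)
    return out
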