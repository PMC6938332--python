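"""Covariate derivation: focal statistics, terrain ruggedness, slope,
and the Spearman collinearity screen.

Focal windows are circular (all cells whose centres lie within the radius);
at grid edges the window shrinks, it never wraps.  Nodata cells are excluded
from every window; a window with no valid cells yields nodata.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import ndimage
from scipy.stats import spearmanr

from .raster import CovariateStack, Raster

log = logging.getLogger(__name__)


def _circular_footprint(radius_m: float, cell_size: float) -> np.ndarray:
    r_cells = radius_m / cell_size
    k = int(np.floor(r_cells))
    dr, dc = np.mgrid[-k : k + 1, -k : k + 1]
    return (dr**2 + dc**2) <= r_cells**2


def focal_statistic(raster: Raster, radius_km: float, stat: str = "mean") -> Raster:
    """Per-cell circular-window summary: ``mean``, ``median`` or ``density``.

    ``density`` is the summed value within the window times the cell area in
    km^2 — for a binary habitat raster this is the habitat area (km^2) within
    the neighbourhood.
    """
    radius_m = radius_km * 1000.0
    if radius_m < raster.cell_size:
        raise ValueError("focal radius must be at least one cell")
    fp = _circular_footprint(radius_m, raster.cell_size)
    data = raster.data
    valid = np.isfinite(data)
    filled = np.where(valid, data, 0.0)

    if stat in ("mean", "density"):
        total = ndimage.correlate(filled, fp.astype(float), mode="constant", cval=0.0)
        count = ndimage.correlate(valid.astype(float), fp.astype(float), mode="constant", cval=0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            if stat == "mean":
                out = np.where(count > 0, total / count, np.nan)
            else:
                cell_km2 = (raster.cell_size / 1000.0) ** 2
                out = np.where(count > 0, total * cell_km2, np.nan)
    elif stat == "median":
        nan_data = np.where(valid, data, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
            out = ndimage.generic_filter(
                nan_data, np.nanmedian, footprint=fp, mode="constant", cval=np.nan
            )
    else:
        raise ValueError(f"unknown focal statistic: {stat!r}")
    return raster.like(out)


def _cell_surface_area(dem: Raster) -> np.ndarray:
    """3-D surface area per cell by triangulating the cell centre with the
    midpoints toward its 8 neighbours (8 triangles whose planar projections
    tile the cell exactly, so the flat-terrain area equals the cell area)."""
    z = dem.data
    if z.shape[0] < 2 or z.shape[1] < 2:
        raise ValueError("DEM too small to estimate surface area (no neighbours)")
    d = dem.cell_size
    zp = np.pad(z, 1, mode="edge")

    # neighbour offsets ordered counter-clockwise starting east
    offsets = [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)]
    centre = np.zeros(z.shape + (3,))
    centre[..., 2] = z
    mids = []
    for dr, dc in offsets:
        zn = zp[1 + dr : 1 + dr + z.shape[0], 1 + dc : 1 + dc + z.shape[1]]
        m = np.zeros(z.shape + (3,))
        m[..., 0] = dc * d / 2.0
        m[..., 1] = -dr * d / 2.0
        m[..., 2] = (z + zn) / 2.0
        mids.append(m)

    area = np.zeros(z.shape)
    for k in range(8):
        a = mids[k] - centre
        b = mids[(k + 1) % 8] - centre
        cross = np.cross(a, b)
        area += 0.5 * np.linalg.norm(cross, axis=-1)
    return area


def terrain_ruggedness(dem: Raster, radius_km: float = 10.0) -> Raster:
    """Ratio of 3-D surface area to planar area within a focal window (>= 1).

    On an inclined plane at slope theta the interior ratio is 1/cos(theta).
    """
    surface = _cell_surface_area(dem)
    valid = np.isfinite(dem.data)
    surface = np.where(valid, surface, 0.0)
    planar = np.where(valid, dem.cell_size**2, 0.0)
    fp = _circular_footprint(radius_km * 1000.0, dem.cell_size).astype(float)
    s_sum = ndimage.correlate(surface, fp, mode="constant", cval=0.0)
    p_sum = ndimage.correlate(planar, fp, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(p_sum > 0, s_sum / p_sum, np.nan)
    return dem.like(ratio)


def slope(dem: Raster) -> Raster:
    """Horn's 3x3 finite-difference slope, degrees; edges use replicated
    neighbours."""
    z = np.pad(dem.data, 1, mode="edge")
    d = dem.cell_size
    a = z[:-2, :-2]; b = z[:-2, 1:-1]; c = z[:-2, 2:]
    dd = z[1:-1, :-2]; f = z[1:-1, 2:]
    g = z[2:, :-2]; h = z[2:, 1:-1]; i = z[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * dd + g)) / (8 * d)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8 * d)
    return dem.like(np.degrees(np.arctan(np.hypot(dzdx, dzdy))))


def screen_collinearity(
    stack: CovariateStack,
    points_xy: np.ndarray,
    threshold: float = 0.70,
    priority: list[str] | None = None,
) -> tuple[list[str], np.ndarray]:
    """Drop the lower-priority member of any covariate pair with |rs| > threshold.

    Spearman rank correlations are computed on covariate values at the given
    points.  ``priority`` (default: stack order) lists covariates from most
    to least biologically meaningful; for a flagged pair the later one is
    dropped.  A covariate constant at the points has undefined rs: it is
    reported and retained.  Returns (retained names, rs matrix in priority
    order).
    """
    points_xy = np.asarray(points_xy, dtype=float)
    if len(points_xy) < 3:
        raise ValueError("need at least 3 points for the correlation screen")
    priority = priority or stack.names
    values = stack.values_at(points_xy[:, 0], points_xy[:, 1], names=priority)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rs = spearmanr(values).statistic
    rs = np.atleast_2d(rs)
    if rs.shape != (len(priority), len(priority)):  # two-covariate case
        r = float(rs.ravel()[0]) if rs.size else np.nan
        rs = np.array([[1.0, r], [r, 1.0]])

    retained: list[str] = []
    for j, name in enumerate(priority):
        if np.nanstd(values[:, j]) == 0:
            log.warning("covariate %s is constant at the points; rs undefined, retained", name)
            retained.append(name)
            continue
        conflict = False
        for kept in retained:
            i = priority.index(kept)
            if np.isfinite(rs[i, j]) and abs(rs[i, j]) > threshold:
                conflict = True
                log.info("dropping %s (|rs|=%.3f with %s)", name, abs(rs[i, j]), kept)
                break
        if not conflict:
            retained.append(name)
    return retained, rs
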