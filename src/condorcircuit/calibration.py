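"""Calibration of current maps against movement points.

The continuous Boyce index compares the distribution of map values at
movement points ("predicted") with the distribution of map values over the
evaluation area ("expected") in overlapping moving windows; the index is the
Spearman rank correlation between window centre and the P/E ratio.  +1 means
the map ranks use consistently, 0 is indistinguishable from random, negative
means the map is wrong.  Evaluation is limited to points within 300 km of a
release site because current values near the ground ring are biased by the
ring itself.  The reverse cumulative frequency curve (fraction of points at
or above each 1-mA threshold) shows how movement attenuates with current.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .circuit import CurrentMap
from .raster import Raster
from .telemetry import ReleaseSite

log = logging.getLogger(__name__)


def _as_raster(m: CurrentMap | Raster) -> Raster:
    return m.raster if isinstance(m, CurrentMap) else m


@dataclass
class PECurve:
    window_centres: np.ndarray
    pe_ratio: np.ndarray
    boyce_index: float  # NaN when undefined (constant map)
    window_width: float
    n_windows: int
    n_points: int
    diagnostics: str = ""

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"window_centre": self.window_centres, "pe_ratio": self.pe_ratio}
        ).to_csv(path, index=False)


@dataclass
class AttenuationCurve:
    thresholds: np.ndarray  # mA
    fraction: np.ndarray  # reverse cumulative fraction of points >= threshold

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"threshold_mA": self.thresholds, "fraction": self.fraction}
        ).to_csv(path, index=False)


def extract_at_points(
    current: CurrentMap | Raster,
    points_xy: np.ndarray,
    sites: list[ReleaseSite],
    max_distance_km: float = 300.0,
) -> np.ndarray:
    """Map values at points within ``max_distance_km`` of any site.

    Points on nodata cells are dropped with a logged count; if no point is
    within range an error is raised.
    """
    raster = _as_raster(current)
    points_xy = np.asarray(points_xy, dtype=float)
    x, y = points_xy[:, 0], points_xy[:, 1]
    if sites:
        d = np.full(len(x), np.inf)
        for s in sites:
            d = np.minimum(d, np.hypot(x - s.x, y - s.y))
        in_range = d <= max_distance_km * 1000.0
    else:
        in_range = np.ones(len(x), dtype=bool)
    if not in_range.any():
        raise ValueError("no points within the evaluation distance of any site")
    vals = raster.values_at(x[in_range], y[in_range])
    n_nodata = int(np.sum(~np.isfinite(vals)))
    if n_nodata:
        log.info("dropped %d points on nodata cells", n_nodata)
    return vals[np.isfinite(vals)]


def boyce_continuous(
    point_values: np.ndarray,
    map_values: np.ndarray,
    window_fraction: float = 0.1,
    n_windows: int = 101,
    disjoint: bool = False,
) -> PECurve:
    """Continuous Boyce index and P/E curve.

    Moving windows of width ``window_fraction * (max - min)`` of the map
    values are centred at ``n_windows`` evenly spaced values; per window,
    P/E = (fraction of point values inside) / (fraction of map cells inside),
    windows with zero expected fraction are skipped, and the index is the
    Spearman correlation of window centre vs P/E (average ranks on ties).
    ``disjoint=True`` uses contiguous non-overlapping bins instead (in which
    mode the expectation-weighted mean of P/E is exactly 1).
    """
    point_values = np.asarray(point_values, dtype=float)
    map_values = np.asarray(map_values, dtype=float)
    map_values = map_values[np.isfinite(map_values)]
    if len(point_values) < 20:
        raise ValueError("need at least 20 point values")
    lo, hi = map_values.min(), map_values.max()
    if not hi > lo:
        return PECurve(
            window_centres=np.empty(0), pe_ratio=np.empty(0),
            boyce_index=float("nan"), window_width=0.0, n_windows=n_windows,
            n_points=len(point_values),
            diagnostics="map values are constant; Boyce index undefined",
        )

    if disjoint:
        edges = np.linspace(lo, hi, n_windows + 1)
        p_counts, _ = np.histogram(point_values, bins=edges)
        e_counts, _ = np.histogram(map_values, bins=edges)
        centres = (edges[:-1] + edges[1:]) / 2.0
        width = edges[1] - edges[0]
        p_frac = p_counts / max(len(point_values), 1)
        e_frac = e_counts / len(map_values)
    else:
        width = window_fraction * (hi - lo)
        centres = np.linspace(lo + width / 2.0, hi - width / 2.0, n_windows)
        p_frac = np.empty(n_windows)
        e_frac = np.empty(n_windows)
        for i, c in enumerate(centres):
            a, b = c - width / 2.0, c + width / 2.0
            p_frac[i] = np.mean((point_values >= a) & (point_values <= b))
            e_frac[i] = np.mean((map_values >= a) & (map_values <= b))

    keep = e_frac > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        pe = np.where(keep, p_frac / np.where(keep, e_frac, 1.0), np.nan)
    centres_kept = centres[keep]
    pe_kept = pe[keep]
    if len(pe_kept) >= 2 and np.std(pe_kept) > 0:
        index = float(spearmanr(centres_kept, pe_kept).statistic)
        diag = ""
    else:
        index = float("nan")
        diag = "fewer than two informative windows; Boyce index undefined"
    return PECurve(
        window_centres=centres_kept, pe_ratio=pe_kept, boyce_index=index,
        window_width=float(width), n_windows=n_windows,
        n_points=len(point_values), diagnostics=diag,
    )


def reverse_cumulative(values: np.ndarray, bin_mA: float = 1.0) -> AttenuationCurve:
    """Fraction of values at or above each threshold 0, 1, 2, ... (mA).

    Starts at exactly 1.0 and is monotone non-increasing; the last threshold
    is the first multiple of ``bin_mA`` above the maximum (fraction 0 unless
    the maximum sits on a bin edge).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no values to summarise")
    if np.any(values < 0):
        raise ValueError("current values must be non-negative")
    n_bins = int(np.floor(values.max() / bin_mA)) + 2
    thresholds = np.arange(n_bins) * bin_mA
    fraction = np.array([np.mean(values >= t) for t in thresholds])
    return AttenuationCurve(thresholds=thresholds, fraction=fraction)


def plot_pe_curve(curve: PECurve, path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve.window_centres, curve.pe_ratio, "o-", ms=3)
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("current (mA)")
    ax.set_ylabel("P/E ratio")
    ax.set_title(f"Boyce index = {curve.boyce_index:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_attenuation(curve: AttenuationCurve, path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.step(curve.thresholds, curve.fraction, where="post")
    ax.set_xlabel("current threshold (mA)")
    ax.set_ylabel("fraction of movement points >= threshold")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
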