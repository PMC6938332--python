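"""GPS-telemetry filtering and background-point construction.

The occurrence pipeline keeps only reliable fixes of birds in powered/soaring
flight (ground speed strictly between 2.78 and 30 m/s), removes offshore
points and points within 5 km of release sites (movement there is inflated by
baiting and pen attraction), thins to one point per bird per calendar day,
and draws a uniform background sample inside the 10-km-buffered convex hull
of the flight points, clipped to land and away from release sites.

Telemetry tables are pandas DataFrames with columns
``bird_id, timestamp, x, y, speed_mps, proofed`` (projected metres, ISO-8601
timestamps on disk).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, Point, mapping

from .raster import Raster

log = logging.getLogger(__name__)

#: Flight-speed window, m/s.  Points at or below/above the bounds are treated
#: as stationary birds or GPS glitches, not flight.
SPEED_MIN_MPS = 2.78
SPEED_MAX_MPS = 30.0

COLUMNS = ["bird_id", "timestamp", "x", "y", "speed_mps", "proofed"]


@dataclass
class ReleaseSite:
    """A release (or former release / trapping) site with its exclusion zone."""

    site_id: str
    x: float
    y: float
    exclusion_radius: float = 5_000.0  # metres

    def __post_init__(self) -> None:
        if self.exclusion_radius < 0:
            raise ValueError("exclusion_radius must be >= 0")


@dataclass
class FilterConfig:
    speed_min: float = SPEED_MIN_MPS
    speed_max: float = SPEED_MAX_MPS
    exclusion_radius_km: float = 5.0
    hull_buffer_km: float = 10.0
    n_background: int = 10_000
    seed: int = 0
    timezone: str = "UTC"  # calendar-day boundary for daily thinning

    def __post_init__(self) -> None:
        if not (0 < self.speed_min < self.speed_max):
            raise ValueError("need 0 < speed_min < speed_max")


def _check_records(records: pd.DataFrame) -> None:
    missing = [c for c in COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"telemetry table missing columns: {missing}")
    if len(records) and (records["speed_mps"] < 0).any():
        raise ValueError("negative ground speeds are malformed input")
    xy = records[["x", "y"]].to_numpy(dtype=float)
    if len(records) and not np.all(np.isfinite(xy)):
        raise ValueError("non-finite coordinates are malformed input")


def filter_flight_points(records: pd.DataFrame, config: FilterConfig | None = None) -> pd.DataFrame:
    """Keep proofed fixes with speed strictly inside the flight window.

    Both bounds are strict: a fix at exactly 2.78 m/s is dropped.
    Input order is preserved.
    """
    config = config or FilterConfig()
    _check_records(records)
    speed = records["speed_mps"].to_numpy(dtype=float)
    keep = (
        (records["proofed"].to_numpy() == 1)
        & (speed > config.speed_min)
        & (speed < config.speed_max)
    )
    out = records.loc[keep].copy()
    log.info("flight filter: %d of %d records kept", len(out), len(records))
    return out


def _distance_to_sites(x: np.ndarray, y: np.ndarray, sites: list[ReleaseSite]) -> np.ndarray:
    if not sites:
        return np.full(len(x), np.inf)
    d = np.full(len(x), np.inf)
    for s in sites:
        d = np.minimum(d, np.hypot(x - s.x, y - s.y))
    return d


def exclude_zones(
    records: pd.DataFrame,
    sites: list[ReleaseSite],
    ocean_mask: Raster | None,
    config: FilterConfig | None = None,
    on_outside: str = "drop",
) -> pd.DataFrame:
    """Remove offshore points and points within each site's exclusion radius.

    Points falling outside the mask extent are dropped with a logged count
    (``on_outside="drop"``, default) or raise (``on_outside="error"``).
    The removal breakdown is attached as ``out.attrs["removed"]``.
    """
    config = config or FilterConfig()
    _check_records(records)
    x = records["x"].to_numpy(dtype=float)
    y = records["y"].to_numpy(dtype=float)

    outside = np.zeros(len(records), dtype=bool)
    offshore = np.zeros(len(records), dtype=bool)
    if ocean_mask is not None:
        inside = ocean_mask.contains(x, y)
        outside = ~inside
        if outside.any() and on_outside == "error":
            raise ValueError(f"{int(outside.sum())} records outside the mask extent")
        vals = ocean_mask.values_at(x, y)
        offshore = inside & (vals > 0)

    near = np.zeros(len(records), dtype=bool)
    for s in sites:
        near |= np.hypot(x - s.x, y - s.y) <= s.exclusion_radius
    near &= ~offshore & ~outside  # disjoint bookkeeping

    keep = ~(outside | offshore | near)
    out = records.loc[keep].copy()
    removed = {
        "offshore": int(offshore.sum()),
        "near_site": int(near.sum()),
        "outside_extent": int(outside.sum()),
    }
    out.attrs["removed"] = removed
    log.info("zone filter removed %s", removed)
    return out


def thin_daily(records: pd.DataFrame, seed: int = 0, timezone: str = "UTC") -> pd.DataFrame:
    """One uniformly random record per (bird, calendar day), seeded.

    The calendar day is taken in ``timezone``; naive timestamps are treated
    as UTC.  Deterministic for a fixed seed regardless of input order.
    """
    _check_records(records)
    if records.empty:
        return records.copy()
    ts = pd.to_datetime(records["timestamp"])
    if ts.dt.tz is None:
        ts = ts.dt.tz_localize("UTC")
    day = ts.dt.tz_convert(timezone).dt.date
    rng = np.random.default_rng(seed)
    chosen: list = []
    groups = records.groupby([records["bird_id"], day], sort=True).groups
    for key in sorted(groups, key=lambda k: (str(k[0]), str(k[1]))):
        idx = groups[key].to_numpy()
        idx.sort()
        chosen.append(idx[rng.integers(len(idx))])
    return records.loc[sorted(chosen, key=list(records.index).index)].copy()


def build_background(
    flight_points: pd.DataFrame | np.ndarray,
    sites: list[ReleaseSite],
    ocean_mask: Raster | None,
    config: FilterConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Uniform background sample inside the buffered convex hull of flight points.

    The hull of the flight points is buffered by ``hull_buffer_km``, clipped
    to land (via the ocean mask), and ``n_background`` points are drawn
    uniformly by rejection sampling over the hull's bounding box, excluding
    each site's exclusion zone.  Returns the points and the hull geometries.
    """
    config = config or FilterConfig()
    if isinstance(flight_points, pd.DataFrame):
        xy = flight_points[["x", "y"]].to_numpy(dtype=float)
    else:
        xy = np.asarray(flight_points, dtype=float)
    if len(xy) < 3:
        raise ValueError("need >= 3 flight points for a convex hull")
    hull = MultiPoint([tuple(p) for p in xy]).convex_hull
    if hull.geom_type != "Polygon" or hull.area == 0:
        raise ValueError("flight points are collinear; hull is degenerate")
    buffered = hull.buffer(config.hull_buffer_km * 1000)

    rng = np.random.default_rng(config.seed)
    minx, miny, maxx, maxy = buffered.bounds
    pts_x: list[np.ndarray] = []
    pts_y: list[np.ndarray] = []
    n_kept = 0
    attempts = 0
    while n_kept < config.n_background:
        if attempts > 1000:
            raise RuntimeError("background sampling is not converging; check masks")
        m = max(4 * (config.n_background - n_kept), 1024)
        cx = rng.uniform(minx, maxx, m)
        cy = rng.uniform(miny, maxy, m)
        ok = shapely.contains_xy(buffered, cx, cy)
        if ocean_mask is not None:
            inside = ocean_mask.contains(cx, cy)
            land = np.zeros(m, dtype=bool)
            land[inside] = ~(ocean_mask.values_at(cx[inside], cy[inside]) > 0)
            ok &= land
        ok &= _distance_to_sites(cx, cy, sites) > config.exclusion_radius_km * 1000
        pts_x.append(cx[ok])
        pts_y.append(cy[ok])
        n_kept += int(ok.sum())
        attempts += 1
        if config.n_background == 0:
            break
    x = np.concatenate(pts_x)[: config.n_background] if pts_x else np.empty(0)
    y = np.concatenate(pts_y)[: config.n_background] if pts_y else np.empty(0)
    points = pd.DataFrame({"x": x, "y": y})
    geoms = {"hull": hull, "buffered_hull": buffered}
    return points, geoms


# -- CSV / GeoJSON helpers ------------------------------------------------

def write_telemetry_csv(records: pd.DataFrame, path: str | Path) -> None:
    out = records.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_telemetry_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def write_geojson(geometries: dict, path: str | Path) -> None:
    """Write named shapely geometries as a GeoJSON FeatureCollection."""
    features = [
        {"type": "Feature", "properties": {"name": name}, "geometry": mapping(geom)}
        for name, geom in geometries.items()
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def points_geojson(points: np.ndarray | pd.DataFrame, path: str | Path, properties: list[dict] | None = None) -> None:
    if isinstance(points, pd.DataFrame):
        points = points[["x", "y"]].to_numpy()
    features = []
    for i, (x, y) in enumerate(points):
        props = properties[i] if properties else {}
        features.append(
            {"type": "Feature", "properties": props, "geometry": mapping(Point(x, y))}
        )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))
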