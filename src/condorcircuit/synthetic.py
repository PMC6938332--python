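"""Synthetic landscapes and telemetry with known truth.

The generator emulates the statistical regime the analysis assumes:

* spatially autocorrelated covariate rasters (Gaussian-smoothed white noise,
  standardised to zero mean / unit variance) on a shared projected grid with
  a contiguous ocean strip along the west edge;
* a known-truth conductance surface — the inverse-logit of a linear +
  quadratic function of the covariates;
* raw GPS tables whose flight-point density increases with conductance and
  decays exponentially with distance from the release site, salted with
  known, counted subsets of unproofed fixes, stationary and implausibly fast
  points, offshore points, and a dense cluster inside the release-site
  exclusion zone — so every downstream filter removes an exactly known
  number of records.

Sampling is per-cell multinomial: there is no within-day movement
autocorrelation, which is irrelevant downstream because the daily-thinning
filter keeps a single point per bird-day anyway.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .raster import CovariateStack, Raster
from .telemetry import COLUMNS, SPEED_MAX_MPS, SPEED_MIN_MPS, ReleaseSite

#: Gaussian-kernel autocorrelation falls to 0.5 at lag = 2*sqrt(ln 2)*sigma,
#: so this factor makes `autocorr_range` the half-correlation length.
_HALF_CORR = 2.0 * np.sqrt(np.log(2.0))

DEFAULT_COEFFICIENTS: dict[str, tuple[float, float]] = {
    # (linear, quadratic) weights on the logit scale per standardised covariate
    "thermal_updraft": (0.6, 0.0),
    "terrain_ruggedness": (1.2, -0.3),
    "terrestrial_habitat": (2.0, 0.0),
}


@dataclass
class SyntheticConfig:
    grid_rows: int = 64
    grid_cols: int = 64
    cell_size: float = 1_000.0  # metres
    autocorr_range: float = 8_000.0  # metres; lag where correlation = 0.5
    true_coefficients: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS)
    )
    decay_length: float = 40_000.0  # metres
    n_birds: int = 10
    days: int = 30
    fixes_per_day: int = 12
    seed: int = 0
    # telemetry salting
    ocean_cols: int = 4  # width of the west ocean strip, cells
    unproofed_fraction: float = 0.10
    slow_fraction: float = 0.10
    fast_fraction: float = 0.05
    n_offshore: int = 50
    n_near_site: int = 200
    crs: str = "synthetic-utm-metres"

    def __post_init__(self) -> None:
        if self.grid_rows < 8 or self.grid_cols < 8:
            raise ValueError("grid must be at least 8x8")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.decay_length <= 0:
            raise ValueError("decay_length must be positive")
        if self.unproofed_fraction + self.slow_fraction + self.fast_fraction >= 1:
            raise ValueError("salting fractions must leave some valid flight points")

    @property
    def n_fixes(self) -> int:
        return self.n_birds * self.days * self.fixes_per_day


def generate_landscape(config: SyntheticConfig) -> CovariateStack:
    """Autocorrelated covariate rasters plus a west-edge ocean mask."""
    rng = np.random.default_rng(config.seed)
    sigma = config.autocorr_range / config.cell_size / _HALF_CORR
    template = Raster(
        data=np.zeros((config.grid_rows, config.grid_cols)),
        cell_size=config.cell_size,
        crs=config.crs,
    )
    layers: dict[str, Raster] = {}
    for name in config.true_coefficients:
        noise = rng.standard_normal((config.grid_rows, config.grid_cols))
        fld = gaussian_filter(noise, sigma=sigma, mode="reflect")
        fld = (fld - fld.mean()) / fld.std()
        layers[name] = template.like(fld)
    ocean = np.zeros((config.grid_rows, config.grid_cols))
    ocean[:, : config.ocean_cols] = 1.0
    return CovariateStack(layers, ocean=template.like(ocean))


def true_conductance(
    stack: CovariateStack, coefficients: Mapping[str, tuple[float, float]]
) -> Raster:
    """Inverse-logit of the linear+quadratic predictor; values in (0, 1)."""
    missing = [n for n in stack.names if n not in coefficients]
    if missing:
        raise ValueError(f"missing coefficients for covariates: {missing}")
    eta = np.zeros(stack.grid.shape)
    for name in stack.names:
        lin, quad = coefficients[name]
        z = stack.layers[name].data
        eta = eta + lin * z + quad * z**2
    return stack.grid.like(expit(eta))


def default_release_site(config: SyntheticConfig) -> ReleaseSite:
    """A release site at the grid centre, clear of the ocean strip."""
    row = config.grid_rows // 2
    col = max(config.grid_cols // 2, config.ocean_cols + 8)
    template = Raster(
        np.zeros((config.grid_rows, config.grid_cols)), config.cell_size, crs=config.crs
    )
    x, y = template.centre_of(row, col)
    return ReleaseSite("release", float(x), float(y))


def simulate_telemetry(
    surface: Raster,
    site: ReleaseSite,
    config: SyntheticConfig,
    ocean_mask: Raster | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Raw GPS table plus a bookkeeping dict of injected category counts.

    Main fixes land on cells with probability proportional to
    ``conductance * exp(-distance / decay_length)``, strictly outside the
    ocean and the site's exclusion zone; salted categories (unproofed, slow,
    fast, offshore, near-site) are mutually disjoint so each filter removes
    exactly its injected count.
    """
    rng = np.random.default_rng(config.seed + 1)
    if not np.nanmax(surface.data) > 0:
        raise ValueError("conductance surface is all zero; nothing to sample")
    if not surface.contains(site.x, site.y):
        raise ValueError("release site is outside the grid")

    X, Y = surface.centres()
    dist = np.hypot(X - site.x, Y - site.y)
    weights = np.where(np.isfinite(surface.data), surface.data, 0.0) * np.exp(
        -dist / config.decay_length
    )
    land = np.ones(surface.shape, dtype=bool)
    if ocean_mask is not None:
        land = ~(ocean_mask.data > 0)
    # keep a half-diagonal margin so jittered points stay outside the zone;
    # a zero radius means no exclusion at all
    if site.exclusion_radius > 0:
        margin = surface.cell_size * np.sqrt(2.0) / 2.0
        weights = np.where(dist > site.exclusion_radius + margin, weights, 0.0)
    weights = np.where(land, weights, 0.0)
    total = weights.sum()
    if total <= 0:
        raise ValueError("no available cells to sample from")
    p = weights.ravel() / total

    n = config.n_fixes
    cells = rng.choice(p.size, size=n, p=p)
    rows, cols = np.unravel_index(cells, surface.shape)
    jitter = rng.uniform(-0.5, 0.5, size=(2, n)) * surface.cell_size
    xs = X[rows, cols] + jitter[0]
    ys = Y[rows, cols] + jitter[1]

    # disjoint speed / fix-quality categories among the main fixes
    n_unproofed = int(round(config.unproofed_fraction * n))
    n_slow = int(round(config.slow_fraction * n))
    n_fast = int(round(config.fast_fraction * n))
    order = rng.permutation(n)
    idx_unproofed = order[:n_unproofed]
    idx_slow = order[n_unproofed : n_unproofed + n_slow]
    idx_fast = order[n_unproofed + n_slow : n_unproofed + n_slow + n_fast]

    speed = rng.uniform(SPEED_MIN_MPS + 1.0, SPEED_MAX_MPS - 5.0, n)
    speed[idx_slow] = rng.uniform(0.0, SPEED_MIN_MPS - 0.1, n_slow)
    speed[idx_fast] = rng.uniform(SPEED_MAX_MPS + 0.5, SPEED_MAX_MPS + 15.0, n_fast)
    proofed = np.ones(n, dtype=int)
    proofed[idx_unproofed] = 0

    bird = np.repeat(np.arange(config.n_birds), config.days * config.fixes_per_day)
    day = np.tile(np.repeat(np.arange(config.days), config.fixes_per_day), config.n_birds)
    fix = np.tile(np.arange(config.fixes_per_day), config.n_birds * config.days)
    base = pd.Timestamp("2015-01-01 08:00:00")
    ts = base + pd.to_timedelta(day, unit="D") + pd.to_timedelta(fix * 10, unit="min")

    frames = [
        pd.DataFrame(
            {
                "bird_id": [f"bird_{b:03d}" for b in bird],
                "timestamp": ts,
                "x": xs,
                "y": ys,
                "speed_mps": speed,
                "proofed": proofed,
            }
        )
    ]

    def _salt(n_extra: int, xe: np.ndarray, ye: np.ndarray) -> pd.DataFrame:
        b = rng.integers(config.n_birds, size=n_extra)
        d = rng.integers(config.days, size=n_extra)
        t = base + pd.to_timedelta(d, unit="D") - pd.to_timedelta(rng.integers(1, 60, n_extra), unit="min")
        return pd.DataFrame(
            {
                "bird_id": [f"bird_{i:03d}" for i in b],
                "timestamp": t,
                "x": xe,
                "y": ye,
                "speed_mps": rng.uniform(SPEED_MIN_MPS + 1.0, SPEED_MAX_MPS - 5.0, n_extra),
                "proofed": np.ones(n_extra, dtype=int),
            }
        )

    n_offshore = 0
    if config.n_offshore and ocean_mask is not None:
        orow, ocol = np.nonzero(ocean_mask.data > 0)
        if len(orow):
            pick = rng.integers(len(orow), size=config.n_offshore)
            ox, oy = surface.centre_of(orow[pick], ocol[pick])
            frames.append(_salt(config.n_offshore, np.asarray(ox, float), np.asarray(oy, float)))
            n_offshore = config.n_offshore

    n_near = 0
    if config.n_near_site:
        r = site.exclusion_radius * 0.95 * np.sqrt(rng.uniform(size=config.n_near_site))
        theta = rng.uniform(0, 2 * np.pi, config.n_near_site)
        nx = site.x + r * np.cos(theta)
        ny = site.y + r * np.sin(theta)
        inside = surface.contains(nx, ny)
        frames.append(_salt(int(inside.sum()), nx[inside], ny[inside]))
        n_near = int(inside.sum())

    table = pd.concat(frames, ignore_index=True)
    table = table.iloc[rng.permutation(len(table))].reset_index(drop=True)
    counts = {
        "total": len(table),
        "flight": n - n_unproofed - n_slow - n_fast,
        "unproofed": n_unproofed,
        "slow": n_slow,
        "fast": n_fast,
        "offshore": n_offshore,
        "near_site": n_near,
    }
    return table[COLUMNS], counts
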