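"""Least-cost linkage network between core habitat patches.

Resistance is the reciprocal of conductance.  Core patches are 8-connected
components of the binarised nesting-suitability raster (threshold 0.04)
with area >= 10 km^2.  Cost-weighted distance (CWD) accumulates
mean-resistance move costs (x sqrt(2) on diagonals, distances in cell-size
kilometres) from every patch cell outward; candidate links come from the
cost-weighted allocation adjacency (patches whose nearest-patch regions
touch), and each link follows the least-cost path between its patches,
dropped if its interior crosses a third patch.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from shapely.geometry import LineString, box, mapping
from shapely.ops import unary_union
from skimage.measure import label as cc_label

from .raster import Raster

log = logging.getLogger(__name__)


@dataclass
class CorePatch:
    patch_id: int
    cells: np.ndarray  # (n, 2) row/col
    area_km2: float
    centroid: tuple[float, float]  # projected x, y


@dataclass
class Link:
    patch_a: int
    patch_b: int
    path_cells: np.ndarray  # (n, 2) row/col, a-side first
    cwd: float  # cost units
    euclidean_length_km: float


@dataclass
class LinkageNetwork:
    patches: list[CorePatch]
    links: list[Link]

    @property
    def summary(self) -> dict:
        cwds = [l.cwd for l in self.links]
        return {
            "n_patches": len(self.patches),
            "n_links": len(self.links),
            "mean_cwd": float(np.mean(cwds)) if cwds else float("nan"),
        }


def resistance_from_conductance(surface: Raster) -> Raster:
    """Cellwise reciprocal; zero-conductance cells must be masked upstream."""
    data = surface.data
    finite = np.isfinite(data)
    if np.any(data[finite] <= 0):
        raise ValueError("conductance must be positive wherever defined")
    out = np.where(finite, 1.0 / np.where(finite, data, 1.0), np.nan)
    return surface.like(out)


def extract_cores(
    suitability: Raster, threshold: float = 0.04, min_area_km2: float = 10.0
) -> list[CorePatch]:
    """Binarise at >= threshold, label 8-connected components, drop small ones."""
    data = suitability.data
    binary = np.where(np.isfinite(data), data >= threshold, False)
    labels = cc_label(binary, connectivity=2)
    cell_km2 = (suitability.cell_size / 1000.0) ** 2
    patches: list[CorePatch] = []
    pid = 0
    for lab in range(1, labels.max() + 1):
        cells = np.column_stack(np.nonzero(labels == lab))
        area = len(cells) * cell_km2
        if area < min_area_km2:
            continue
        pid += 1
        x, y = suitability.centre_of(cells[:, 0], cells[:, 1])
        patches.append(
            CorePatch(patch_id=pid, cells=cells, area_km2=area,
                      centroid=(float(np.mean(x)), float(np.mean(y))))
        )
    return patches


def _lattice_graph(resistance: Raster):
    """Sparse 8-neighbour move-cost graph; weights are mean resistance times
    centre distance in cell-size kilometres."""
    r = resistance.data
    land = np.isfinite(r)
    node_index = np.full(r.shape, -1, dtype=int)
    rows, cols = np.nonzero(land)
    node_index[rows, cols] = np.arange(len(rows))
    step_km = resistance.cell_size / 1000.0
    us, vs, ws = [], [], []
    nr, nc = r.shape
    for dr, dc, dist in [(0, 1, 1.0), (1, 0, 1.0), (1, 1, np.sqrt(2)), (1, -1, np.sqrt(2))]:
        r0 = slice(max(0, -dr), min(nr, nr - dr))
        c0 = slice(max(0, -dc), min(nc, nc - dc))
        r1 = slice(max(0, dr), min(nr, nr + dr))
        c1 = slice(max(0, dc), min(nc, nc + dc))
        a, b = node_index[r0, c0], node_index[r1, c1]
        ra, rb = r[r0, c0], r[r1, c1]
        ok = (a >= 0) & (b >= 0)
        us.append(a[ok]); vs.append(b[ok])
        ws.append((ra[ok] + rb[ok]) / 2.0 * dist * step_km)
    n = len(rows)
    graph = coo_matrix(
        (np.concatenate(ws), (np.concatenate(us), np.concatenate(vs))), shape=(n, n)
    ).tocsr()
    return graph, node_index, np.column_stack([rows, cols])


@dataclass
class CWDResult:
    patch_id: int
    cwd: Raster  # accumulated cost; inf where unreachable
    predecessors: np.ndarray  # per-node predecessor node id (-9999 none)
    node_index: np.ndarray
    cells: np.ndarray


def cost_weighted_distance(resistance: Raster, patch: CorePatch) -> CWDResult:
    """Multi-source Dijkstra from all patch cells (cost 0 inside the patch)."""
    if np.any(resistance.data[np.isfinite(resistance.data)] <= 0):
        raise ValueError("resistance must be positive")
    graph, node_index, cells = _lattice_graph(resistance)
    sources = node_index[patch.cells[:, 0], patch.cells[:, 1]]
    sources = sources[sources >= 0]
    if sources.size == 0:
        raise ValueError("patch has no cells on the resistance grid")
    dist, pred, _ = dijkstra(
        graph, directed=False, indices=sources, min_only=True, return_predecessors=True
    )
    grid = np.full(resistance.shape, np.inf)
    grid[cells[:, 0], cells[:, 1]] = dist
    grid[~np.isfinite(resistance.data)] = np.nan
    return CWDResult(patch_id=patch.patch_id, cwd=resistance.like(grid),
                     predecessors=pred, node_index=node_index, cells=cells)


def adjacency_network(patches: list[CorePatch], cwd_results: list[CWDResult]) -> list[tuple[int, int]]:
    """Candidate pairs via cost-weighted allocation adjacency.

    Each cell is allocated to the patch with the smallest CWD (ties to the
    lower patch id); pairs whose allocation regions share an 8-neighbour
    boundary are candidates.
    """
    if len(patches) < 2:
        return []
    stack = np.stack([r.cwd.data for r in cwd_results])
    ids = np.array([r.patch_id for r in cwd_results])
    finite_any = np.any(np.isfinite(stack) & ~np.isnan(stack), axis=0)
    safe = np.where(np.isnan(stack), np.inf, stack)
    alloc = np.where(finite_any, ids[np.argmin(safe, axis=0)], 0)
    pairs: set[tuple[int, int]] = set()
    for dr, dc in [(0, 1), (1, 0), (1, 1), (1, -1)]:
        nr, nc = alloc.shape
        r0 = slice(max(0, -dr), min(nr, nr - dr)); c0 = slice(max(0, -dc), min(nc, nc - dc))
        r1 = slice(max(0, dr), min(nr, nr + dr)); c1 = slice(max(0, dc), min(nc, nc + dc))
        a, b = alloc[r0, c0], alloc[r1, c1]
        ok = (a > 0) & (b > 0) & (a != b)
        for pa, pb in zip(a[ok].ravel(), b[ok].ravel()):
            pairs.add((int(min(pa, pb)), int(max(pa, pb))))
    return sorted(pairs)


def _backtrack(node: int, pred: np.ndarray, cells: np.ndarray) -> list[tuple[int, int]]:
    path = []
    while node >= 0:
        path.append((int(cells[node, 0]), int(cells[node, 1])))
        node = int(pred[node])
    return path


def least_cost_paths(
    resistance: Raster,
    pairs: list[tuple[int, int]],
    patches: list[CorePatch],
    cwd_results: list[CWDResult] | None = None,
) -> LinkageNetwork:
    """Least-cost link per candidate pair; links whose interior crosses a
    third patch are dropped, as are pairs with no finite path (logged)."""
    by_id = {p.patch_id: p for p in patches}
    if cwd_results is None:
        cwd_results = [cost_weighted_distance(resistance, p) for p in patches]
    cwd_by_id = {r.patch_id: r for r in cwd_results}
    patch_of_cell: dict[tuple[int, int], int] = {}
    for p in patches:
        for rc in map(tuple, p.cells):
            patch_of_cell[rc] = p.patch_id

    links: list[Link] = []
    for pa, pb in pairs:
        ra, rb = cwd_by_id[pa], cwd_by_id[pb]
        total = ra.cwd.data + rb.cwd.data
        if not np.isfinite(total).any():
            log.info("no finite path between patches %d and %d; skipped", pa, pb)
            continue
        meet = np.unravel_index(np.nanargmin(np.where(np.isfinite(total), total, np.inf)), total.shape)
        if not np.isfinite(total[meet]):
            log.info("no finite path between patches %d and %d; skipped", pa, pb)
            continue
        node = ra.node_index[meet]
        half_a = _backtrack(node, ra.predecessors, ra.cells)[::-1]  # patch a -> meet
        half_b = _backtrack(node, rb.predecessors, rb.cells)  # meet -> patch b
        path = half_a + half_b[1:]
        interior = [rc for rc in path if patch_of_cell.get(rc) not in (pa, pb, None)]
        if interior:
            log.info("link %d-%d crosses patch %d; dropped", pa, pb, patch_of_cell[interior[0]])
            continue
        xs, ys = zip(*(resistance.centre_of(r, c) for r, c in path))
        length_km = float(
            np.sum(np.hypot(np.diff(xs), np.diff(ys))) / 1000.0
        ) if len(path) > 1 else 0.0
        links.append(Link(patch_a=pa, patch_b=pb, path_cells=np.array(path),
                          cwd=float(total[meet]), euclidean_length_km=length_km))
    return LinkageNetwork(patches=patches, links=links)


# -- GeoJSON output -------------------------------------------------------

def write_network_geojson(network: LinkageNetwork, raster: Raster, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    half = raster.cell_size / 2.0
    patch_features = []
    for p in network.patches:
        boxes = []
        for r, c in p.cells:
            x, y = raster.centre_of(int(r), int(c))
            boxes.append(box(x - half, y - half, x + half, y + half))
        geom = unary_union(boxes)
        patch_features.append({
            "type": "Feature",
            "properties": {"patch_id": p.patch_id, "area_km2": p.area_km2},
            "geometry": mapping(geom),
        })
    (directory / "patches.geojson").write_text(
        json.dumps({"type": "FeatureCollection", "features": patch_features})
    )
    link_features = []
    for l in network.links:
        coords = [tuple(map(float, raster.centre_of(int(r), int(c)))) for r, c in l.path_cells]
        geom = LineString(coords) if len(coords) > 1 else LineString(coords * 2)
        link_features.append({
            "type": "Feature",
            "properties": {
                "patch_a": l.patch_a, "patch_b": l.patch_b,
                "cwd": l.cwd, "length_km": l.euclidean_length_km,
            },
            "geometry": mapping(geom),
        })
    (directory / "links.geojson").write_text(
        json.dumps({"type": "FeatureCollection", "features": link_features})
    )
    (directory / "network.json").write_text(json.dumps(network.summary, indent=2))
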