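"""Electrical-circuit engine over a conductance raster.

Every land cell is a node; 8-neighbour edges carry the mean of the two cell
conductances, divided by sqrt(2) for diagonals.  A source node injects a
fixed current (default 1 A) and a ground node is tied directly to 0 V; the
resulting Kirchhoff system (graph Laplacian) is solved sparsely and the
per-cell current magnitude — half the sum of absolute incident edge
currents, with source/ground cells carrying the full injection — is the
movement-probability prediction.  Iterating one solve per (source, ground)
pair over a ring of ground nodes on a buffer around the release sites and
averaging the maps yields a direction-neutral connectivity map, reported in
milliamps (x 1,000).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu
from shapely.geometry import Point
from shapely.ops import unary_union

from .raster import Raster
from .telemetry import ReleaseSite

Cell = tuple[int, int]


@dataclass
class NodeConfig:
    """Sources (cell, injected amps) and grounds (cells tied to 0 V)."""

    sources: list[tuple[Cell, float]]
    grounds: list[Cell]
    mode: str = "iterate-all-pairs"
    ground_resistance: float = 0.0  # ohms between ground cell and true ground

    def __post_init__(self) -> None:
        if not self.sources or not self.grounds:
            raise ValueError("need at least one source and one ground")
        src_cells = {tuple(c) for c, _ in self.sources}
        if src_cells & {tuple(c) for c in self.grounds}:
            raise ValueError("sources and grounds must be disjoint")


@dataclass
class CurrentMap:
    """Per-cell current magnitude with units and provenance."""

    raster: Raster
    units: str = "A"
    provenance: list[str] = field(default_factory=list)

    @property
    def data(self) -> np.ndarray:
        return self.raster.data


class CircuitGraph:
    """Resistor network built from a conductance raster (or explicit edges)."""

    def __init__(self, n_nodes: int, edges_u: np.ndarray, edges_v: np.ndarray,
                 edges_g: np.ndarray, raster: Raster | None = None,
                 node_index: np.ndarray | None = None, cells: np.ndarray | None = None):
        if np.any(edges_g <= 0):
            raise ValueError("edge conductances must be positive")
        self.n_nodes = n_nodes
        self.edges_u = edges_u
        self.edges_v = edges_v
        self.edges_g = edges_g
        self.raster = raster
        self.node_index = node_index  # (nrows, ncols) int, -1 off-graph
        self.cells = cells  # (n_nodes, 2) row/col
        self._labels: np.ndarray | None = None
        self._factors: dict[int, tuple] = {}

    # -- construction -----------------------------------------------------
    @classmethod
    def from_raster(cls, conductance: Raster, neighborhood: int = 8) -> "CircuitGraph":
        if neighborhood not in (4, 8):
            raise ValueError("neighborhood must be 4 or 8")
        g = conductance.data
        land = np.isfinite(g)
        if not land.any():
            raise ValueError("conductance raster is all nodata")
        if np.any(g[land] <= 0):
            raise ValueError("conductance must be positive on land cells")
        node_index = np.full(g.shape, -1, dtype=int)
        rows, cols = np.nonzero(land)
        node_index[rows, cols] = np.arange(len(rows))
        cells = np.column_stack([rows, cols])

        offsets = [(0, 1, 1.0), (1, 0, 1.0)]
        if neighborhood == 8:
            offsets += [(1, 1, np.sqrt(2)), (1, -1, np.sqrt(2))]
        us, vs, gs = [], [], []
        nr, nc = g.shape
        for dr, dc, dist in offsets:
            r0 = slice(max(0, -dr), min(nr, nr - dr))
            c0 = slice(max(0, -dc), min(nc, nc - dc))
            r1 = slice(max(0, dr), min(nr, nr + dr))
            c1 = slice(max(0, dc), min(nc, nc + dc))
            a = node_index[r0, c0]
            b = node_index[r1, c1]
            ga = g[r0, c0]
            gb = g[r1, c1]
            ok = (a >= 0) & (b >= 0)
            us.append(a[ok])
            vs.append(b[ok])
            gs.append((ga[ok] + gb[ok]) / 2.0 / dist)
        return cls(
            n_nodes=len(rows),
            edges_u=np.concatenate(us), edges_v=np.concatenate(vs),
            edges_g=np.concatenate(gs),
            raster=conductance, node_index=node_index, cells=cells,
        )

    @classmethod
    def from_edges(cls, n_nodes: int, edges: list[tuple[int, int, float]]) -> "CircuitGraph":
        u, v, g = (np.array(x) for x in zip(*edges))
        return cls(n_nodes, u.astype(int), v.astype(int), g.astype(float))

    # -- linear algebra ---------------------------------------------------
    def laplacian(self) -> csr_matrix:
        u, v, g = self.edges_u, self.edges_v, self.edges_g
        i = np.concatenate([u, v, u, v])
        j = np.concatenate([v, u, u, v])
        w = np.concatenate([-g, -g, g, g])
        return coo_matrix((w, (i, j)), shape=(self.n_nodes, self.n_nodes)).tocsr()

    def components(self) -> np.ndarray:
        if self._labels is None:
            adj = coo_matrix(
                (self.edges_g, (self.edges_u, self.edges_v)),
                shape=(self.n_nodes, self.n_nodes),
            )
            _, self._labels = connected_components(adj, directed=False)
        return self._labels

    def node_of(self, cell: Cell) -> int:
        if self.node_index is None:
            return int(cell)  # explicit-edge graphs address nodes directly
        node = int(self.node_index[cell[0], cell[1]])
        if node < 0:
            raise ValueError(f"cell {cell} is not on the graph")
        return node

    def _component_solver(self, comp: int):
        """Cached LU of the component Laplacian with its last node as the
        voltage reference (removed row/column)."""
        if comp not in self._factors:
            labels = self.components()
            nodes = np.nonzero(labels == comp)[0]
            local = -np.ones(self.n_nodes, dtype=int)
            local[nodes] = np.arange(len(nodes))
            mask = labels[self.edges_u] == comp
            u = local[self.edges_u[mask]]
            v = local[self.edges_v[mask]]
            g = self.edges_g[mask]
            n = len(nodes)
            i = np.concatenate([u, v, u, v])
            j = np.concatenate([v, u, u, v])
            w = np.concatenate([-g, -g, g, g])
            L = coo_matrix((w, (i, j)), shape=(n, n)).tocsr()
            keep = np.arange(n - 1)
            lu = splu(L[keep][:, keep].tocsc()) if n > 1 else None
            self._factors[comp] = (nodes, local, lu)
        return self._factors[comp]

    # -- solves -----------------------------------------------------------
    def solve_pair(self, source: Cell | int, ground: Cell | int,
                   injection: float = 1.0, ground_resistance: float = 0.0) -> "PairSolution":
        """Voltages and per-cell current for one source-ground connection.

        Solves the Laplacian system with the ground node at 0 V and
        ``injection`` amperes entering at the source; equivalent to a +I/-I
        injection pair, shifted so the ground sits at ``I * ground_resistance``
        volts above true ground (0 for a direct tie).
        """
        s = self.node_of(source) if not np.isscalar(source) else int(source)
        t = self.node_of(ground) if not np.isscalar(ground) else int(ground)
        if s == t:
            raise ValueError("source and ground must differ")
        labels = self.components()
        if labels[s] != labels[t]:
            raise ValueError(
                f"source (component {labels[s]}) and ground (component {labels[t]}) "
                "are not connected"
            )
        nodes, local, lu = self._component_solver(int(labels[s]))
        n = len(nodes)
        b = np.zeros(n - 1)
        ref = nodes[-1]
        if s != ref:
            b[local[s]] += injection
        if t != ref:
            b[local[t]] -= injection
        v_local = np.zeros(n)
        v_local[:-1] = lu.solve(b)
        voltages = np.zeros(self.n_nodes)
        voltages[nodes] = v_local - v_local[local[t]] + injection * ground_resistance

        edge_cur = self.edges_g * (voltages[self.edges_u] - voltages[self.edges_v])
        node_cur = np.zeros(self.n_nodes)
        np.add.at(node_cur, self.edges_u, np.abs(edge_cur))
        np.add.at(node_cur, self.edges_v, np.abs(edge_cur))
        node_cur *= 0.5
        node_cur[s] = abs(injection)
        node_cur[t] = abs(injection)
        node_cur[labels != labels[s]] = 0.0

        current = None
        if self.raster is not None:
            grid = np.full(self.raster.shape, np.nan)
            grid[self.cells[:, 0], self.cells[:, 1]] = node_cur
            current = CurrentMap(
                raster=self.raster.like(grid), units="A",
                provenance=[f"source={tuple(np.atleast_1d(source))}->ground={tuple(np.atleast_1d(ground))}"],
            )
        return PairSolution(voltages=voltages, node_currents=node_cur,
                            edge_currents=edge_cur, current=current)


@dataclass
class PairSolution:
    voltages: np.ndarray
    node_currents: np.ndarray
    edge_currents: np.ndarray
    current: CurrentMap | None


def effective_resistance(graph: CircuitGraph, a: Cell | int, b: Cell | int) -> float:
    """Voltage difference per unit current injected at a and drained at b."""
    sol = graph.solve_pair(a, b, injection=1.0)
    na = graph.node_of(a) if not np.isscalar(a) else int(a)
    return float(sol.voltages[na])


def fill_outside(conductance: Raster, study_mask: Raster, ocean_mask: Raster) -> Raster:
    """Assign min in-study conductance to ocean cells and the median to
    terrestrial cells outside the study area; in-study cells are untouched."""
    for m in (study_mask, ocean_mask):
        if not m.aligned_with(conductance):
            raise ValueError("masks must align with the conductance raster")
    in_study = study_mask.data > 0
    vals = conductance.data[in_study]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("study area is empty")
    out = conductance.data.copy()
    ocean = (ocean_mask.data > 0) & ~in_study
    outside_land = ~in_study & ~ocean
    out[ocean] = vals.min()
    out[outside_land] = np.median(vals)
    return conductance.like(out)


def place_ground_ring(
    sites: list[ReleaseSite],
    buffer_km: float = 350.0,
    spacing_km: float = 10.0,
    quad_segs: int = 64,
) -> np.ndarray:
    """Ground-node points every ``spacing_km`` along the boundary of the
    union of per-site buffer disks, starting at the easternmost point.

    The count is ceil(perimeter / spacing) per exterior ring; a single site
    with a 350-km buffer and 10-km spacing yields 220 nodes.
    """
    if buffer_km <= 0:
        raise ValueError("buffer must be positive")
    if not sites:
        raise ValueError("need at least one site")
    union = unary_union(
        [Point(s.x, s.y).buffer(buffer_km * 1000.0, quad_segs=quad_segs) for s in sites]
    )
    polys = [union] if union.geom_type == "Polygon" else list(union.geoms)
    spacing = spacing_km * 1000.0
    points = []
    for poly in polys:
        ring = poly.exterior
        if spacing >= ring.length:
            raise ValueError("spacing must be smaller than the ring perimeter")
        coords = np.asarray(ring.coords)
        east = coords[np.argmax(coords[:, 0])]
        s0 = ring.project(Point(east))
        count = int(np.ceil(ring.length / spacing))
        for i in range(count):
            p = ring.interpolate((s0 + i * spacing) % ring.length)
            points.append((p.x, p.y))
    return np.asarray(points)


def ring_cells(points: np.ndarray, raster: Raster) -> list[Cell]:
    """Map ring points to unique grid cells (clipped to the grid), in order."""
    seen: list[Cell] = []
    for x, y in points:
        row, col = raster.cell_of(x, y)
        row = int(np.clip(row, 0, raster.nrows - 1))
        col = int(np.clip(col, 0, raster.ncols - 1))
        if (row, col) not in seen:
            seen.append((row, col))
    return seen


def mean_current(maps: list[CurrentMap]) -> CurrentMap:
    """Cellwise mean of per-pair maps, converted to milliamps (x 1,000)."""
    if not maps:
        raise ValueError("need at least one current map")
    base = maps[0].raster
    for m in maps[1:]:
        if not m.raster.aligned_with(base):
            raise ValueError("current maps are not aligned")
    stack = np.stack([m.data for m in maps])
    prov = [p for m in maps for p in m.provenance]
    return CurrentMap(raster=base.like(stack.mean(axis=0) * 1000.0), units="mA", provenance=prov)


def combine_max(map_a: CurrentMap, map_b: CurrentMap) -> CurrentMap:
    """Cellwise maximum of two aligned maps (post-hoc attractant overlay)."""
    if not map_a.raster.aligned_with(map_b.raster):
        raise ValueError("maps are not aligned")
    if map_a.units != map_b.units:
        raise ValueError("maps have different units")
    return CurrentMap(
        raster=map_a.raster.like(np.fmax(map_a.data, map_b.data)),
        units=map_a.units,
        provenance=map_a.provenance + map_b.provenance,
    )


def ring_mean_current(
    graph: CircuitGraph,
    sources: list[tuple[Cell, float]],
    grounds: list[Cell],
    skip_unreachable: bool = False,
) -> CurrentMap:
    """Direction-neutral map: one solve per (source, ground) pair, averaged
    (unweighted over all pairs) and converted to mA."""
    maps = []
    for cell, amps in sources:
        for gcell in grounds:
            if tuple(gcell) == tuple(cell):
                continue
            try:
                sol = graph.solve_pair(cell, gcell, injection=amps)
            except ValueError:
                if skip_unreachable:
                    continue
                raise
            maps.append(sol.current)
    return mean_current(maps)


def attractant_overlay(
    graph: CircuitGraph,
    sources: list[tuple[Cell, float]],
    destinations: list[Cell],
    base_map: CurrentMap,
) -> CurrentMap:
    """Post-hoc high-use-area workflow: pairwise source-to-destination solves,
    averaged in mA, then cellwise max with the ring map."""
    extra = ring_mean_current(graph, sources, destinations)
    return combine_max(base_map, extra)
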