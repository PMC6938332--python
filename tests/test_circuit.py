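"""Circuit engine: lattice construction, Kirchhoff solves against a dense
oracle, ground-ring geometry, conservation laws and symmetry."""
import numpy as np
import pytest

from condorcircuit.circuit import (CircuitGraph, combine_max,
                                   effective_resistance, fill_outside,
                                   mean_current, place_ground_ring,
                                   ring_cells, ring_mean_current)
from condorcircuit.raster import Raster
from condorcircuit.telemetry import ReleaseSite


def dense_solve(graph: CircuitGraph, source: int, ground: int, injection=1.0):
    """Independent oracle: full dense Laplacian with the ground row replaced
    by the identity constraint v[ground] = 0."""
    L = graph.laplacian().toarray()
    L[ground, :] = 0.0
    L[ground, ground] = 1.0
    b = np.zeros(graph.n_nodes)
    b[source] = injection
    return np.linalg.solve(L, b)


class TestGraphConstruction:
    def test_edge_conductance_is_mean_of_cells(self):
        g = CircuitGraph.from_raster(Raster(np.array([[2.0, 4.0]]), 1.0))
        assert g.edges_g[0] == pytest.approx(3.0)

    def test_diagonal_scaled_by_sqrt2(self):
        g = CircuitGraph.from_raster(Raster(np.full((2, 2), 1.0), 1.0))
        diag = [c for c in g.edges_g if c < 0.9]
        assert diag == pytest.approx([1 / np.sqrt(2)] * 2)

    def test_3x3_uniform_counts(self):
        g = CircuitGraph.from_raster(Raster(np.ones((3, 3)), 1.0))
        assert g.n_nodes == 9
        assert len(g.edges_g) == 20  # 12 orthogonal + 8 diagonal

    def test_invalid_rasters_rejected(self):
        with pytest.raises(ValueError):
            CircuitGraph.from_raster(Raster(np.full((3, 3), np.nan), 1.0))
        with pytest.raises(ValueError):
            CircuitGraph.from_raster(Raster(np.zeros((3, 3)), 1.0))


class TestSolvePair:
    def test_series_chain_carries_full_current(self):
        r = Raster(np.ones((1, 3)), 1.0)
        g = CircuitGraph.from_raster(r)
        sol = g.solve_pair((0, 0), (0, 2))
        np.testing.assert_allclose(sol.node_currents, 1.0, atol=1e-12)
        assert sol.voltages[g.node_of((0, 0))] == pytest.approx(2.0)  # two unit resistors

    def test_two_parallel_paths_split_evenly(self):
        g = CircuitGraph.from_edges(4, [(0, 1, 1.0), (1, 3, 1.0),
                                        (0, 2, 1.0), (2, 3, 1.0)])
        sol = g.solve_pair(0, 3)
        assert sol.node_currents[1] == pytest.approx(0.5)
        assert sol.node_currents[2] == pytest.approx(0.5)

    def test_source_equals_ground_rejected(self):
        g = CircuitGraph.from_raster(Raster(np.ones((2, 2)), 1.0))
        with pytest.raises(ValueError):
            g.solve_pair((0, 0), (0, 0))

    def test_disconnected_pair_names_components(self):
        data = np.ones((1, 5))
        data[0, 2] = np.nan  # break the chain
        g = CircuitGraph.from_raster(Raster(data, 1.0))
        with pytest.raises(ValueError, match="component"):
            g.solve_pair((0, 0), (0, 4))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_dense_oracle_on_random_grids(self, seed):
        rng = np.random.default_rng(seed)
        shape = (int(rng.integers(2, 7)), int(rng.integers(2, 7)))
        g = CircuitGraph.from_raster(Raster(rng.uniform(0.1, 5.0, shape), 1.0))
        source, ground = rng.choice(g.n_nodes, size=2, replace=False)
        sol = g.solve_pair(int(source), int(ground))
        v_oracle = dense_solve(g, int(source), int(ground))
        np.testing.assert_allclose(sol.voltages, v_oracle, rtol=1e-8, atol=1e-11)
        # per-cell current from the oracle voltages
        cur = np.zeros(g.n_nodes)
        ec = g.edges_g * (v_oracle[g.edges_u] - v_oracle[g.edges_v])
        np.add.at(cur, g.edges_u, np.abs(ec))
        np.add.at(cur, g.edges_v, np.abs(ec))
        cur *= 0.5
        cur[[source, ground]] = 1.0
        np.testing.assert_allclose(sol.node_currents, cur, rtol=1e-8, atol=1e-11)

    @pytest.mark.parametrize("seed", range(20))
    def test_kirchhoff_conservation_at_interior_nodes(self, seed):
        rng = np.random.default_rng(100 + seed)
        g = CircuitGraph.from_raster(Raster(rng.uniform(0.2, 3.0, (5, 5)), 1.0))
        source, ground = rng.choice(g.n_nodes, size=2, replace=False)
        sol = g.solve_pair(int(source), int(ground))
        net = np.zeros(g.n_nodes)
        np.add.at(net, g.edges_u, -sol.edge_currents)
        np.add.at(net, g.edges_v, sol.edge_currents)
        interior = np.ones(g.n_nodes, dtype=bool)
        interior[[source, ground]] = False
        assert np.abs(net[interior]).max() < 1e-9
        # total current entering ground equals the injection
        assert net[ground] == pytest.approx(1.0, abs=1e-9)

    def test_symmetry_across_source_ground_axis(self):
        g = CircuitGraph.from_raster(Raster(np.ones((5, 5)), 1.0))
        sol = g.solve_pair((2, 0), (2, 4))
        grid = sol.current.data
        np.testing.assert_allclose(grid, grid[::-1, :], atol=1e-10)

    def test_raising_path_conductance_does_not_reduce_path_current(self):
        """A 1-wide bridge between source and ground: higher bridge
        conductance cannot lower the current through it."""
        def bridge_current(gc):
            data = np.full((3, 3), 0.2)
            data[1, :] = gc
            g = CircuitGraph.from_raster(Raster(data, 1.0))
            return g.solve_pair((1, 0), (1, 2)).node_currents[g.node_of((1, 1))]

        currents = [bridge_current(gc) for gc in (0.2, 0.5, 1.0, 2.0)]
        assert all(b >= a - 1e-12 for a, b in zip(currents, currents[1:]))


class TestEffectiveResistance:
    def test_series_law(self):
        g = CircuitGraph.from_edges(3, [(0, 1, 1 / 2.0), (1, 2, 1 / 3.0)])
        assert effective_resistance(g, 0, 2) == pytest.approx(5.0)

    def test_parallel_law(self):
        g = CircuitGraph.from_edges(2, [(0, 1, 1 / 2.0), (0, 1, 1 / 3.0)])
        assert effective_resistance(g, 0, 1) == pytest.approx(1 / (1 / 2 + 1 / 3))

    def test_matches_laplacian_pseudoinverse(self, rng):
        n = 8
        edges = [(int(u), int(v), float(rng.uniform(0.5, 2.0)))
                 for u in range(n) for v in range(u + 1, n) if rng.uniform() < 0.5]
        edges += [(i, i + 1, 1.0) for i in range(n - 1)]  # ensure connected
        g = CircuitGraph.from_edges(n, edges)
        Lp = np.linalg.pinv(g.laplacian().toarray())
        for a, b in [(0, 5), (2, 7), (1, 3)]:
            oracle = Lp[a, a] + Lp[b, b] - 2 * Lp[a, b]
            assert effective_resistance(g, a, b) == pytest.approx(oracle, rel=1e-10)


class TestFillOutside:
    def test_min_median_fill_by_hand(self):
        cond = Raster(np.array([[0.2, 0.4, np.nan], [0.6, 0.8, np.nan]]), 1.0)
        study = cond.like([[1, 1, 0], [1, 1, 0]])
        ocean = cond.like([[0, 0, 1], [0, 0, 0]])
        out = fill_outside(cond, study, ocean)
        assert out.data[0, 2] == pytest.approx(0.2)  # ocean <- min
        assert out.data[1, 2] == pytest.approx(0.5)  # outside land <- median
        np.testing.assert_allclose(out.data[:, :2], cond.data[:, :2])

    def test_no_outside_cells_is_identity(self, rng):
        cond = Raster(rng.uniform(0.1, 1, (4, 4)), 1.0)
        study = cond.like(np.ones((4, 4)))
        ocean = cond.like(np.zeros((4, 4)))
        np.testing.assert_array_equal(fill_outside(cond, study, ocean).data, cond.data)

    def test_random_fill_matches_brute_force(self, rng):
        cond = Raster(rng.uniform(0.1, 1, (6, 6)), 1.0)
        study = cond.like(rng.integers(0, 2, (6, 6)).astype(float))
        if not study.data.any():
            study.data[0, 0] = 1
        ocean = cond.like((rng.uniform(size=(6, 6)) < 0.3).astype(float) * (1 - study.data))
        out = fill_outside(cond, study, ocean)
        vals = cond.data[study.data > 0]
        for i in range(6):
            for j in range(6):
                if study.data[i, j] > 0:
                    exp = cond.data[i, j]
                elif ocean.data[i, j] > 0:
                    exp = vals.min()
                else:
                    exp = np.median(vals)
                assert out.data[i, j] == pytest.approx(exp)

    def test_empty_study_area_rejected(self):
        cond = Raster(np.ones((3, 3)), 1.0)
        with pytest.raises(ValueError):
            fill_outside(cond, cond.like(np.zeros((3, 3))), cond.like(np.zeros((3, 3))))


class TestGroundRing:
    def test_single_site_350km_buffer_gives_220_nodes(self):
        pts = place_ground_ring([ReleaseSite("s", 0.0, 0.0)], buffer_km=350.0,
                                spacing_km=10.0)
        assert len(pts) == 220  # ceil(2*pi*350 / 10)
        radii = np.hypot(pts[:, 0], pts[:, 1])
        np.testing.assert_allclose(radii, 350_000.0, rtol=1e-3)

    def test_quarter_perimeter_spacing_gives_four_nodes(self):
        perimeter_km = 2 * np.pi * 50.0
        pts = place_ground_ring([ReleaseSite("s", 0.0, 0.0)], buffer_km=50.0,
                                spacing_km=perimeter_km / 4.0)
        assert len(pts) == 4

    def test_two_site_union_count_matches_perimeter_oracle(self):
        from shapely.geometry import Point
        from shapely.ops import unary_union
        sites = [ReleaseSite("a", 0.0, 0.0), ReleaseSite("b", 100_000.0, 0.0)]
        pts = place_ground_ring(sites, buffer_km=80.0, spacing_km=10.0)
        union = unary_union([Point(s.x, s.y).buffer(80_000.0, quad_segs=64)
                             for s in sites])
        assert len(pts) == int(np.ceil(union.exterior.length / 10_000.0))

    def test_invalid_buffer_rejected(self):
        with pytest.raises(ValueError):
            place_ground_ring([ReleaseSite("s", 0.0, 0.0)], buffer_km=-1.0)

    def test_ring_cells_unique_and_on_grid(self):
        r = Raster(np.ones((50, 50)), 2_000.0, x_origin=-50_000.0, y_origin=50_000.0)
        pts = place_ground_ring([ReleaseSite("s", 0.0, 0.0)], buffer_km=40.0,
                                spacing_km=10.0)
        cells = ring_cells(pts, r)
        assert len(cells) == len(set(cells))
        assert all(0 <= c[0] < 50 and 0 <= c[1] < 50 for c in cells)


class TestMapAlgebra:
    def _cm(self, data):
        from condorcircuit.circuit import CurrentMap
        return CurrentMap(raster=Raster(np.asarray(data, float), 1.0), units="A")

    def test_mean_converts_to_milliamps(self):
        out = mean_current([self._cm(np.full((2, 2), 0.005))])
        assert out.units == "mA"
        np.testing.assert_allclose(out.data, 5.0)

    def test_mean_of_identical_maps_is_that_map(self, rng):
        m = self._cm(rng.uniform(0, 1, (3, 3)))
        out = mean_current([m, m, m])
        np.testing.assert_allclose(out.data, m.data * 1000.0)

    def test_mean_matches_hand_average(self, rng):
        maps = [self._cm(rng.uniform(0, 1, (2, 3))) for _ in range(3)]
        out = mean_current(maps)
        exp = (maps[0].data + maps[1].data + maps[2].data) / 3 * 1000
        np.testing.assert_allclose(out.data, exp)

    def test_misaligned_maps_rejected(self):
        from condorcircuit.circuit import CurrentMap
        a = self._cm(np.ones((2, 2)))
        b = CurrentMap(raster=Raster(np.ones((3, 3)), 1.0), units="A")
        with pytest.raises(ValueError):
            mean_current([a, b])

    def test_combine_max_idempotent_and_zero_identity(self, rng):
        m = self._cm(rng.uniform(0, 1, (3, 3)))
        z = self._cm(np.zeros((3, 3)))
        np.testing.assert_array_equal(combine_max(m, m).data, m.data)
        np.testing.assert_array_equal(combine_max(m, z).data, m.data)

    def test_combine_max_matches_loop_oracle(self, rng):
        a, b = self._cm(rng.uniform(0, 1, (4, 4))), self._cm(rng.uniform(0, 1, (4, 4)))
        out = combine_max(a, b).data
        for i in range(4):
            for j in range(4):
                assert out[i, j] == max(a.data[i, j], b.data[i, j])


def test_ring_mean_current_smoke():
    rng = np.random.default_rng(1)
    cond = Raster(rng.uniform(0.2, 1.0, (21, 21)), 2_000.0,
                  x_origin=-21_000.0, y_origin=21_000.0)
    graph = CircuitGraph.from_raster(cond)
    pts = place_ground_ring([ReleaseSite("s", 0.0, 0.0)], buffer_km=18.0, spacing_km=10.0)
    grounds = ring_cells(pts, cond)
    out = ring_mean_current(graph, [((10, 10), 1.0)], grounds)
    assert out.units == "mA"
    assert np.isfinite(out.data).all() and (out.data >= 0).all()
    assert out.data[10, 10] == pytest.approx(1000.0)  # source cell: 1 A -> 1000 mA
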