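import math

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from scgeom.ph import (
    Filtration,
    FiltrationError,
    PersistenceDiagram,
    cap_diagram,
    diagram_wasserstein,
    edge_weighted_vr_filtration,
    persistence,
    persistence_oracle,
    relative_persistence,
    relative_persistence_oracle,
    vertex_clique_filtration,
    vr_filtration,
)


class Net:
    def __init__(self, n, edges=None, edge_weight=None, node_weight=None):
        self.gene_ids = [f"g{i}" for i in range(n)]
        self.edge_weight = edge_weight
        self.node_weight = node_weight
        self.edges = edges if edges is not None else set(edge_weight or {})


class TestVRFiltration:
    def test_two_points(self):
        f = vr_filtration([[0.0, 1.0], [1.0, 0.0]], max_dim=0)
        assert f.simplices == [((0,), 0.0), ((1,), 0.0), ((0, 1), 1.0)]

    def test_unit_square_entry_values(self, unit_square_filtration):
        values = dict(unit_square_filtration.simplices)
        sides = [((0, 1)), ((1, 2)), ((2, 3)), ((0, 3))]
        assert all(values[s] == pytest.approx(1.0) for s in sides)
        assert values[(0, 2)] == pytest.approx(math.sqrt(2))
        assert values[(1, 3)] == pytest.approx(math.sqrt(2))
        tri_values = [v for s, v in unit_square_filtration.simplices if len(s) == 3]
        assert len(tri_values) == 4 and all(v == pytest.approx(math.sqrt(2)) for v in tri_values)

    def test_max_scale_truncates(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        f = vr_filtration(squareform(pdist(pts)), max_dim=1, max_scale=0.5)
        assert all(len(s) == 1 for s, _ in f.simplices)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            vr_filtration([[0.0, 1.0], [2.0, 0.0]])


class TestEdgeWeightedFiltration:
    def test_single_edge_enters_at_zero(self):
        f = edge_weighted_vr_filtration(Net(2, edge_weight={(0, 1): 3.0}), max_dim=1)
        assert f.simplices == [((0,), 0.0), ((1,), 0.0), ((0, 1), 0.0)]

    def test_triangle_min_weight_rule(self):
        net = Net(3, edge_weight={(0, 1): 3.0, (1, 2): 2.0, (0, 2): 1.0})
        values = dict(edge_weighted_vr_filtration(net, max_dim=1).simplices)
        assert values[(0, 1)] == 0.0 and values[(1, 2)] == 1.0 and values[(0, 2)] == 2.0
        assert values[(0, 1, 2)] == 2.0

    def test_empty_edge_set_vertices_at_delta_max(self):
        f = edge_weighted_vr_filtration(Net(3, edges=set(), edge_weight={}), max_dim=1)
        assert f.simplices == [((0,), 0.0), ((1,), 0.0), ((2,), 0.0)]

    def test_constant_weight_shift_leaves_diagram_unchanged(self, rng):
        w = {(0, 1): 2.0, (1, 2): 1.0, (2, 3): 3.0, (0, 3): 0.5, (0, 2): 1.5}
        d1 = persistence(edge_weighted_vr_filtration(Net(4, edge_weight=w), max_dim=1))
        w2 = {e: v + 4.0 for e, v in w.items()}
        d2 = persistence(edge_weighted_vr_filtration(Net(4, edge_weight=w2), max_dim=1))
        assert d1 == d2

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            edge_weighted_vr_filtration(Net(2, edge_weight={(0, 1): -1.0}))


class TestVertexCliqueFiltration:
    def test_path_min_endpoint_rule(self):
        net = Net(3, edges={(0, 1), (1, 2)}, node_weight={0: 3.0, 1: 1.0, 2: 2.0})
        values = dict(vertex_clique_filtration(net, max_dim=1).simplices)
        assert values[(0,)] == 0.0 and values[(1,)] == 2.0 and values[(2,)] == 1.0
        assert values[(0, 1)] == 2.0 and values[(1, 2)] == 2.0

    def test_equal_weights_collapse_to_single_value(self):
        net = Net(3, edges={(0, 1), (1, 2), (0, 2)}, node_weight={i: 2.0 for i in range(3)})
        f = vertex_clique_filtration(net, max_dim=1)
        assert {v for _, v in f.simplices} == {0.0}

    def test_isolated_high_weight_vertex_extra_bar(self):
        net = Net(3, edges={(0, 1)}, node_weight={0: 1.0, 1: 1.0, 2: 5.0})
        d = persistence(vertex_clique_filtration(net, max_dim=1))
        inf_bars = [(b, dd) for b, dd in d.of_dim(0) if math.isinf(dd)]
        assert (0.0, math.inf) in inf_bars  # vertex 2 born at delta_max - 5 = 0
        assert len(inf_bars) == 2

    def test_missing_node_weight_rejected(self):
        net = Net(2, edges={(0, 1)}, node_weight={0: 1.0})
        with pytest.raises(ValueError, match="missing"):
            vertex_clique_filtration(net)


class TestPersistence:
    def test_single_point(self):
        d = persistence(Filtration([((0,), 0.0)], max_dim=0))
        assert d.pairs == [(0, 0.0, math.inf)]

    def test_two_points_one_edge(self):
        d = persistence(Filtration([((0,), 0.0), ((1,), 0.0), ((0, 1), 1.0)], max_dim=0))
        assert sorted(d.of_dim(0)) == [(0.0, 1.0), (0.0, math.inf)]

    def test_unit_square_h1(self, unit_square_filtration):
        d = persistence(unit_square_filtration)
        assert d.of_dim(1) == [(1.0, pytest.approx(math.sqrt(2)))]

    def test_oracle_empty(self):
        assert len(persistence_oracle(Filtration([], max_dim=1))) == 0

    def test_nonmonotone_rejected(self):
        bad = Filtration([((0,), 0.0), ((1,), 0.0), ((0, 1), 1.0), ((0, 1, 2), 0.5)], max_dim=1)
        with pytest.raises(FiltrationError):
            persistence(bad)

    def test_h0_bar_count_equals_point_count(self, rng):
        pts = rng.normal(size=(9, 2))
        d = persistence(vr_filtration(squareform(pdist(pts)), max_dim=0))
        assert len(d.of_dim(0)) == 9  # n-1 finite merges + 1 infinite bar
        assert sum(1 for _, dd in d.of_dim(0) if math.isinf(dd)) == 1

    def test_optimized_equals_oracle_on_random_clouds(self, rng):
        for _ in range(40):
            n = int(rng.integers(3, 12))
            pts = rng.normal(size=(n, int(rng.integers(1, 4))))
            f = vr_filtration(squareform(pdist(pts)), max_dim=int(rng.integers(0, 3)))
            assert persistence(f) == persistence_oracle(f)

    def test_diagram_csv_roundtrip(self, tmp_path, unit_square_filtration):
        d = persistence(unit_square_filtration)
        p = tmp_path / "diag.csv"
        d.write_csv(p)
        assert PersistenceDiagram.read_csv(p) == d
        assert "inf" in p.read_text()


class TestRelativePersistence:
    def test_empty_l_equals_absolute(self, unit_square_filtration):
        assert relative_persistence(unit_square_filtration, set()) == persistence(
            unit_square_filtration
        )

    def test_l_equals_k_gives_empty_diagram(self, unit_square_filtration):
        assert len(relative_persistence(unit_square_filtration, {0, 1, 2, 3})) == 0

    def test_two_far_points_relative_to_one(self):
        f = vr_filtration([[0.0, 5.0], [5.0, 0.0]], max_dim=1)
        d = relative_persistence(f, {0})
        assert d.pairs == [(0, 0.0, 5.0)]

    def test_cone_matches_quotient_oracle_random(self, rng):
        for _ in range(40):
            n = int(rng.integers(4, 12))
            pts = rng.normal(size=(n, 2))
            f = vr_filtration(
                squareform(pdist(pts)), max_dim=1,
                max_scale=float(np.percentile(pdist(pts), 80)),
            )
            L = set(rng.choice(n, size=int(rng.integers(0, n)), replace=False).tolist())
            assert relative_persistence(f, L) == relative_persistence_oracle(f, L)


class TestWasserstein:
    def test_identity_is_zero(self, unit_square_filtration):
        d = cap_diagram(persistence(unit_square_filtration), 2.0)
        assert diagram_wasserstein(d, d, 0) == 0.0
        assert diagram_wasserstein(d, d, 1) == 0.0

    def test_single_bar_to_empty_costs_half_persistence(self):
        d1 = PersistenceDiagram([(0, 0.0, 1.0)])
        assert diagram_wasserstein(d1, PersistenceDiagram([]), 0, q=1.0) == pytest.approx(0.5)

    def test_matching_beats_diagonal_route(self):
        d1 = PersistenceDiagram([(0, 0.0, 2.0)])
        d2 = PersistenceDiagram([(0, 0.0, 1.0)])
        assert diagram_wasserstein(d1, d2, 0, q=1.0) == pytest.approx(1.0)

    def test_symmetry_and_triangle_inequality(self, rng):
        def rand_diag():
            pairs = []
            for _ in range(int(rng.integers(0, 6))):
                b = rng.uniform(0, 2)
                pairs.append((0, b, b + rng.uniform(0.01, 2)))
            return PersistenceDiagram(pairs)

        for _ in range(30):
            a, b, c = rand_diag(), rand_diag(), rand_diag()
            dab = diagram_wasserstein(a, b, 0)
            assert dab == pytest.approx(diagram_wasserstein(b, a, 0))
            assert dab <= diagram_wasserstein(a, c, 0) + diagram_wasserstein(c, b, 0) + 1e-8

    def test_infinite_deaths_must_be_capped(self):
        d = PersistenceDiagram([(0, 0.0, math.inf)])
        with pytest.raises(ValueError, match="cap"):
            diagram_wasserstein(d, PersistenceDiagram([]), 0)
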