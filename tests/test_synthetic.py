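import numpy as np
import pytest
from scipy.stats import ttest_ind

from scgeom.preprocess import knn_graph
from scgeom.synthetic import (
    FixtureSpec,
    generate,
    make_blob,
    make_bridge_clusters,
    make_modular_network,
    make_nb_counts,
    make_pluripotency_profiles,
    make_ring,
    make_topo_signal_classes,
)


class TestDeterminism:
    @pytest.mark.parametrize(
        "kind,params",
        [
            ("bridge_clusters", {"n_core": 20, "n_bridge": 8}),
            ("ring", {"n": 20}),
            ("blob", {"n": 20}),
            ("modular_network", {"n_genes": 20}),
            ("topo_signal_classes", {"n_cells": 40}),
            ("nb_counts", {"n_cells": 10, "n_genes": 8}),
        ],
    )
    def test_same_seed_same_output(self, kind, params):
        a = generate(FixtureSpec(kind=kind, params=params, seed=3))
        b = generate(FixtureSpec(kind=kind, params=params, seed=3))

        def values(x):
            if isinstance(x, tuple):
                x = x[0]
            return getattr(x, "coords", getattr(x, "values", x))

        if kind == "modular_network":
            assert a == b
        else:
            assert np.array_equal(values(a), values(b))

    def test_different_seeds_differ(self):
        a = make_blob(n=20, seed=1)
        b = make_blob(n=20, seed=2)
        assert not np.array_equal(a, b)


class TestBridgeClusters:
    def test_no_bridge_graph_disconnects(self):
        import networkx as nx

        E, labels = make_bridge_clusters(n_core=40, n_bridge=0, seed=0)
        G = knn_graph(E, k=4)
        g = nx.Graph(G.edges)
        g.add_nodes_from(range(E.n_cells))
        assert nx.number_connected_components(g) >= 2

    def test_labels_and_counts(self):
        E, labels = make_bridge_clusters(n_core=10, n_bridge=4, n_clusters=3, seed=0)
        assert E.n_cells == 34
        assert sorted(set(labels)) == ["bridge0", "bridge1", "core0", "core1", "core2"]

    def test_vanishing_separation_kills_curvature_contrast(self):
        from scgeom.curvature import orc_all

        E, labels = make_bridge_clusters(separation=0.1, seed=0)
        G = knn_graph(E, k=10)
        res = orc_all(G)
        nc = np.array([res.node_curvature[v] for v in range(E.n_cells)])
        is_b = np.char.startswith(labels.astype(str), "bridge")
        pooled = np.sqrt((nc[is_b].var() + nc[~is_b].var()) / 2)
        effect = abs(nc[is_b].mean() - nc[~is_b].mean()) / pooled
        assert effect < 0.2


class TestRing:
    def test_dominant_h1_bar(self):
        from scipy.spatial.distance import pdist, squareform

        from scgeom.ph import persistence, vr_filtration

        pts = make_ring(n=60, radius=1.0, noise_sd=0.05, seed=0)
        d = persistence(vr_filtration(squareform(pdist(pts)), max_dim=1), validate=False)
        pers = sorted((dd - b for b, dd in d.of_dim(1)), reverse=True)
        assert pers[0] > 3 * pers[1]

    def test_noiseless_birth_death(self):
        from scipy.spatial.distance import pdist, squareform

        from scgeom.ph import persistence, vr_filtration

        n = 60
        pts = make_ring(n=n, radius=1.0, noise_sd=0.0, seed=0)
        d = persistence(vr_filtration(squareform(pdist(pts)), max_dim=1), validate=False)
        (b, dd), = d.of_dim(1)
        assert b == pytest.approx(2 * np.sin(np.pi / n), abs=1e-9)
        assert dd == pytest.approx(np.sqrt(3), abs=1e-6)

    def test_minimum_size(self):
        with pytest.raises(ValueError):
            make_ring(n=5)


class TestModularNetwork:
    def test_connected_and_denser_within_modules(self):
        import networkx as nx

        edges, modules = make_modular_network(seed=0)
        g = nx.Graph(edges)
        g.add_nodes_from(modules)
        largest = max(nx.connected_components(g), key=len)
        assert len(largest) >= 0.95 * len(modules)
        within = sum(1 for a, b in edges if modules[a] == modules[b])
        across = len(edges) - within
        n_within_pairs = sum(1 for a in modules for b in modules
                             if a < b and modules[a] == modules[b])
        n_across_pairs = sum(1 for a in modules for b in modules
                             if a < b and modules[a] != modules[b])
        assert within / n_within_pairs > across / n_across_pairs

    def test_p_in_must_exceed_p_out(self):
        with pytest.raises(ValueError):
            make_modular_network(p_in=0.1, p_out=0.2)


class TestPluripotencyProfiles:
    def test_zero_noise_localized_support_is_the_module(self):
        edges, modules = make_modular_network(seed=0)
        X, labels = make_pluripotency_profiles(
            sorted(modules), modules, n_cells=5, noise=0.0, background=0.0, seed=0
        )
        loc = X.values[labels == "localized"]
        genes = sorted(modules)
        active = set(np.array(genes)[loc[0] > 0])
        assert active == {g for g in genes if modules[g] == 0}

    def test_broad_fewer_components_mid_filtration(self):
        from scgeom.features import betti_curve
        from scgeom.gene_topology import attach_node_weights, gene_network_features
        from scgeom.ph import cap_diagram, persistence, vertex_clique_filtration

        edges, modules = make_modular_network(seed=0)
        X, labels = make_pluripotency_profiles(sorted(modules), modules, n_cells=20, seed=0)
        grid = np.linspace(0, 3.0, 50)
        curves = {"broad": [], "localized": []}
        for cell in range(X.n_cells):
            net = attach_node_weights(edges, X, cell)
            d = cap_diagram(
                persistence(vertex_clique_filtration(net, max_dim=0), validate=False),
                net.delta_max,
            )
            curves[labels[cell]].append(betti_curve(d, 0, grid).counts)
        broad = np.mean(curves["broad"], axis=0)
        localized = np.mean(curves["localized"], axis=0)
        inner = slice(5, 45)
        assert np.mean(broad[inner] <= localized[inner]) >= 0.8


class TestTopoSignalClasses:
    def test_marginal_means_matched(self):
        X, labels = make_topo_signal_classes(seed=0)
        loop = labels == "loop"
        p = np.array([
            ttest_ind(X.values[loop, j], X.values[~loop, j], equal_var=False).pvalue
            for j in range(X.n_genes)
        ])
        # non-significant at 0.01 after Bonferroni correction for >= 95% of genes
        assert np.mean(p > 0.01 / X.n_genes) >= 0.95

    def test_values_are_angles(self):
        X, _ = make_topo_signal_classes(n_cells=40, seed=1)
        assert X.values.min() >= 0 and X.values.max() < 2 * np.pi


class TestNbCounts:
    def test_raw_integral_counts(self):
        X = make_nb_counts(n_cells=20, n_genes=10, seed=0)
        assert X.layer_tag == "raw"
        assert np.array_equal(X.values, np.round(X.values))
        assert (X.values >= 0).all()

    def test_size_factor_spread(self):
        X = make_nb_counts(n_cells=400, n_genes=200, seed=0)
        totals = X.values.sum(axis=1)
        assert totals.max() / totals.min() > 2.0
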