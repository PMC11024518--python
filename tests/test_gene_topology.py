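import numpy as np
import pytest

from scgeom.gene_topology import (
    WeightedGeneNetwork,
    attach_node_weights,
    build_csn,
    csn_statistic,
    gene_network_features,
    read_network_tsv,
)
from scgeom.preprocess import ExpressionMatrix


def em(values, layer="lognorm"):
    values = np.asarray(values, float)
    n, g = values.shape
    return ExpressionMatrix(
        values, [f"c{i}" for i in range(n)], [f"g{j}" for j in range(g)], layer_tag=layer
    )


class TestCsnStatistic:
    def test_monotone_transform_invariance(self, rng):
        n = 80
        x = rng.uniform(size=n)
        y = rng.uniform(size=n)
        X1 = em(np.column_stack([x, y]))
        X2 = em(np.column_stack([np.exp(3 * x), y**3]))
        for cell in (0, 17, 55):
            assert csn_statistic(X1, cell, 0, 1) == pytest.approx(
                csn_statistic(X2, cell, 0, 1)
            )

    def test_constant_gene_warns_zero(self, rng):
        X = em(np.column_stack([np.ones(30), rng.uniform(size=30)]))
        with pytest.warns(UserWarning, match="constant"):
            assert csn_statistic(X, 0, 0, 1) == 0.0

    def test_independent_genes_mean_rho_matches_permutation_null(self, rng):
        # Monte-Carlo oracle: the exact null mean of rho under independence
        # (the statistic has a small positive O(1/n) bias because a cell
        # always lies inside its own boxes)
        from scgeom.gene_topology import _csn_null

        n = 500
        rho = []
        for rep in range(4):
            x, y = rng.uniform(size=n), rng.uniform(size=n)
            X = em(np.column_stack([x, y]))
            rho += [csn_statistic(X, cell, 0, 1) for cell in range(0, n, 4)]
        rho = np.asarray(rho)
        null = _csn_null(n, round(0.1 * n), 4000, seed=1)
        se = rho.std(ddof=1) / np.sqrt(len(rho))
        assert abs(rho.mean() - null.mean()) < 3 * se

    def test_forced_arithmetic(self):
        # rho = n_xy/n - (n_x/n)(n_y/n) directly from the counts
        assert 10 / 100 - (10 / 100) * (10 / 100) == pytest.approx(0.09)
        n = 40
        x = np.arange(n, dtype=float)
        X = em(np.column_stack([x, x]))  # identical genes: boxes coincide
        n_box = round(0.1 * n)
        assert csn_statistic(X, 20, 0, 1) == pytest.approx(n_box / n - (n_box / n) ** 2)


class TestBuildCsn:
    def test_rank_correlated_pair_always_retained(self, rng):
        n = 200
        x = rng.uniform(size=n)
        X = em(np.column_stack([x, x**2 + 1e-9 * rng.uniform(size=n)]))
        for cell in range(0, n, 20):
            net = build_csn(X, cell, n_perm=1000, seed=0)
            assert (0, 1) in net.edges
            assert net.kind == "edge_weighted"

    def test_single_gene_empty_network(self, rng):
        X = em(rng.uniform(size=(50, 1)))
        net = build_csn(X, 0, n_perm=1000, seed=0)
        assert net.edges == set()

    def test_insufficient_permutations_rejected(self, rng):
        X = em(rng.uniform(size=(50, 2)))
        with pytest.raises(ValueError, match="n_perm"):
            build_csn(X, 0, sig_level=0.01, n_perm=50)

    def test_calibration_on_independent_genes(self, rng):
        # retention rate on independent genes ~ sig_level (99% binomial CI)
        n, g = 200, 10
        X = em(rng.uniform(size=(n, g)))
        retained = trials = 0
        for cell in range(0, n, 10):
            net = build_csn(X, cell, sig_level=0.01, n_perm=1000, seed=0)
            retained += len(net.edges)
            trials += g * (g - 1) // 2
        rate = retained / trials
        half = 2.576 * np.sqrt(0.01 * 0.99 / trials)
        assert abs(rate - 0.01) < half


class TestAttachNodeWeights:
    def test_weights_are_expression_passthrough(self):
        X = em([[0.5, 1.5, 0.0], [2.0, 0.0, 1.0]])
        net = attach_node_weights([("g0", "g1"), ("g1", "g2")], X, cell=0)
        assert net.kind == "node_weighted"
        gi = {g: i for i, g in enumerate(net.gene_ids)}
        assert net.node_weight[gi["g0"]] == 0.5
        assert net.node_weight[gi["g1"]] == 1.5

    def test_gene_absent_from_matrix_gets_zero(self):
        X = em([[0.5, 1.5]])
        net = attach_node_weights([("g0", "gX")], X, cell=0)
        gi = {g: i for i, g in enumerate(net.gene_ids)}
        assert net.node_weight[gi["gX"]] == 0.0

    def test_identical_cells_identical_networks(self):
        X = em([[1.0, 2.0], [1.0, 2.0]])
        n0 = attach_node_weights([("g0", "g1")], X, 0)
        n1 = attach_node_weights([("g0", "g1")], X, 1)
        assert n0.node_weight == n1.node_weight and n0.edges == n1.edges

    def test_empty_intersection_rejected(self):
        X = em([[1.0]])
        with pytest.raises(ValueError, match="overlap"):
            attach_node_weights([("gX", "gY")], X, 0)

    def test_raw_layer_rejected(self):
        X = em([[1.0, 2.0]], layer="raw")
        with pytest.raises(ValueError):
            attach_node_weights([("g0", "g1")], X, 0)


class TestGeneNetworkFeatures:
    def test_node_weighted_star_h0_total(self):
        # center weight 5 born at 0; leaves weight 1 born at 4, absorbed at 4
        net = WeightedGeneNetwork(
            gene_ids=["c", "l1", "l2", "l3"],
            edges={(0, 1), (0, 2), (0, 3)},
            node_weight={0: 5.0, 1: 1.0, 2: 1.0, 3: 1.0},
            kind="node_weighted",
        )
        rec = gene_network_features(net, max_dim=1, include_betti=False)
        assert rec["h0_total_persistence"] == pytest.approx(5.0)
        assert rec["h1_total_persistence"] == 0.0

    def test_empty_network_zero_features(self):
        net = WeightedGeneNetwork(gene_ids=[], edges=set(), edge_weight={}, kind="edge_weighted")
        rec = gene_network_features(net, include_betti=False)
        assert rec["h0_total_persistence"] == 0.0 and rec["h1_entropy"] == 0.0

    def test_broad_vs_localized_profiles_direction(self):
        from scipy.stats import mannwhitneyu

        from scgeom.gene_topology import prior_network_features_table
        from scgeom.synthetic import make_modular_network, make_pluripotency_profiles

        edges, modules = make_modular_network(seed=0)
        X, labels = make_pluripotency_profiles(sorted(modules), modules, n_cells=25, seed=0)
        tab = prior_network_features_table(edges, X, max_dim=1)
        broad = labels == "broad"
        h0 = tab["h0_total_persistence"].to_numpy()
        h1 = tab["h1_total_persistence"].to_numpy()
        assert mannwhitneyu(h0[broad], h0[~broad], alternative="less").pvalue < 0.01
        assert mannwhitneyu(h1[broad], h1[~broad], alternative="greater").pvalue < 0.01

    def test_network_kind_validation(self):
        with pytest.raises(ValueError):
            WeightedGeneNetwork(gene_ids=["a"], edges=set(), kind="edge_weighted")
        with pytest.raises(ValueError):
            WeightedGeneNetwork(
                gene_ids=["a"], edges=set(), edge_weight={}, node_weight={0: 1.0},
                kind="edge_weighted",
            )


def test_read_network_tsv(tmp_path):
    p = tmp_path / "net.tsv"
    p.write_text("gA\tgB\t0.5\ngB\tgC\t0.7\n")
    assert read_network_tsv(p) == [("gA", "gB"), ("gB", "gC")]
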