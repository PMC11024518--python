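"""Seeded synthetic-data generators for every structure the pipeline
consumes.

These generators are first-class, tested code: they plant the structures
the geometric and topological statistics are designed to detect, so the
whole pipeline is exercisable without external downloads.

* :func:`make_bridge_clusters` -- dense Gaussian cluster cores connected by
  sparse corridors of cells (stable states + transition cells).
* :func:`make_ring` / :func:`make_blob` -- point sets with and without a
  planted one-dimensional loop.
* :func:`make_modular_network` -- planted-partition gene graph standing in
  for a knowledge-based prior network.
* :func:`make_pluripotency_profiles` -- node-weight profiles on a modular
  network that are either broadly active (pluripotent-like) or localized to
  one module (differentiated-like).
* :func:`make_topo_signal_classes` -- two cell classes with identical
  per-gene marginals whose gene-gene dependence differs in topology (a
  co-activation loop vs. disjoint pairs), so cell-specific-network topology
  separates them while mean expression does not.
* :func:`make_nb_counts` -- negative-binomial raw counts with a x3 spread
  of cell size factors, to exercise count normalization realistically.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import Embedding, ExpressionMatrix

__all__ = [
    "FixtureSpec",
    "generate",
    "make_bridge_clusters",
    "make_ring",
    "make_blob",
    "make_modular_network",
    "make_pluripotency_profiles",
    "make_topo_signal_classes",
    "make_nb_counts",
]


def make_bridge_clusters(
    n_core: int = 120,
    n_bridge: int = 60,
    n_clusters: int = 2,
    separation: float = 10.0,
    noise_sd: float = 1.0,
    dim: int = 2,
    seed: int = 0,
):
    """Gaussian cluster cores at separated centers plus bridge cells spread
    along the inter-center segments (interior 10-90% of each segment, same
    Gaussian noise). Returns (Embedding, labels) with labels ``core<i>`` /
    ``bridge<i>``."""
    if n_clusters < 2:
        raise ValueError("need at least 2 clusters")
    rng = np.random.default_rng(seed)
    centers = np.zeros((n_clusters, dim))
    for c in range(n_clusters):
        angle = 2 * np.pi * c / n_clusters
        centers[c, 0] = separation * np.cos(angle)
        if dim > 1:
            centers[c, 1] = separation * np.sin(angle)
    pts, labels = [], []
    for c in range(n_clusters):
        pts.append(centers[c] + rng.normal(0, noise_sd, size=(n_core, dim)))
        labels += [f"core{c}"] * n_core
    n_seg = n_clusters - 1
    per_seg = [n_bridge // n_seg + (1 if s < n_bridge % n_seg else 0) for s in range(n_seg)]
    for s in range(n_seg):
        t = rng.uniform(0.1, 0.9, size=per_seg[s])[:, None]
        base = centers[s] + t * (centers[s + 1] - centers[s])
        pts.append(base + rng.normal(0, noise_sd, size=(per_seg[s], dim)))
        labels += [f"bridge{s}"] * per_seg[s]
    coords = np.vstack(pts)
    ids = [f"c{i:04d}" for i in range(len(coords))]
    return Embedding(coords, ids), np.array(labels)


def make_ring(n: int = 60, radius: float = 1.0, noise_sd: float = 0.05, seed: int = 0):
    """Noisy circle: n evenly spaced angles, Gaussian coordinate noise."""
    if n < 8:
        raise ValueError("need at least 8 points for a recognizable ring")
    rng = np.random.default_rng(seed)
    angles = 2 * np.pi * np.arange(n) / n
    pts = radius * np.column_stack([np.cos(angles), np.sin(angles)])
    return pts + rng.normal(0, noise_sd, size=pts.shape)


def make_blob(n: int = 60, sd: float = 1.0, dim: int = 2, seed: int = 0):
    """Isotropic Gaussian blob (no planted loop)."""
    rng = np.random.default_rng(seed)
    return rng.normal(0, sd, size=(n, dim))


def make_modular_network(
    n_genes: int = 40,
    n_modules: int = 4,
    p_in: float = 0.6,
    p_out: float = 0.05,
    seed: int = 0,
):
    """Planted-partition gene graph: within-module edges at p_in, cross-
    module at p_out (p_in > p_out). Returns (edge list of gene-id pairs,
    module assignment dict)."""
    if not p_in > p_out:
        raise ValueError("p_in must exceed p_out")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:03d}" for i in range(n_genes)]
    module = {genes[i]: i % n_modules for i in range(n_genes)}
    edges = []
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            p = p_in if module[genes[i]] == module[genes[j]] else p_out
            if rng.uniform() < p:
                edges.append((genes[i], genes[j]))
    return edges, module


def make_pluripotency_profiles(
    genes,
    modules: dict,
    n_cells: int = 50,
    broad_level: float = 1.0,
    localized_level: float = 3.0,
    background: float = 0.05,
    localized_module: int = 0,
    noise: float = 0.1,
    seed: int = 0,
):
    """Node-weight profiles over a modular gene network.

    ``broad`` cells (pluripotent-like) express every module at a moderate
    level; ``localized`` cells (differentiated-like) express one module
    highly and the rest near zero. Values are on a log-normalized scale
    (layer ``lognorm``), clipped at 0. Returns (ExpressionMatrix, labels).
    """
    rng = np.random.default_rng(seed)
    genes = list(genes)
    g = len(genes)
    in_module = np.array([modules[x] == localized_module for x in genes])
    broad = broad_level + rng.normal(0, noise, size=(n_cells, g))
    loc_mean = np.where(in_module, localized_level, background)
    localized = loc_mean + rng.normal(0, noise, size=(n_cells, g))
    values = np.clip(np.vstack([broad, localized]), 0, None)
    ids = [f"c{i:04d}" for i in range(2 * n_cells)]
    labels = np.array(["broad"] * n_cells + ["localized"] * n_cells)
    return ExpressionMatrix(values, ids, genes, layer_tag="lognorm"), labels


def make_topo_signal_classes(
    n_cells: int = 300,
    n_genes: int = 12,
    seed: int = 0,
    step_sd: float = 0.35,
    pairs_arc: float = 1.8,
):
    """Two cell classes with identical per-gene marginals but different
    co-activation topology.

    Every gene's value is an angle in [0, 2*pi), exactly uniform in both
    classes, so per-gene means carry no class signal. The classes differ in
    how genes co-vary within a cell. In the ``loop`` class the gene values
    follow a wrapped Brownian bridge around the gene ring (step standard
    deviation ``step_sd``): consecutive genes are tightly coupled, coupling
    decays with ring distance, and the gene-gene dependency graph is a
    (locally thickened) cycle. In the ``pairs`` class each disjoint gene
    pair is a two-step walk with the same step_sd, anchored uniformly on an
    arc of half-width ``pairs_arc`` around a shared per-cell state: the
    pairwise coupling strength matches the loop class's, the dependency
    graph is six dumbbells over diffuse background coupling, and no cycle is
    planted; the shared state keeps the per-cell profile spread from
    trivially revealing the class to a classifier on raw expression.
    Cell-specific-network topology separates the classes; mean expression
    does not. Returns (ExpressionMatrix, labels).
    """
    if n_genes % 2 or n_genes < 6:
        raise ValueError("n_genes must be even and >= 6")
    rng = np.random.default_rng(seed)
    half = n_cells // 2
    two_pi = 2 * np.pi
    # loop class: wrapped Brownian bridge around the ring (steps sum to 0)
    start = rng.uniform(0, two_pi, size=(half, 1))
    steps = rng.normal(0, step_sd, size=(half, n_genes))
    steps -= steps.mean(axis=1, keepdims=True)
    loop_vals = np.mod(start + np.cumsum(steps, axis=1), two_pi)
    # pairs class: anchors per gene pair scattered uniformly over an arc
    # around a shared cell state; the pair partner sits one bridge step away
    n_pairs = n_genes // 2
    sig_p = step_sd * np.sqrt(1.0 - 1.0 / n_genes)
    start2 = rng.uniform(0, two_pi, size=(n_cells - half, 1))
    anchors = start2 + rng.uniform(-pairs_arc, pairs_arc, size=(n_cells - half, n_pairs))
    partner = anchors + rng.normal(0, sig_p, size=anchors.shape)
    pair_vals = np.empty((n_cells - half, n_genes))
    pair_vals[:, 0::2] = np.mod(anchors, two_pi)
    pair_vals[:, 1::2] = np.mod(partner, two_pi)
    values = np.vstack([loop_vals, pair_vals])
    labels = np.array(["loop"] * half + ["pairs"] * (n_cells - half))
    ids = [f"c{i:04d}" for i in range(n_cells)]
    genes = [f"g{i:03d}" for i in range(n_genes)]
    return ExpressionMatrix(values, ids, genes, layer_tag="lognorm"), labels


def make_nb_counts(
    n_cells: int = 100,
    n_genes: int = 50,
    mean: float = 5.0,
    dispersion: float = 0.5,
    size_factor_spread: float = 3.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Negative-binomial raw counts (gamma-Poisson) with per-cell size
    factors spanning a ``size_factor_spread``-fold range."""
    rng = np.random.default_rng(seed)
    log_half = np.log(size_factor_spread) / 2
    sf = np.exp(rng.uniform(-log_half, log_half, size=n_cells))
    gene_mean = rng.gamma(shape=2.0, scale=mean / 2.0, size=n_genes)
    mu = sf[:, None] * gene_mean[None, :]
    lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * mu)
    counts = rng.poisson(lam).astype(float)
    ids = [f"c{i:04d}" for i in range(n_cells)]
    genes = [f"g{i:03d}" for i in range(n_genes)]
    return ExpressionMatrix(counts, ids, genes, layer_tag="raw")


@dataclass
class FixtureSpec:
    """Declarative fixture request: same spec + seed gives byte-identical
    output."""

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0


def generate(spec: FixtureSpec):
    """Dispatch a FixtureSpec to its generator."""
    dispatch = {
        "bridge_clusters": make_bridge_clusters,
        "ring": make_ring,
        "blob": make_blob,
        "modular_network": make_modular_network,
        "topo_signal_classes": make_topo_signal_classes,
        "nb_counts": make_nb_counts,
    }
    if spec.kind == "pluripotency_profiles":
        params = dict(spec.params)
        net_seed = params.pop("network_seed", spec.seed)
        net_kwargs = {
            k: params.pop(k) for k in ("n_genes", "n_modules", "p_in", "p_out") if k in params
        }
        edges, modules = make_modular_network(seed=net_seed, **net_kwargs)
        X, labels = make_pluripotency_profiles(
            sorted(modules), modules, seed=spec.seed, **params
        )
        return {"expression": X, "labels": labels, "network_edges": edges, "modules": modules}
    if spec.kind not in dispatch:
        raise ValueError(f"unknown fixture kind: {spec.kind!r}")
    return dispatch[spec.kind](seed=spec.seed, **spec.params)
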