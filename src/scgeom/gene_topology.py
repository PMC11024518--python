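"""Per-cell gene networks and their persistence features.

Two network flavors are supported, mirroring the two ways gene-level
structure can be attached to a single cell:

* **Cell-specific networks (CSN)** -- for each cell, the local association
  of a gene pair (x, y) is scored by the box statistic

      rho_xy = n_xy / n - (n_x / n)(n_y / n),

  where the boxes I_x, I_y are the rank-windows of the ``box_fraction * n``
  cells whose expression of the respective gene is nearest (in rank) to the
  cell's own, and n_xy counts cells falling in both boxes. Edges whose rho
  is significant against a seeded permutation null (shuffling one gene's
  values) are kept with weight rho, giving an edge-weighted network.

* **Prior-knowledge networks** -- a fixed gene graph is reused for every
  cell with the cell's log-normalized expression as node weights.

Edge-weighted networks are featurized through the descending edge-weight
Rips filtration and node-weighted networks through the vertex-based clique
filtration; H0/H1 total persistence, persistence entropy and Betti curves
summarize the diagrams.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import features as feat
from .ph import cap_diagram, edge_weighted_vr_filtration, persistence, vertex_clique_filtration
from .preprocess import ExpressionMatrix

__all__ = [
    "WeightedGeneNetwork",
    "csn_statistic",
    "build_csn",
    "attach_node_weights",
    "gene_network_features",
    "csn_features_table",
    "prior_network_features_table",
    "read_network_tsv",
]


@dataclass
class WeightedGeneNetwork:
    """Gene graph carrying either edge weights (CSN) or node weights
    (prior network + expression). Edges are index pairs (i, j), i < j,
    into ``gene_ids``."""

    gene_ids: list
    edges: set
    edge_weight: Optional[dict] = None
    node_weight: Optional[dict] = None
    kind: str = "edge_weighted"

    def __post_init__(self):
        if self.kind not in ("edge_weighted", "node_weighted"):
            raise ValueError(f"unknown network kind: {self.kind!r}")
        populated = (self.edge_weight is not None) + (self.node_weight is not None)
        if populated != 1:
            raise ValueError("exactly one of edge_weight / node_weight must be set")
        if self.kind == "edge_weighted" and self.edge_weight is None:
            raise ValueError("edge_weighted network requires edge_weight")
        if self.kind == "node_weighted" and self.node_weight is None:
            raise ValueError("node_weighted network requires node_weight")
        weights = self.edge_weight if self.kind == "edge_weighted" else self.node_weight
        if any(w < 0 for w in weights.values()):
            raise ValueError("weights must be non-negative")

    @property
    def delta_max(self) -> float:
        weights = self.edge_weight if self.kind == "edge_weighted" else self.node_weight
        return max(weights.values(), default=0.0)


def read_network_tsv(path) -> list:
    """Prior-network edge list: TSV with two gene-symbol columns (an
    optional third weight column is ignored in node-weighted mode)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return [(str(a), str(b)) for a, b in df.iloc[:, :2].itertuples(index=False)]


# ---------------------------------------------------------------------------
# CSN statistic (box statistic on rank windows)
# ---------------------------------------------------------------------------


def _rank_window(values: np.ndarray, k: int, n_box: int) -> np.ndarray:
    """Boolean membership of the symmetric rank-window of ``n_box`` cells
    around cell k's expression value, expanded greedily (ties between the
    two sides broken by lower cell index). Purely rank-based, hence
    invariant under strictly monotone transforms."""
    n = len(values)
    order = np.argsort(values, kind="stable")
    pos = int(np.nonzero(order == k)[0][0])
    members = [k]
    left, right = pos - 1, pos + 1
    while len(members) < n_box:
        if left < 0 and right >= n:
            break
        if left < 0:
            members.append(order[right]); right += 1
        elif right >= n:
            members.append(order[left]); left -= 1
        else:
            dl, dr = pos - left, right - pos
            if dl < dr or (dl == dr and order[left] < order[right]):
                members.append(order[left]); left -= 1
            else:
                members.append(order[right]); right += 1
    mask = np.zeros(n, dtype=bool)
    mask[members] = True
    return mask


def csn_statistic(
    X: ExpressionMatrix, cell: int, gene_x, gene_y, box_fraction: float = 0.1
) -> float:
    """The box statistic rho for one cell and one gene pair.

    Constant genes produce a degenerate interval: rho = 0 with a warning.
    """
    if not 0 < box_fraction < 1:
        raise ValueError("box_fraction must lie in (0, 1)")
    n = X.n_cells
    if n < 3:
        raise ValueError("need at least 3 cells")
    ix = X.gene_ids.index(gene_x) if isinstance(gene_x, str) else int(gene_x)
    iy = X.gene_ids.index(gene_y) if isinstance(gene_y, str) else int(gene_y)
    xv, yv = X.values[:, ix], X.values[:, iy]
    if xv.max() == xv.min() or yv.max() == yv.min():
        warnings.warn("constant gene: CSN interval degenerate, rho = 0")
        return 0.0
    n_box = int(round(box_fraction * n))
    mx = _rank_window(xv, cell, n_box)
    my = _rank_window(yv, cell, n_box)
    n_xy = int(np.sum(mx & my))
    return n_xy / n - (n_box / n) * (n_box / n)


_NULL_CACHE: dict = {}


def _csn_null(n: int, n_box: int, n_perm: int, seed: int, cell: int = 0) -> np.ndarray:
    """Seeded permutation null of rho: gene values are shuffled across cells
    and rho recomputed with the same rank-window routine. Simulated on
    distinct ranks (exact for tie-free genes, since under shuffling the null
    law of n_xy depends only on n and the box sizes, including the
    index-based tie-break coupling of the two windows). One independent null
    sample per cell (cached), so retention decisions for different cells do
    not share one sample's tail wobble."""
    key = (n, n_box, n_perm, seed, cell)
    if key not in _NULL_CACHE:
        rng = np.random.default_rng([seed, cell, n, n_box])
        out = np.empty(n_perm)
        for p in range(n_perm):
            mx = _rank_window(rng.permutation(n).astype(float), 0, n_box)
            my = _rank_window(rng.permutation(n).astype(float), 0, n_box)
            out[p] = np.sum(mx & my) / n - (n_box / n) ** 2
        _NULL_CACHE[key] = out
    return _NULL_CACHE[key]


def build_csn(
    X: ExpressionMatrix,
    cell: int,
    box_fraction: float = 0.1,
    sig_level: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
) -> WeightedGeneNetwork:
    """Cell-specific gene network: edges are the gene pairs whose rho is
    significant at ``sig_level`` against the seeded permutation null.

    The statistic is discrete (a count), so the permutation p-value uses a
    seeded randomized tie-break on the boundary atom, which makes the
    retention rate on independent genes equal to ``sig_level`` by
    construction. Retained edges carry weight rho.
    """
    if n_perm < 1.0 / sig_level:
        raise ValueError(
            f"n_perm={n_perm} cannot resolve sig_level={sig_level}; need >= {1/sig_level:.0f}"
        )
    n, g = X.n_cells, X.n_genes
    n_box = int(round(box_fraction * n))
    null = _csn_null(n, n_box, n_perm, seed, cell)
    tie_rng = np.random.default_rng([seed, cell, 7919])
    masks = []
    degenerate = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for gi in range(g):
            v = X.values[:, gi]
            if v.max() == v.min():
                degenerate.append(gi)
                masks.append(None)
            else:
                masks.append(_rank_window(v, cell, n_box))
    edges = {}
    for gi, gj in itertools.combinations(range(g), 2):
        if masks[gi] is None or masks[gj] is None:
            tie_rng.uniform()
            continue
        n_xy = int(np.sum(masks[gi] & masks[gj]))
        rho = n_xy / n - (n_box / n) ** 2
        greater = int(np.sum(null > rho))
        equal = int(np.sum(null == rho))
        p = (greater + tie_rng.uniform() * (equal + 1)) / (n_perm + 1)
        if p <= sig_level and rho > 0:
            edges[(gi, gj)] = rho
    return WeightedGeneNetwork(
        gene_ids=list(X.gene_ids),
        edges=set(edges),
        edge_weight=edges,
        kind="edge_weighted",
    )


def attach_node_weights(
    net_edges: Sequence, X: ExpressionMatrix, cell: int
) -> WeightedGeneNetwork:
    """Assign a cell's log-normalized expression as node weights on a prior
    gene network (edge list of gene-id pairs). Network genes absent from X
    get weight 0; an empty gene intersection is an error."""
    if X.layer_tag != "lognorm":
        raise ValueError("attach_node_weights expects a lognorm-layer matrix")
    genes = sorted({g for e in net_edges for g in e})
    pos = {g: i for i, g in enumerate(genes)}
    in_x = {g: i for i, g in enumerate(X.gene_ids)}
    if not any(g in in_x for g in genes):
        raise ValueError("no overlap between network genes and expression matrix genes")
    node_weight = {
        pos[g]: float(X.values[cell, in_x[g]]) if g in in_x else 0.0 for g in genes
    }
    edges = {tuple(sorted((pos[a], pos[b]))) for a, b in net_edges if a != b}
    return WeightedGeneNetwork(
        gene_ids=genes, edges=edges, node_weight=node_weight, kind="node_weighted"
    )


# ---------------------------------------------------------------------------
# Featurization
# ---------------------------------------------------------------------------


def gene_network_features(
    net: WeightedGeneNetwork,
    max_dim: int = 1,
    grid: Optional[np.ndarray] = None,
    n_grid: int = 100,
    include_betti: bool = True,
) -> dict:
    """Persistence features of a weighted gene network.

    Routes to the filtration matching the network kind, computes
    persistence and returns H0/H1 total persistence and entropy (deaths
    capped at the network's delta_max) plus Betti curves on a grid (100
    even values on [0, delta_max] unless a shared grid is given).
    """
    delta_max = net.delta_max
    empty = (net.kind == "edge_weighted" and not net.edge_weight) or (
        net.kind == "node_weighted" and not net.node_weight
    )
    record = {}
    if empty:
        diag = None
    else:
        if net.kind == "edge_weighted":
            filt = edge_weighted_vr_filtration(net, max_dim=max_dim)
        else:
            filt = vertex_clique_filtration(net, max_dim=max_dim)
        diag = persistence(filt, validate=False)
        diag = cap_diagram(diag, delta_max)
    if grid is None:
        grid = np.linspace(0.0, delta_max if delta_max > 0 else 1.0, n_grid)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(max_dim + 1):
            if diag is None:
                record[f"h{k}_total_persistence"] = 0.0
                record[f"h{k}_entropy"] = 0.0
                counts = np.zeros(len(grid), dtype=int)
            else:
                record[f"h{k}_total_persistence"] = feat.total_persistence(diag, k, delta_max)
                record[f"h{k}_entropy"] = feat.persistence_entropy(diag, k, delta_max)
                counts = feat.betti_curve(diag, k, grid).counts
            if include_betti:
                for j, c in enumerate(counts):
                    record[f"bc_h{k}_{j:03d}"] = int(c)
    return record


def csn_features_table(
    X: ExpressionMatrix,
    box_fraction: float = 0.1,
    sig_level: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
    max_dim: int = 1,
    include_betti: bool = False,
) -> pd.DataFrame:
    """Per-cell CSN topology features (one network + featurization per cell)."""
    rows = []
    for cell in range(X.n_cells):
        net = build_csn(
            X, cell, box_fraction=box_fraction, sig_level=sig_level,
            n_perm=n_perm, seed=seed,
        )
        rec = gene_network_features(net, max_dim=max_dim, include_betti=include_betti)
        rec["cell_id"] = X.cell_ids[cell]
        rows.append(rec)
    df = pd.DataFrame(rows)
    return df[["cell_id"] + [c for c in df.columns if c != "cell_id"]]


def prior_network_features_table(
    net_edges: Sequence,
    X: ExpressionMatrix,
    max_dim: int = 1,
    include_betti: bool = False,
    shared_grid: bool = True,
    n_grid: int = 100,
) -> pd.DataFrame:
    """Per-cell node-weighted prior-network topology features.

    With ``shared_grid``, Betti curves use one grid spanning the dataset-wide
    maximum node weight so curves are averageable across cells.
    """
    grid = None
    if include_betti and shared_grid:
        nets = [attach_node_weights(net_edges, X, c) for c in range(X.n_cells)]
        dmax = max((nt.delta_max for nt in nets), default=1.0)
        grid = np.linspace(0.0, dmax if dmax > 0 else 1.0, n_grid)
    else:
        nets = [attach_node_weights(net_edges, X, c) for c in range(X.n_cells)]
    rows = []
    for cell, net in enumerate(nets):
        rec = gene_network_features(
            net, max_dim=max_dim, grid=grid, include_betti=include_betti, n_grid=n_grid
        )
        rec["cell_id"] = X.cell_ids[cell]
        rows.append(rec)
    df = pd.DataFrame(rows)
    return df[["cell_id"] + [c for c in df.columns if c != "cell_id"]]
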