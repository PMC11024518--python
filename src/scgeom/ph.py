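"""Simplicial filtrations and persistent homology.

This module is the topological core of the package: it builds filtered
simplicial complexes from point clouds (Vietoris--Rips), from edge-weighted
gene networks (descending-threshold Rips re-expressed as an ascending
filtration), and from node-weighted gene networks (vertex-based clique
filtration), and computes their persistence diagrams by boundary-matrix
reduction over the field with two elements.

Two independent reduction code paths are provided: :func:`persistence`
(optimized, bitmask columns with a pivot table) and
:func:`persistence_oracle` (deliberately naive left-to-right column
reduction). They share only the :class:`Filtration` input contract, so one
can serve as a correctness oracle for the other.

Relative persistent homology -- the homology of the chain groups of the
whole complex modulo the full subcomplex spanned by a vertex set ``L`` --
is computed by coning ``L`` to a virtual apex (:func:`relative_persistence`)
and, as an independent oracle, by direct reduction of the quotient chain
complex (:func:`relative_persistence_oracle`).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "Filtration",
    "PersistenceDiagram",
    "FiltrationError",
    "vr_filtration",
    "edge_weighted_vr_filtration",
    "vertex_clique_filtration",
    "persistence",
    "persistence_oracle",
    "relative_persistence",
    "relative_persistence_oracle",
    "cap_diagram",
    "diagram_wasserstein",
]


class FiltrationError(ValueError):
    """Raised when a filtration violates monotonicity or an input contract."""


Simplex = tuple  # sorted tuple of vertex indices; dim = len - 1


@dataclass
class PersistenceDiagram:
    """Multiset of (dim, birth, death) with death possibly ``math.inf``.

    Zero-persistence pairs (birth == death) are never stored.
    """

    pairs: list = field(default_factory=list)

    def of_dim(self, dim: int) -> list:
        return [(b, d) for (k, b, d) in self.pairs if k == dim]

    def dims(self) -> set:
        return {k for (k, _, _) in self.pairs}

    def as_multiset(self):
        return sorted(
            (k, round(b, 12), round(d, 12) if math.isfinite(d) else math.inf)
            for (k, b, d) in self.pairs
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, PersistenceDiagram):
            return NotImplemented
        return self.as_multiset() == other.as_multiset()

    def __len__(self) -> int:
        return len(self.pairs)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.pairs, columns=["dim", "birth", "death"])

    def write_csv(self, path) -> None:
        df = self.to_frame()
        df["death"] = df["death"].map(lambda d: "inf" if math.isinf(d) else repr(d))
        df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "PersistenceDiagram":
        import pandas as pd

        df = pd.read_csv(path)
        pairs = [
            (int(k), float(b), math.inf if str(d) == "inf" else float(d))
            for k, b, d in df.itertuples(index=False)
        ]
        return cls(pairs)


@dataclass
class Filtration:
    """Ordered sequence of (simplex, filtration value).

    Simplices are sorted tuples of integer vertex indices. The sequence is
    kept sorted by (value, dim, vertex tuple) so that faces precede their
    cofaces whenever the filtration is monotone.
    """

    simplices: list  # list[(Simplex, float)]
    max_dim: int = 1

    def __post_init__(self):
        self.simplices = sorted(
            ((tuple(s), float(v)) for s, v in self.simplices),
            key=lambda sv: (sv[1], len(sv[0]), sv[0]),
        )
        for s, _ in self.simplices:
            if any(s[i] >= s[i + 1] for i in range(len(s) - 1)):
                raise FiltrationError(f"simplex vertices not strictly increasing: {s}")

    def __len__(self) -> int:
        return len(self.simplices)

    def validate_monotone(self) -> None:
        """Every facet must be present with a value <= the simplex's value."""
        value = {s: v for s, v in self.simplices}
        for s, v in self.simplices:
            if len(s) == 1:
                continue
            for i in range(len(s)):
                face = s[:i] + s[i + 1 :]
                fv = value.get(face)
                if fv is None:
                    raise FiltrationError(f"face {face} of {s} missing from filtration")
                if fv > v + 1e-12:
                    raise FiltrationError(
                        f"face {face} enters at {fv} after its coface {s} at {v}"
                    )

    @property
    def max_value(self) -> float:
        return max((v for _, v in self.simplices), default=0.0)


# ---------------------------------------------------------------------------
# Filtration constructions
# ---------------------------------------------------------------------------


def vr_filtration(D, max_dim: int = 1, max_scale: float = math.inf) -> Filtration:
    """Vietoris--Rips filtration of a finite metric space.

    A simplex enters at the largest pairwise distance among its vertices;
    simplices entering above ``max_scale`` are omitted. The complex is built
    up to dimension ``max_dim + 1`` so that homology in dimension
    ``max_dim`` is correct.

    Parameters
    ----------
    D : (n, n) array-like
        Symmetric non-negative distance matrix with zero diagonal.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be a square matrix")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if np.any(D < -1e-12):
        raise ValueError("distance matrix must be non-negative")
    n = D.shape[0]
    simplices = [((i,), 0.0) for i in range(n)]
    # edges
    edge_val = {}
    for i in range(n):
        for j in range(i + 1, n):
            v = D[i, j]
            if v <= max_scale:
                simplices.append(((i, j), v))
                edge_val[(i, j)] = v
    # higher simplices: extend cliques dimension by dimension
    prev = list(edge_val.items())  # [(simplex, value)]
    for _ in range(max_dim):  # adds dims 2 .. max_dim+1
        nxt = []
        for s, v in prev:
            # extend with a vertex larger than all current ones
            for u in range(s[-1] + 1, n):
                ok = True
                val = v
                for w in s:
                    ev = edge_val.get((w, u))
                    if ev is None:
                        ok = False
                        break
                    if ev > val:
                        val = ev
                if ok:
                    nxt.append((s + (u,), val))
        simplices.extend(nxt)
        prev = nxt
    return Filtration(simplices, max_dim=max_dim)


def _cliques_up_to(n_vertices: int, edges: Iterable[Simplex], max_size: int):
    """All cliques of the graph with at most ``max_size`` vertices."""
    adj = {i: set() for i in range(n_vertices)}
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    cliques = [(i,) for i in range(n_vertices)]
    frontier = cliques
    size = 1
    while size < max_size:
        nxt = []
        for c in frontier:
            common = adj[c[0]].intersection(*(adj[w] for w in c[1:])) if len(c) > 1 else adj[c[0]]
            for u in common:
                if u > c[-1]:
                    nxt.append(c + (u,))
        cliques.extend(nxt)
        frontier = nxt
        size += 1
    return cliques


def edge_weighted_vr_filtration(net, max_dim: int = 1) -> Filtration:
    """Descending edge-weight Rips filtration of an edge-weighted network.

    The network is thresholded from delta = delta_max (the largest edge
    weight) down to 0, keeping a simplex once all of its edges have weight
    >= delta; the result is re-expressed as an ascending filtration in the
    transformed value delta_max - delta, i.e. a simplex enters at
    ``delta_max - min(edge weights in the simplex)``. Only cliques of the
    network become simplices. Each vertex enters together with its first
    (largest-weight) incident edge; isolated vertices enter at delta_max.

    ``net`` must expose ``gene_ids`` (or ``n_nodes``), ``edges`` and
    ``edge_weight``.
    """
    edge_weight = dict(net.edge_weight)
    if any(w < 0 for w in edge_weight.values()):
        raise ValueError("edge weights must be non-negative")
    n = len(net.gene_ids) if hasattr(net, "gene_ids") else net.n_nodes
    delta_max = max(edge_weight.values(), default=0.0)
    simplices = []
    # vertex entry: transformed value of its largest-weight incident edge
    best = [None] * n
    for (i, j), w in edge_weight.items():
        for v in (i, j):
            if best[v] is None or w > best[v]:
                best[v] = w
    for v in range(n):
        simplices.append(((v,), delta_max if best[v] is None else delta_max - best[v]))
    cliques = _cliques_up_to(n, edge_weight.keys(), max_dim + 2)
    for c in cliques:
        if len(c) < 2:
            continue
        wmin = min(
            edge_weight[(a, b)] for a, b in itertools.combinations(c, 2)
        )
        simplices.append((c, delta_max - wmin))
    return Filtration(simplices, max_dim=max_dim)


def vertex_clique_filtration(net, max_dim: int = 1) -> Filtration:
    """Vertex-based clique-complex filtration of a node-weighted network.

    Thresholding node weights from delta_max (largest node weight) down to
    0 keeps a vertex once its weight is >= delta and an edge once both of
    its endpoints are kept; re-expressed ascending, vertex ``i`` enters at
    ``delta_max - W(v_i)``, an edge at ``delta_max - min`` of its endpoint
    weights, and a higher clique at the max of its faces' values (i.e.
    ``delta_max - min`` vertex weight in the clique).
    """
    node_weight = dict(net.node_weight)
    if any(w < 0 for w in node_weight.values()):
        raise ValueError("node weights must be non-negative")
    n = len(net.gene_ids) if hasattr(net, "gene_ids") else net.n_nodes
    for v in range(n):
        if v not in node_weight:
            raise ValueError(f"node {v} missing from the weight table")
    delta_max = max(node_weight.values(), default=0.0)
    cliques = _cliques_up_to(n, net.edges, max_dim + 2)
    simplices = [
        (c, delta_max - min(node_weight[v] for v in c)) for c in cliques
    ]
    return Filtration(simplices, max_dim=max_dim)


# ---------------------------------------------------------------------------
# Persistence by boundary-matrix reduction over Z/2
# ---------------------------------------------------------------------------


def _boundary_bitmasks(filt: Filtration):
    index = {s: i for i, (s, _) in enumerate(filt.simplices)}
    cols = []
    for s, _ in filt.simplices:
        col = 0
        if len(s) > 1:
            for i in range(len(s)):
                face = s[:i] + s[i + 1 :]
                col |= 1 << index[face]
        cols.append(col)
    return cols


def _pairs_to_diagram(filt: Filtration, pairs, unpaired) -> PersistenceDiagram:
    out = []
    for i, j in pairs:
        (si, bi), (sj, dj) = filt.simplices[i], filt.simplices[j]
        if dj > bi:
            out.append((len(si) - 1, bi, dj))
    for i in unpaired:
        s, b = filt.simplices[i]
        if len(s) - 1 <= filt.max_dim:
            out.append((len(s) - 1, b, math.inf))
    return PersistenceDiagram(out)


def persistence(filt: Filtration, validate: bool = True) -> PersistenceDiagram:
    """Persistence diagram of a monotone filtration (Z/2 coefficients).

    Standard left-to-right column reduction with columns stored as integer
    bitmasks and a pivot-to-column table. Pairs of zero persistence are
    dropped; one infinite H0 bar remains per connected component of the
    final complex (and likewise for higher-dimensional essential classes
    up to ``max_dim``).
    """
    if validate:
        filt.validate_monotone()
    cols = _boundary_bitmasks(filt)
    n = len(cols)
    pivot_of = {}
    pairs = []
    zero_cols = []
    for j in range(n):
        col = cols[j]
        while col:
            p = col.bit_length() - 1
            j2 = pivot_of.get(p)
            if j2 is None:
                break
            col ^= cols[j2]
        cols[j] = col
        if col:
            p = col.bit_length() - 1
            pivot_of[p] = j
            pairs.append((p, j))
        else:
            zero_cols.append(j)
    unpaired = [j for j in zero_cols if j not in pivot_of]
    return _pairs_to_diagram(filt, pairs, unpaired)


def persistence_oracle(filt: Filtration, validate: bool = True) -> PersistenceDiagram:
    """Unoptimized reduction oracle: independent code path from
    :func:`persistence`, intended for small filtrations (a few hundred
    simplices). Columns are Python sets; the column with a matching pivot
    is found by linear scan."""
    if validate:
        filt.validate_monotone()
    index = {s: i for i, (s, _) in enumerate(filt.simplices)}
    cols = []
    for s, _ in filt.simplices:
        faces = set()
        if len(s) > 1:
            for i in range(len(s)):
                faces.add(index[s[:i] + s[i + 1 :]])
        cols.append(faces)
    n = len(cols)
    pairs = []
    for j in range(n):
        while cols[j]:
            low = max(cols[j])
            # naive scan for an earlier reduced column with the same pivot
            found = None
            for j2 in range(j):
                if cols[j2] and max(cols[j2]) == low:
                    found = j2
                    break
            if found is None:
                break
            cols[j] = cols[j].symmetric_difference(cols[found])
        if cols[j]:
            pairs.append((max(cols[j]), j))
    paired = {i for i, _ in pairs} | {j for _, j in pairs}
    unpaired = [j for j in range(n) if j not in paired and not cols[j]]
    return _pairs_to_diagram(filt, pairs, unpaired)


# ---------------------------------------------------------------------------
# Relative persistent homology
# ---------------------------------------------------------------------------


def relative_persistence(
    filt: Filtration, l_vertices: Iterable[int], validate: bool = True
) -> PersistenceDiagram:
    """Persistence of the filtration relative to the full subcomplex on
    ``l_vertices``.

    Realized by coning: every simplex fully contained in ``l_vertices`` is
    coned to a virtual apex entering at the minimum filtration value, which
    is homotopy-equivalent to collapsing the subcomplex; the apex
    component's essential H0 bar is removed (reduced homology). With
    ``l_vertices`` empty this reduces to absolute persistence.
    """
    L = set(l_vertices)
    if not L:
        return persistence(filt, validate=validate)
    if validate:
        filt.validate_monotone()
    apex = max(v for s, _ in filt.simplices for v in s) + 1
    v0 = min(v for _, v in filt.simplices)
    simplices = list(filt.simplices) + [((apex,), v0)]
    for s, v in filt.simplices:
        if set(s) <= L and len(s) <= filt.max_dim + 1:
            simplices.append((s + (apex,), v))
    coned = Filtration(simplices, max_dim=filt.max_dim)
    diag = persistence(coned, validate=False)
    # drop one essential H0 bar born at the apex value (reduced homology)
    pairs = list(diag.pairs)
    for idx, (k, b, d) in enumerate(pairs):
        if k == 0 and math.isinf(d) and b <= v0 + 1e-12:
            del pairs[idx]
            break
    return PersistenceDiagram(pairs)


def relative_persistence_oracle(
    filt: Filtration, l_vertices: Iterable[int], validate: bool = True
) -> PersistenceDiagram:
    """Direct reduction of the quotient chain complex C(K)/C(K ∩ L).

    The basis consists of the simplices not fully contained in the vertex
    set ``l_vertices``; boundary faces lying in the subcomplex are set to
    zero. Independent of the cone construction used by
    :func:`relative_persistence`.
    """
    L = set(l_vertices)
    if validate:
        filt.validate_monotone()
    kept = [(s, v) for s, v in filt.simplices if not set(s) <= L]
    sub = Filtration.__new__(Filtration)
    sub.simplices = kept
    sub.max_dim = filt.max_dim
    index = {s: i for i, (s, _) in enumerate(kept)}
    cols = []
    for s, _ in kept:
        col = 0
        if len(s) > 1:
            for i in range(len(s)):
                face = s[:i] + s[i + 1 :]
                fi = index.get(face)
                if fi is not None:  # faces inside L vanish in the quotient
                    col |= 1 << fi
        cols.append(col)
    pivot_of = {}
    pairs = []
    zero_cols = []
    for j in range(len(cols)):
        col = cols[j]
        while col:
            p = col.bit_length() - 1
            j2 = pivot_of.get(p)
            if j2 is None:
                break
            col ^= cols[j2]
        cols[j] = col
        if col:
            pivot_of[col.bit_length() - 1] = j
            pairs.append((col.bit_length() - 1, j))
        else:
            zero_cols.append(j)
    unpaired = [j for j in zero_cols if j not in pivot_of]
    return _pairs_to_diagram(sub, pairs, unpaired)


# ---------------------------------------------------------------------------
# Diagram distances and capping
# ---------------------------------------------------------------------------


def cap_diagram(diag: PersistenceDiagram, delta_max: float) -> PersistenceDiagram:
    """Replace deaths by min(death, delta_max), dropping pairs that become
    zero-persistence."""
    pairs = []
    for k, b, d in diag.pairs:
        d2 = min(d, delta_max)
        if d2 > b:
            pairs.append((k, b, d2))
    return PersistenceDiagram(pairs)


def diagram_wasserstein(
    d1: PersistenceDiagram, d2: PersistenceDiagram, dim: int, q: float = 1.0
) -> float:
    """Order-q Wasserstein distance between the dim-``dim`` parts of two
    diagrams, with the L-infinity ground metric on the plane and diagonal
    projections as the matching slack.

    Infinite deaths must be capped beforehand (see :func:`cap_diagram`).
    """
    p1 = d1.of_dim(dim)
    p2 = d2.of_dim(dim)
    if any(math.isinf(d) for _, d in p1 + p2):
        raise ValueError(
            "diagram contains infinite deaths; cap them (cap_diagram) before "
            "computing the Wasserstein distance"
        )
    n1, n2 = len(p1), len(p2)
    if n1 == 0 and n2 == 0:
        return 0.0
    size = n1 + n2
    BIG = None
    C = np.zeros((size, size))
    diag1 = [(d - b) / 2.0 for b, d in p1]
    diag2 = [(d - b) / 2.0 for b, d in p2]
    for i, (b1, dd1) in enumerate(p1):
        for j, (b2, dd2) in enumerate(p2):
            C[i, j] = max(abs(b1 - b2), abs(dd1 - dd2)) ** q
    BIG = (C[:n1, :n2].sum() + sum(x**q for x in diag1 + diag2) + 1.0) * 2
    C[:n1, n2:] = BIG
    for i in range(n1):
        C[i, n2 + i] = diag1[i] ** q
    C[n1:, :n2] = BIG
    for j in range(n2):
        C[n1 + j, j] = diag2[j] ** q
    C[n1:, n2:] = 0.0
    rows, cols = linear_sum_assignment(C)
    total = C[rows, cols].sum()
    return float(total ** (1.0 / q))
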