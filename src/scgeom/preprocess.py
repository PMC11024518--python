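"""Expression-matrix ingestion, normalization, HVG selection, PCA and the
kNN cell graph.

Reads Matrix Market triplets (with barcode/gene sidecar TSVs) or dense CSV
(cells as rows, header = gene ids, first column = cell ids), applies
total-count normalization with log1p, ranks highly variable genes by
variance of the log-normalized values, embeds with mean-centered PCA (with
a deterministic sign convention), and builds a union-symmetrized k-nearest-
neighbor graph over the cells.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial.distance import cdist

__all__ = [
    "ExpressionMatrix",
    "Embedding",
    "CellGraph",
    "read_counts",
    "normalize_log1p",
    "select_hvg",
    "pca_embed",
    "knn_graph",
]


@dataclass
class ExpressionMatrix:
    """Cells x genes matrix with identifiers and a layer tag (raw | lognorm)."""

    values: np.ndarray
    cell_ids: list
    gene_ids: list
    layer_tag: str = "raw"

    def __post_init__(self):
        if sp.issparse(self.values):
            self.values = np.asarray(self.values.todense(), dtype=float)
        else:
            self.values = np.asarray(self.values, dtype=float)
        n, g = self.values.shape
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(c) for c in self.gene_ids]
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} matrix rows")
        if len(self.gene_ids) != g:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {g} matrix columns")
        if len(set(self.cell_ids)) != n or len(set(self.gene_ids)) != g:
            raise ValueError("duplicate cell or gene identifiers")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene_ids: Sequence[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([pos[g] for g in gene_ids], dtype=int)


@dataclass
class Embedding:
    coords: np.ndarray
    cell_ids: list

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or len(self.cell_ids) != self.coords.shape[0]:
            raise ValueError("coords must be 2D with one row per cell id")

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    @property
    def n_comps(self) -> int:
        return self.coords.shape[1]

    def write_csv(self, path) -> None:
        cols = [f"pc{i + 1}" for i in range(self.n_comps)]
        df = pd.DataFrame(self.coords, columns=cols)
        df.insert(0, "cell_id", self.cell_ids)
        df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "Embedding":
        df = pd.read_csv(path)
        return cls(df.iloc[:, 1:].to_numpy(float), df.iloc[:, 0].astype(str).tolist())


@dataclass
class CellGraph:
    """Undirected graph over cells; edges are (i, j) with i < j."""

    n_nodes: int
    edges: set
    edge_length: dict = field(default_factory=dict)
    k: Optional[int] = None

    def __post_init__(self):
        for i, j in self.edges:
            if i == j:
                raise ValueError("self-loops are not allowed")
            if not (0 <= i < j < self.n_nodes):
                raise ValueError(f"invalid edge ({i}, {j}) for {self.n_nodes} nodes")

    def neighbors(self) -> list:
        adj = [set() for _ in range(self.n_nodes)]
        for i, j in self.edges:
            adj[i].add(j)
            adj[j].add(i)
        return adj

    def degree(self, v: int) -> int:
        return sum(1 for e in self.edges if v in e)

    def write_tsv(self, path, cell_ids: Optional[Sequence[str]] = None) -> None:
        rows = sorted(self.edges)
        df = pd.DataFrame(rows, columns=["i", "j"])
        df["length"] = [self.edge_length.get(e, 1.0) for e in rows]
        df.to_csv(path, sep="\t", index=False)
        if cell_ids is not None:
            side = os.path.splitext(str(path))[0] + ".nodes.tsv"
            pd.DataFrame({"node": range(self.n_nodes), "cell_id": list(cell_ids)}).to_csv(
                side, sep="\t", index=False
            )

    @classmethod
    def read_tsv(cls, path) -> "CellGraph":
        df = pd.read_csv(path, sep="\t")
        edges = set()
        lengths = {}
        for i, j, ln in df.itertuples(index=False):
            e = (min(int(i), int(j)), max(int(i), int(j)))
            edges.add(e)
            lengths[e] = float(ln)
        n = int(df[["i", "j"]].to_numpy().max()) + 1 if len(df) else 0
        return cls(n_nodes=n, edges=edges, edge_length=lengths)


def read_counts(path, format: str = "mtx") -> ExpressionMatrix:
    """Read a raw count matrix from disk, orientation-normalized to
    cells-as-rows.

    ``mtx``: Matrix Market triplets (genes x cells, the common convention;
    transposed on read) with sibling ``barcodes.tsv`` and ``genes.tsv``
    one-id-per-line files. ``csv``: cells x genes with a header row of gene
    ids and the first column holding cell ids.
    """
    path = str(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"counts file not found: {path}")
    if format == "csv":
        df = pd.read_csv(path, index_col=0)
        return ExpressionMatrix(
            df.to_numpy(float), df.index.astype(str).tolist(), df.columns.astype(str).tolist()
        )
    if format == "mtx":
        import scipy.io as sio

        d = os.path.dirname(path)
        barcodes_path = os.path.join(d, "barcodes.tsv")
        genes_path = os.path.join(d, "genes.tsv")
        for p in (barcodes_path, genes_path):
            if not os.path.exists(p):
                raise FileNotFoundError(f"sidecar id file not found: {p}")
        mat = sio.mmread(path)  # genes x cells triplets
        values = np.asarray(sp.csr_matrix(mat).todense()).T
        barcodes = pd.read_csv(barcodes_path, header=None, sep="\t")[0].astype(str).tolist()
        genes = pd.read_csv(genes_path, header=None, sep="\t")[0].astype(str).tolist()
        if values.shape[0] != len(barcodes) or values.shape[1] != len(genes):
            raise ValueError(
                f"matrix is {values.shape[1]} genes x {values.shape[0]} cells but id files "
                f"list {len(genes)} genes and {len(barcodes)} barcodes"
            )
        return ExpressionMatrix(values, barcodes, genes)
    raise ValueError(f"unknown format: {format!r} (expected 'mtx' or 'csv')")


def normalize_log1p(X: ExpressionMatrix, target_sum: float = 1e4) -> ExpressionMatrix:
    """Scale each cell's counts to ``target_sum`` total, then log(1 + x).

    Cells with zero total count are left all-zero with a warning.
    """
    if X.layer_tag != "raw":
        raise ValueError("normalize_log1p expects a raw-layer matrix")
    totals = X.values.sum(axis=1)
    zero = totals == 0
    if np.any(zero):
        warnings.warn(f"{int(zero.sum())} cell(s) with zero total count left as zeros")
    scale = np.where(zero, 1.0, target_sum / np.where(zero, 1.0, totals))
    vals = np.log1p(X.values * scale[:, None])
    return ExpressionMatrix(vals, X.cell_ids, X.gene_ids, layer_tag="lognorm")


def select_hvg(X: ExpressionMatrix, n_top: int) -> list:
    """Top ``n_top`` gene ids by variance of the log-normalized values
    (descending; ties broken by gene order). Deterministic."""
    if X.layer_tag != "lognorm":
        raise ValueError("select_hvg expects a lognorm-layer matrix")
    if n_top > X.n_genes:
        raise ValueError(f"n_top={n_top} exceeds gene count {X.n_genes}")
    var = X.values.var(axis=0)
    order = np.argsort(-var, kind="stable")[:n_top]
    return [X.gene_ids[i] for i in order]


def pca_embed(
    X: ExpressionMatrix, n_comps: int = 30, gene_subset: Optional[Sequence[str]] = None
) -> Embedding:
    """Mean-centered PCA scores of the (optionally gene-subset) lognorm
    matrix. Each component's sign is fixed so that its largest-absolute
    loading is positive, making outputs stable across runs."""
    if X.layer_tag != "lognorm":
        raise ValueError("pca_embed expects a lognorm-layer matrix")
    vals = X.values
    if gene_subset is not None:
        vals = vals[:, X.gene_index(gene_subset)]
    if n_comps > min(vals.shape):
        raise ValueError(
            f"n_comps={n_comps} exceeds min(cells, genes) = {min(vals.shape)}"
        )
    centered = vals - vals.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(centered, full_matrices=False)
    for c in range(n_comps):
        lead = np.argmax(np.abs(Vt[c]))
        if Vt[c, lead] < 0:
            U[:, c] = -U[:, c]
            Vt[c] = -Vt[c]
    scores = U[:, :n_comps] * S[:n_comps]
    return Embedding(scores, X.cell_ids)


def _pairwise(coords: np.ndarray, metric: str) -> np.ndarray:
    if metric not in ("euclidean", "cosine", "correlation"):
        raise ValueError(f"unknown metric: {metric!r}")
    D = cdist(coords, coords, metric=metric)
    np.fill_diagonal(D, 0.0)
    return D


def knn_graph(E: Embedding, k: int = 15, metric: str = "euclidean") -> CellGraph:
    """Union-symmetrized k-nearest-neighbor graph of the embedding.

    Node i is connected to its k nearest neighbors (self excluded); an edge
    is kept if either endpoint selects the other, so every node has degree
    >= k. Exact distance ties are broken by lower node index. Edge lengths
    store the metric distance.
    """
    n = E.n_cells
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    D = _pairwise(E.coords, metric)
    edges = set()
    lengths = {}
    for i in range(n):
        order = np.lexsort((np.arange(n), D[i]))  # ascending (distance, index)
        picked = 0
        for j in order:
            if j == i:
                continue
            e = (min(i, j), max(i, j))
            edges.add(e)
            lengths[e] = float(D[i, j])
            picked += 1
            if picked == k:
                break
    return CellGraph(n_nodes=n, edges=edges, edge_length=lengths, k=k)
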