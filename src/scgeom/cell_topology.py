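"""Per-cell local and relative persistent homology on the cell point cloud.

Local persistent homology runs a Vietoris--Rips filtration on the Euclidean
neighborhood of each cell in the PCA embedding, summarizing the multiscale
structure around the cell; cells sitting in sparse corridors between dense
states produce longer H0 bars than cells inside a dense state. Relative
persistent homology measures how much the global diagram changes when the
chain groups of a small neighborhood of the cell are quotiented out, i.e.
the cell's importance in assembling the global structure, quantified by the
Wasserstein distance to the regular diagram of the full dataset.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from . import features as feat
from .ph import (
    PersistenceDiagram,
    cap_diagram,
    diagram_wasserstein,
    persistence,
    relative_persistence,
    vr_filtration,
)
from .preprocess import Embedding

__all__ = [
    "local_ph",
    "relative_ph",
    "relative_importance",
    "cell_features_table",
]


def _neighborhood(E: Embedding, cell: int, k_local=None, radius=None, include_center=True):
    d = np.linalg.norm(E.coords - E.coords[cell], axis=1)
    order = np.lexsort((np.arange(E.n_cells), d))
    order = order[order != cell]
    if radius is not None:
        sel = [j for j in order if d[j] <= radius]
    else:
        sel = list(order[:k_local])
    if include_center:
        sel = [cell] + sel
    return np.array(sel, dtype=int)


def local_ph(
    E: Embedding,
    cell: int,
    k_local: Optional[int] = 30,
    radius: Optional[float] = None,
    max_dim: int = 1,
    include_center: bool = True,
):
    """VR persistence of the point cloud formed by a cell and its selected
    neighbors (top ``k_local`` nearest, or all within ``radius``), at the
    Euclidean distance of the embedding. ``max_scale`` is the neighborhood
    diameter. Returns (diagram, diameter)."""
    idx = _neighborhood(E, cell, k_local=k_local, radius=radius, include_center=include_center)
    if len(idx) < 2:
        warnings.warn(f"neighborhood of cell {cell} has fewer than 2 points; empty diagram")
        return PersistenceDiagram([]), 0.0
    pts = E.coords[idx]
    D = squareform(pdist(pts))
    diameter = float(D.max())
    filt = vr_filtration(D, max_dim=max_dim, max_scale=diameter)
    return persistence(filt, validate=False), diameter


def _global_filtration(E: Embedding, max_dim: int, max_scale: Optional[float]):
    D = squareform(pdist(E.coords))
    if max_scale is None:
        max_scale = float(np.percentile(pdist(E.coords), 90))
    return vr_filtration(D, max_dim=max_dim, max_scale=max_scale), max_scale


def relative_ph(
    E: Embedding,
    cell: int,
    l_size: int = 10,
    max_dim: int = 1,
    max_scale: Optional[float] = None,
    _filtration=None,
):
    """Persistence of the global VR filtration relative to the full
    subcomplex on the cell and its (l_size - 1) nearest neighbors.

    ``max_scale`` defaults to the 90th percentile of pairwise distances (to
    bound complex size). ``l_size = 0`` reduces to absolute persistence.
    Returns (diagram, max_scale).
    """
    if l_size >= E.n_cells:
        raise ValueError("l_size must be smaller than the number of cells")
    if _filtration is None:
        filt, max_scale = _global_filtration(E, max_dim, max_scale)
    else:
        filt = _filtration
    L = set(_neighborhood(E, cell, k_local=l_size - 1)) if l_size >= 1 else set()
    return relative_persistence(filt, L, validate=False), max_scale


def relative_importance(
    E: Embedding,
    cell: int,
    l_size: int = 10,
    max_dim: int = 1,
    q: float = 1.0,
    max_scale: Optional[float] = None,
    _filtration=None,
    _regular=None,
) -> float:
    """Sum over dimensions <= max_dim of the Wasserstein distance between
    the relative diagram of the cell's neighborhood and the regular diagram
    of the whole dataset (deaths capped at max_scale)."""
    if _filtration is None:
        _filtration, max_scale = _global_filtration(E, max_dim, max_scale)
    rel, _ = relative_ph(E, cell, l_size=l_size, max_dim=max_dim, _filtration=_filtration)
    reg = _regular if _regular is not None else persistence(_filtration, validate=False)
    cap = _filtration.max_value if max_scale is None else max_scale
    rel_c = cap_diagram(rel, cap)
    reg_c = cap_diagram(reg, cap)
    return float(
        sum(diagram_wasserstein(rel_c, reg_c, dim=k, q=q) for k in range(max_dim + 1))
    )


def cell_features_table(
    E: Embedding,
    k_local: int = 30,
    max_dim: int = 1,
    include_relative: bool = False,
    l_size: int = 10,
    q: float = 1.0,
    max_scale: Optional[float] = None,
) -> pd.DataFrame:
    """Per-cell topological feature table: local H0/H1 total persistence and
    persistence entropy (deaths capped at the neighborhood diameter), and
    optionally the relative-persistence importance score."""
    rows = []
    filt = regular = None
    if include_relative:
        filt, max_scale = _global_filtration(E, max_dim, max_scale)
        regular = persistence(filt, validate=False)
    for cell in range(E.n_cells):
        diag, diameter = local_ph(E, cell, k_local=k_local, max_dim=max_dim)
        cap = diameter if diameter > 0 else 1.0
        row = {"cell_id": E.cell_ids[cell]}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for k in range(max_dim + 1):
                row[f"h{k}_total_persistence"] = feat.total_persistence(diag, k, cap)
                row[f"h{k}_entropy"] = feat.persistence_entropy(diag, k, cap)
        if include_relative:
            row["relative_importance"] = relative_importance(
                E, cell, l_size=l_size, max_dim=max_dim, q=q,
                max_scale=max_scale, _filtration=filt, _regular=regular,
            )
        rows.append(row)
    return pd.DataFrame(rows)
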