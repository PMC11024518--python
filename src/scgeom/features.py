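"""Scalar and curve featurizations of persistence diagrams.

Three standard summaries: total persistence (sum of capped bar lengths),
persistence entropy (Shannon entropy, base 2, of the normalized capped bar
lengths) and Betti curves (bar counts over a grid of filtration values,
half-open interval convention).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .ph import PersistenceDiagram

__all__ = ["BettiCurve", "total_persistence", "persistence_entropy", "betti_curve"]


@dataclass
class BettiCurve:
    grid: np.ndarray
    counts: np.ndarray
    dim: int


def _capped_lengths(diag: PersistenceDiagram, dim: int, delta_max: float):
    lengths = []
    for k, b, d in diag.pairs:
        if k != dim:
            continue
        if b > delta_max:
            raise ValueError(
                f"bar born at {b} above delta_max={delta_max}; capping is ill-defined"
            )
        lengths.append(min(d, delta_max) - b)
    return [x for x in lengths if x > 0]


def total_persistence(diag: PersistenceDiagram, dim: int, delta_max: float = math.inf) -> float:
    """Sum of (min(death, delta_max) - birth) over the bars of a dimension."""
    return float(sum(_capped_lengths(diag, dim, delta_max)))


def persistence_entropy(diag: PersistenceDiagram, dim: int, delta_max: float = math.inf) -> float:
    """Base-2 Shannon entropy of the normalized capped bar lengths.

    A single bar gives 0; an empty diagram gives 0 with a warning (keeps
    feature tables total over degenerate cells).
    """
    lengths = _capped_lengths(diag, dim, delta_max)
    if not lengths:
        warnings.warn(f"empty H{dim} diagram: persistence entropy defined as 0")
        return 0.0
    ell = np.asarray(lengths, dtype=float)
    p = ell / ell.sum()
    return float(-(p * np.log2(p)).sum())


def betti_curve(diag: PersistenceDiagram, dim: int, grid) -> BettiCurve:
    """Betti curve on a grid: counts[j] = #{[b, d) : grid[j] in [b, d)}."""
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) < 0):
        raise ValueError("grid must be sorted ascending")
    counts = np.zeros(len(grid), dtype=int)
    for k, b, d in diag.pairs:
        if k != dim:
            continue
        counts += (grid >= b) & (grid < d)
    return BettiCurve(grid=grid, counts=counts, dim=dim)
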