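"""Run configuration: one validated object holding every stage's parameters.

Serializes to and round-trips from a single YAML file; unknown keys are
rejected so typos fail loudly rather than silently falling back to defaults.
"""

from __future__ import annotations

import hashlib
import json
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["RunConfig"]


class RunConfig(BaseModel):
    """All pipeline parameters with their defaults, plus I/O paths."""

    model_config = ConfigDict(extra="forbid")

    # io
    counts: Optional[str] = None
    counts_format: str = "csv"
    network: Optional[str] = None
    clusters: Optional[str] = None
    out_dir: str = "scgeom_out"

    # preprocessing
    target_sum: float = 1e4
    n_hvg: int = 1000
    n_comps: int = 30
    knn: int = 15
    metric: str = "euclidean"

    # curvature
    alpha: float = Field(0.5, ge=0.0, le=1.0)
    ground: str = "hop"

    # cell topology
    k_local: int = 30
    l_size: int = 10
    max_dim: int = 1
    q_wasserstein: float = 1.0

    # gene topology
    gene_mode: str = "csn"  # csn | prior
    box_fraction: float = 0.1
    sig_level: float = 0.01
    n_perm: int = 1000

    # transitions
    transition_score: str = "h0_total_persistence"
    transition_q: float = 0.1

    # randomness
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
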