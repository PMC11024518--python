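"""End-to-end orchestration: run the requested stages in dependency order,
write per-stage artifacts and a manifest (config echo + hash, versions,
timings, warnings)."""

from __future__ import annotations

import json
import logging
import os
import time

import numpy as np
import pandas as pd

from . import __version__
from .cell_topology import cell_features_table
from .config import RunConfig
from .curvature import orc_all
from .downstream import associate_transition_groups, call_transitions
from .gene_topology import csn_features_table, prior_network_features_table, read_network_tsv
from .preprocess import knn_graph, normalize_log1p, pca_embed, read_counts, select_hvg

__all__ = ["run_pipeline", "STAGES"]

STAGES = ("preprocess", "curvature", "cell-topology", "gene-topology", "transitions")

logger = logging.getLogger("scgeom")


def _require(path: str, stage: str, needed_by: str):
    if not os.path.exists(path):
        raise FileNotFoundError(
            f"stage '{needed_by}' needs the output of stage '{stage}' ({path}); "
            f"run that stage first"
        )


def run_pipeline(config: RunConfig, stages=STAGES) -> str:
    """Execute the requested stages; returns the artifact directory.

    Stages: preprocess (embedding.csv, graph.tsv), curvature
    (curvature_nodes.csv, curvature_edges.csv), cell-topology
    (cell_features.csv), gene-topology (gene_features.csv), transitions
    (calls.csv, transition_groups.json). All randomness flows from
    ``config.seed``.
    """
    stages = list(stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    handler = logging.FileHandler(os.path.join(out, "run.log"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    timings = {}
    try:
        emb_path = os.path.join(out, "embedding.csv")
        graph_path = os.path.join(out, "graph.tsv")
        feat_path = os.path.join(out, "cell_features.csv")

        if "preprocess" in stages:
            t0 = time.time()
            X = read_counts(config.counts, format=config.counts_format)
            Xn = normalize_log1p(X, target_sum=config.target_sum)
            hvg = select_hvg(Xn, min(config.n_hvg, Xn.n_genes))
            n_comps = min(config.n_comps, Xn.n_cells, len(hvg))
            E = pca_embed(Xn, n_comps=n_comps, gene_subset=hvg)
            G = knn_graph(E, k=config.knn, metric=config.metric)
            E.write_csv(emb_path)
            G.write_tsv(graph_path, cell_ids=E.cell_ids)
            timings["preprocess"] = time.time() - t0
            logger.info("preprocess: %d cells, %d HVGs, %d edges", E.n_cells, len(hvg), len(G.edges))

        if "curvature" in stages:
            _require(emb_path, "preprocess", "curvature")
            from .preprocess import CellGraph, Embedding

            E = Embedding.read_csv(emb_path)
            G = CellGraph.read_tsv(graph_path)
            t0 = time.time()
            res = orc_all(G, alpha=config.alpha, ground=config.ground)
            pd.DataFrame(
                {
                    "cell_id": E.cell_ids,
                    "node_curvature": [res.node_curvature.get(v, np.nan) for v in range(E.n_cells)],
                }
            ).to_csv(os.path.join(out, "curvature_nodes.csv"), index=False)
            pd.DataFrame(
                [(i, j, k) for (i, j), k in sorted(res.edge_curvature.items())],
                columns=["i", "j", "kappa"],
            ).to_csv(os.path.join(out, "curvature_edges.csv"), index=False)
            timings["curvature"] = time.time() - t0

        if "cell-topology" in stages:
            _require(emb_path, "preprocess", "cell-topology")
            from .preprocess import Embedding

            E = Embedding.read_csv(emb_path)
            t0 = time.time()
            tab = cell_features_table(E, k_local=config.k_local, max_dim=config.max_dim)
            tab.to_csv(feat_path, index=False)
            timings["cell-topology"] = time.time() - t0

        if "gene-topology" in stages:
            t0 = time.time()
            X = read_counts(config.counts, format=config.counts_format)
            Xn = normalize_log1p(X, target_sum=config.target_sum)
            if config.gene_mode == "csn":
                hvg = select_hvg(Xn, min(config.n_hvg, Xn.n_genes))
                idx = Xn.gene_index(hvg)
                from .preprocess import ExpressionMatrix

                Xh = ExpressionMatrix(Xn.values[:, idx], Xn.cell_ids, hvg, layer_tag="lognorm")
                tab = csn_features_table(
                    Xh,
                    box_fraction=config.box_fraction,
                    sig_level=config.sig_level,
                    n_perm=config.n_perm,
                    seed=config.seed,
                    max_dim=config.max_dim,
                )
            elif config.gene_mode == "prior":
                if config.network is None:
                    raise ValueError("gene_mode 'prior' requires a network TSV")
                net_edges = read_network_tsv(config.network)
                tab = prior_network_features_table(net_edges, Xn, max_dim=config.max_dim)
            else:
                raise ValueError(f"unknown gene_mode: {config.gene_mode!r}")
            tab.to_csv(os.path.join(out, "gene_features.csv"), index=False)
            timings["gene-topology"] = time.time() - t0

        if "transitions" in stages:
            _require(feat_path, "cell-topology", "transitions")
            _require(graph_path, "preprocess", "transitions")
            from .preprocess import CellGraph

            t0 = time.time()
            tab = pd.read_csv(feat_path)
            if config.transition_score not in tab.columns:
                raise ValueError(
                    f"transition score column {config.transition_score!r} not in features"
                )
            calls = call_transitions(
                tab[config.transition_score].to_numpy(),
                q=config.transition_q,
                cell_ids=tab["cell_id"].astype(str).tolist(),
            )
            G = CellGraph.read_tsv(graph_path)
            if config.clusters is not None:
                clusters = (
                    pd.read_csv(config.clusters).iloc[:, 1].astype(str).to_numpy()
                )
            else:
                clusters = np.array(["all"] * len(calls.cell_ids))
            assoc, modified = associate_transition_groups(calls, clusters, G)
            pd.DataFrame(
                {
                    "cell_id": calls.cell_ids,
                    "score": calls.score,
                    "is_transition": calls.is_transition,
                    "group": calls.groups,
                    "modified_cluster": modified,
                }
            ).to_csv(os.path.join(out, "calls.csv"), index=False)
            with open(os.path.join(out, "transition_groups.json"), "w") as fh:
                json.dump({str(g): r for g, r in assoc.items()}, fh, indent=2)
            timings["transitions"] = time.time() - t0

        manifest = {
            "scgeom_version": __version__,
            "config": config.model_dump(),
            "config_hash": config.hash(),
            "seed": config.seed,
            "stages": stages,
            "timings_s": {k: round(v, 3) for k, v in timings.items()},
        }
        with open(os.path.join(out, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out
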