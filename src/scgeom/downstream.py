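"""Transition-cell calling, cluster association and topology-augmented
cell-type classification.

Transition cells are flagged by an upper-quantile rule on a per-cell score
(e.g. local H0 total persistence, or negated node curvature): cells whose
score lies above the (1 - q) quantile are called, with deterministic
tie-breaking by (score, index). Flagged cells are split into transition
groups by connected components of the cell graph restricted to flagged
cells, and each group is associated with the original clusters by ranked
population overlap.

Classification fits a random forest or SVM (class-balanced weighting, 5000
trees / C = 0.5) on gene features, topological features, or both, and
reports accuracy, adjusted balanced accuracy, and macro precision/recall.
The adjusted balanced accuracy here is mean per-class recall minus the
chance level 1/C (0 at chance, 1 - 1/C for a perfect C-class prediction);
the conventional normalized form, which divides by 1 - 1/C, is available
via ``adjusted="normalized"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .preprocess import CellGraph

__all__ = [
    "TransitionCalls",
    "ClassificationReport",
    "call_transitions",
    "associate_transition_groups",
    "metrics",
    "classify",
]


@dataclass
class TransitionCalls:
    cell_ids: list
    is_transition: np.ndarray
    score: np.ndarray
    groups: Optional[np.ndarray] = None  # -1 where not transition

    def flagged(self) -> np.ndarray:
        return np.nonzero(self.is_transition)[0]


@dataclass
class ClassificationReport:
    accuracy: float
    balanced_accuracy_adjusted: float
    precision_macro: float
    recall_macro: float

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "balanced_accuracy_adjusted": self.balanced_accuracy_adjusted,
            "precision_macro": self.precision_macro,
            "recall_macro": self.recall_macro,
        }


def call_transitions(
    score: Sequence[float], rule: str = "quantile", q: float = 0.1,
    cell_ids: Optional[Sequence[str]] = None,
) -> TransitionCalls:
    """Flag the round(q * n) cells with the highest scores (the cells above
    the (1 - q) quantile); ties are broken by (score, then lower index
    first among equals). Constant scores yield no calls and a warning.
    Invariant under strictly increasing transforms of the score."""
    if rule != "quantile":
        raise ValueError(f"unknown rule: {rule!r}")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    score = np.asarray(score, dtype=float)
    n = len(score)
    ids = list(cell_ids) if cell_ids is not None else [str(i) for i in range(n)]
    flags = np.zeros(n, dtype=bool)
    if np.all(score == score[0]):
        warnings.warn("constant scores: no transition cells called")
        return TransitionCalls(ids, flags, score)
    m = int(round(q * n))
    order = np.lexsort((np.arange(n), -score))
    flags[order[:m]] = True
    return TransitionCalls(ids, flags, score)


def associate_transition_groups(
    calls: TransitionCalls, clusters: Sequence, G: CellGraph
):
    """Split flagged cells into groups (connected components of the cell
    graph restricted to flagged cells), associate each group with the
    original clusters ranked by overlap count, and build the modified
    clustering where flagged cells are reassigned to new transition labels.

    Returns ``(association, modified_labels)`` where ``association`` maps
    group id -> list of (cluster label, overlap count) in descending
    overlap, and ``modified_labels`` is the original labels with flagged
    cells relabelled ``"transition_<group>"``. Also fills ``calls.groups``.
    """
    clusters = np.asarray(clusters)
    if len(clusters) != len(calls.is_transition):
        raise ValueError("clusters must label every cell")
    flagged = set(calls.flagged().tolist())
    # union-find over flagged-induced subgraph
    parent = {v: v for v in flagged}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for i, j in G.edges:
        if i in flagged and j in flagged:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)
    roots = sorted({find(v) for v in flagged})
    gid = {r: g for g, r in enumerate(roots)}
    groups = np.full(len(clusters), -1, dtype=int)
    for v in flagged:
        groups[v] = gid[find(v)]
    calls.groups = groups
    association = {}
    for g in range(len(roots)):
        members = np.nonzero(groups == g)[0]
        labels, counts = np.unique(clusters[members], return_counts=True)
        ranked = sorted(zip(labels.tolist(), counts.tolist()), key=lambda t: (-t[1], str(t[0])))
        association[g] = ranked
    modified = clusters.astype(object).copy()
    for v in flagged:
        modified[v] = f"transition_{groups[v]}"
    return association, modified


def metrics(y_true, y_pred, adjusted: str = "plain") -> ClassificationReport:
    """Accuracy, adjusted balanced accuracy and macro precision/recall.

    Classes are the distinct ground-truth labels. Adjusted balanced
    accuracy is mean per-class recall minus 1/C (``adjusted="plain"``) or
    its normalized form (mean recall - 1/C) / (1 - 1/C)
    (``adjusted="normalized"``, the scikit-learn convention). A macro
    precision term with an empty predicted class contributes 0.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred) or len(y_true) == 0:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    classes = np.unique(y_true)
    C = len(classes)
    acc = float(np.mean(y_true == y_pred))
    recalls, precisions = [], []
    for c in classes:
        in_c = y_true == c
        pred_c = y_pred == c
        recalls.append(float(np.sum(in_c & pred_c)) / float(np.sum(in_c)))
        npred = float(np.sum(pred_c))
        precisions.append(float(np.sum(in_c & pred_c)) / npred if npred > 0 else 0.0)
    mean_recall = float(np.mean(recalls))
    ba = mean_recall - 1.0 / C
    if adjusted == "normalized":
        ba = ba / (1.0 - 1.0 / C) if C > 1 else ba
    elif adjusted != "plain":
        raise ValueError("adjusted must be 'plain' or 'normalized'")
    return ClassificationReport(
        accuracy=acc,
        balanced_accuracy_adjusted=ba,
        precision_macro=float(np.mean(precisions)),
        recall_macro=mean_recall,
    )


def _fit_model(model: str, seed: int):
    if model == "rf":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(
            n_estimators=5000, class_weight="balanced", random_state=seed, n_jobs=1
        )
    if model == "svm":
        from sklearn.svm import SVC

        return SVC(C=0.5, class_weight="balanced", random_state=seed)
    raise ValueError(f"unknown model: {model!r}")


def classify(
    gene_features,
    topo_features,
    labels,
    model: str = "rf",
    feature_set: str = "gene+topo",
    split=0.5,
    seed: int = 0,
    adjusted: str = "plain",
):
    """Fit the classifier on the chosen feature block(s) and evaluate on the
    test split.

    ``split`` is either a (train_idx, test_idx) pair or a test fraction for
    a seeded stratified split. Returns (ClassificationReport, y_pred).
    """
    blocks = []
    if feature_set in ("gene", "gene+topo"):
        blocks.append(np.asarray(gene_features, dtype=float))
    if feature_set in ("topo", "gene+topo"):
        blocks.append(np.asarray(topo_features, dtype=float))
    if not blocks:
        raise ValueError(f"unknown feature_set: {feature_set!r}")
    X = np.hstack(blocks)
    y = np.asarray(labels)
    if isinstance(split, (tuple, list)) and len(split) == 2:
        train_idx, test_idx = np.asarray(split[0], int), np.asarray(split[1], int)
    else:
        from sklearn.model_selection import train_test_split

        train_idx, test_idx = train_test_split(
            np.arange(len(y)), test_size=float(split), random_state=seed, stratify=y
        )
    missing = set(np.unique(y[test_idx])) - set(np.unique(y[train_idx]))
    if missing:
        raise ValueError(f"classes absent from the training split: {sorted(missing)}")
    clf = _fit_model(model, seed)
    clf.fit(X[train_idx], y[train_idx])
    y_pred = clf.predict(X[test_idx])
    return metrics(y[test_idx], y_pred, adjusted=adjusted), y_pred
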