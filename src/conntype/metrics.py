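"""Evaluation protocol: cluster-to-label matching and the four metrics.

Unsupervised cluster labels are arbitrary, so predicted clusters are first
matched to ground-truth types by a maximum-weight bipartite matching whose
edge weights are overlap counts |A ∩ B| (Hungarian algorithm); the matched
accuracy is the total matched overlap divided by n.  Seeded predictions
are evaluated directly with accuracy, top-k accuracy, adjusted Rand index
and support-weighted F1.
"""

from __future__ import annotations

from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score, f1_score

from .graph import Labeling

__all__ = [
    "match_clusters",
    "MatchResult",
    "accuracy",
    "top_k_accuracy",
    "adjusted_rand_index",
    "weighted_f1",
    "evaluate_seeded",
    "evaluate_unseeded",
]


def _common_nodes(pred: Labeling, truth: Labeling) -> list[str]:
    p, t = set(pred.assignment), set(truth.assignment)
    if p != t:
        raise ValueError(
            f"node set mismatch: {len(p - t)} extra predicted, "
            f"{len(t - p)} missing"
        )
    return list(pred.assignment)


class MatchResult(NamedTuple):
    mapping: dict[str, str]  # predicted cluster label -> truth label
    matched_accuracy: float
    relabeled: Labeling  # prediction after applying the mapping


def match_clusters(pred: Labeling, truth: Labeling) -> MatchResult:
    """Optimal relabeling of predicted clusters against ground truth.

    Builds the contingency table between predicted clusters and truth
    labels and solves the assignment problem maximizing total overlap.
    Predicted clusters left unmatched (when K > K*) keep their own label
    and contribute zero correct nodes; unmatched truth labels (K < K*)
    are simply never predicted.
    """
    nodes = _common_nodes(pred, truth)
    p_labels = list(pred.label_universe)
    t_labels = list(truth.label_universe)
    p_lut = {lab: i for i, lab in enumerate(p_labels)}
    t_lut = {lab: i for i, lab in enumerate(t_labels)}
    table = np.zeros((len(p_labels), len(t_labels)), dtype=np.int64)
    for u in nodes:
        table[p_lut[pred.assignment[u]], t_lut[truth.assignment[u]]] += 1
    rows, cols = linear_sum_assignment(table, maximize=True)
    mapping = {p_labels[r]: t_labels[c] for r, c in zip(rows, cols)}
    matched = int(table[rows, cols].sum())
    relabeled = Labeling(
        {u: mapping.get(pred.assignment[u], pred.assignment[u])
         for u in nodes},
        seed_set=pred.seed_set,
        label_universe=tuple(sorted(
            set(t_labels)
            | {mapping.get(l, l) for l in p_labels}
        )),
    )
    return MatchResult(mapping, matched / len(nodes), relabeled)


def accuracy(
    pred: Labeling,
    truth: Labeling,
    exclude: Iterable[str] = (),
) -> float:
    """Fraction of nodes labeled correctly, skipping ``exclude``.

    In seeded mode the seeds are conventionally excluded (they are
    given); pass ``exclude=()`` to count them.
    """
    skip = set(exclude)
    nodes = [u for u in _common_nodes(pred, truth) if u not in skip]
    if not nodes:
        raise ValueError("no nodes to evaluate")
    hits = sum(pred.assignment[u] == truth.assignment[u] for u in nodes)
    return hits / len(nodes)


def top_k_accuracy(
    ranked: Mapping[str, Sequence[tuple[str, float]]],
    truth: Labeling,
    k: int,
    exclude: Iterable[str] = (),
) -> float:
    """Fraction of nodes whose true label appears among the k closest
    unique predicted labels.  Top-1 equals plain accuracy."""
    if k < 1:
        raise ValueError("k must be >= 1")
    skip = set(exclude)
    nodes = [u for u in truth.assignment if u not in skip]
    if not nodes:
        raise ValueError("no nodes to evaluate")
    hits = 0
    for u in nodes:
        if u not in ranked:
            raise ValueError(f"missing ranked prediction for node {u!r}")
        top = [lab for lab, _ in ranked[u][:k]]
        hits += truth.assignment[u] in top
    return hits / len(nodes)


def _paired_arrays(pred: Labeling, truth: Labeling):
    nodes = _common_nodes(pred, truth)
    return (
        [pred.assignment[u] for u in nodes],
        [truth.assignment[u] for u in nodes],
    )


def adjusted_rand_index(pred: Labeling, truth: Labeling) -> float:
    """Chance-adjusted pair-counting similarity of the two partitions;
    invariant to relabeling, 1.0 for identical partitions."""
    p, t = _paired_arrays(pred, truth)
    return float(adjusted_rand_score(t, p))


def weighted_f1(pred: Labeling, truth: Labeling) -> float:
    """Per-class F1 averaged with weights proportional to class support.

    For unsupervised output, apply ``match_clusters`` first so class
    labels are comparable.
    """
    p, t = _paired_arrays(pred, truth)
    return float(f1_score(t, p, average="weighted", zero_division=0))


def evaluate_seeded(
    pred: Labeling,
    truth: Labeling,
    ranked: Mapping[str, Sequence[tuple[str, float]]] | None = None,
    include_seeds: bool = False,
) -> dict[str, float]:
    """The seeded-mode metric report: accuracy, top-5 accuracy (when a
    ranking is supplied), ARI and weighted F1."""
    exclude = () if include_seeds else pred.seed_set
    report = {
        "accuracy": accuracy(pred, truth, exclude=exclude),
        "ari": adjusted_rand_index(pred, truth),
        "weighted_f1": weighted_f1(pred, truth),
    }
    if ranked is not None:
        report["top5_accuracy"] = top_k_accuracy(
            ranked, truth, 5, exclude=exclude
        )
    return report


def evaluate_unseeded(pred: Labeling, truth: Labeling) -> dict[str, float]:
    """The unseeded-mode report: matched accuracy, ARI, weighted F1 after
    optimal cluster-to-label matching."""
    match = match_clusters(pred, truth)
    return {
        "matched_accuracy": match.matched_accuracy,
        "ari": adjusted_rand_index(pred, truth),
        "weighted_f1": weighted_f1(match.relabeled, truth),
    }
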