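"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive — double loops, exhaustive
enumeration — and shares no code path with the package internals.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
from sympy.utilities.iterables import multiset_partitions


def naive_jaccard(a, b) -> float:
    """Scalar-loop weighted Jaccard distance."""
    smin = smax = 0.0
    for x, y in zip(a, b):
        smin += min(x, y)
        smax += max(x, y)
    return 0.0 if smax == 0 else 1.0 - smin / smax


def naive_pairwise(A, B) -> np.ndarray:
    """Double-loop pairwise Jaccard distances."""
    out = np.empty((len(A), len(B)))
    for i, a in enumerate(A):
        for j, b in enumerate(B):
            out[i, j] = naive_jaccard(a, b)
    return out


def embeddings_by_summation(graph, partition) -> np.ndarray:
    """Degree-count embeddings via direct per-edge summation."""
    labels = list(partition.label_universe)
    pos = {lab: j for j, lab in enumerate(labels)}
    k = len(labels)
    emb = np.zeros((graph.n, 2 * k))
    for src, tgt, w in graph.edge_records():
        i, j = graph.index(src), graph.index(tgt)
        emb[i, pos[partition.assignment[tgt]]] += w
        emb[j, k + pos[partition.assignment[src]]] += w
    return emb


def blocks_are_equitable(adj: np.ndarray, blocks: list[list[int]]) -> bool:
    """Exhaustive check: constant per-node in/out totals to every block."""
    for B in blocks:
        for C in blocks:
            outs = {adj[u, C].sum() for u in B}
            ins = {adj[C, u].sum() for u in B}
            if len(outs) > 1 or len(ins) > 1:
                return False
    return True


def min_equitable_clusters_below(adj: np.ndarray, limit: int) -> int | None:
    """Smallest cluster count < limit over all equitable set partitions.

    Returns None when no equitable partition with fewer than ``limit``
    clusters exists.  Exhaustive over all set partitions with a fixed
    block count, so only usable at n <= 10.
    """
    n = adj.shape[0]
    for k in range(1, limit):
        for blocks in multiset_partitions(list(range(n)), k):
            if blocks_are_equitable(adj, blocks):
                return k
    return None


def all_bipartitions(n: int):
    """All 2-block set partitions of range(n)."""
    yield from multiset_partitions(list(range(n)), 2)


def brute_force_matched_accuracy(pred_labels, truth_labels) -> float:
    """Max accuracy over all injections of predicted clusters into truth
    labels (feasible for <= 6 predicted clusters)."""
    p_set = sorted(set(pred_labels))
    t_set = sorted(set(truth_labels))
    n = len(pred_labels)
    best = 0
    small, large, pred_is_small = (
        (p_set, t_set, True) if len(p_set) <= len(t_set)
        else (t_set, p_set, False)
    )
    for perm in permutations(large, len(small)):
        if pred_is_small:
            mapping = dict(zip(small, perm))
            hits = sum(
                mapping[p] == t for p, t in zip(pred_labels, truth_labels)
            )
        else:
            mapping = dict(zip(perm, small))
            hits = sum(
                mapping.get(p) == t
                for p, t in zip(pred_labels, truth_labels)
            )
        best = max(best, hits)
    return best / n
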