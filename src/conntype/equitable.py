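"""Exact equitable partitions and the Jaccard cost functional.

A partition is *equitable* when every member of a cluster has exactly the
same degree-count embedding w.r.t. that partition — i.e. cells of the same
type send and receive identical total weight to and from every cluster.
The coarsest equitable partition is unique and is found by classical
iterative refinement (the weighted, directed analogue of color
refinement / 1-WL).

The *Jaccard cost* of a partition relaxes exactness: it is the summed
Jaccard distance between each node's embedding and its cluster centroid,
and is zero precisely when the partition is equitable (median centroids).
Minimizing it over partitions into at most k clusters is the approximate
equitable partitioning problem solved heuristically by the unseeded
algorithm.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .embedding import cluster_centroids, compute_embeddings, pairwise_jaccard
from .graph import Labeling, WeightedDigraph

__all__ = [
    "coarsest_equitable_partition",
    "is_equitable",
    "partition_cost",
    "PartitionCost",
    "refinement_indices",
]


def _labeling_from_groups(graph: WeightedDigraph, idx: np.ndarray) -> Labeling:
    """Relabel group indices so clusters are ordered by smallest member."""
    order: dict[int, int] = {}
    for g in idx:
        if g not in order:
            order[g] = len(order)
    k = len(order)
    width = max(1, len(str(k - 1)))
    labels = [f"c{j:0{width}d}" for j in range(k)]
    new_idx = np.array([order[g] for g in idx], dtype=np.intp)
    return Labeling.from_indices(graph, new_idx, labels)


def _group_by_rows(emb: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Split each group of ``idx`` by exact equality of embedding rows."""
    n = emb.shape[0]
    new = np.empty(n, dtype=np.intp)
    seen: dict[tuple, int] = {}
    for i in range(n):
        key = (int(idx[i]), emb[i].tobytes())
        if key not in seen:
            seen[key] = len(seen)
        new[i] = seen[key]
    return new


def refinement_indices(graph: WeightedDigraph) -> np.ndarray:
    """Cluster index per node of the coarsest equitable partition.

    Starts from the trivial one-cluster partition and repeatedly splits
    clusters whose members disagree on any embedding coordinate, until
    stable.  Comparison is exact: integral input weights stay exactly
    representable in float64, so refinement is not corrupted by round-off.
    Terminates in at most n rounds (cluster count strictly increases until
    fixpoint).
    """
    n = graph.n
    idx = np.zeros(n, dtype=np.intp)
    k = 1
    while True:
        part = _labeling_from_groups(graph, idx)
        emb = compute_embeddings(graph, part)
        new_idx = _group_by_rows(emb, idx)
        new_k = int(new_idx.max()) + 1 if n else 0
        if new_k == k:
            return idx
        idx, k = new_idx, new_k


def coarsest_equitable_partition(graph: WeightedDigraph) -> Labeling:
    """The unique minimum-cluster-count equitable partition.

    Cluster identifiers are deterministic: clusters are numbered by their
    smallest member in graph node order.
    """
    return _labeling_from_groups(graph, refinement_indices(graph))


def is_equitable(graph: WeightedDigraph, partition: Labeling) -> bool:
    """True iff all within-cluster embeddings are exactly equal."""
    emb = compute_embeddings(graph, partition)
    for members in partition.clusters(graph):
        if len(members) > 1 and not (emb[members] == emb[members[0]]).all():
            return False
    return True


class PartitionCost(NamedTuple):
    total: float
    average: float  # total / n, the per-node normalized cost
    centroids: np.ndarray  # (k, 2k) cluster centroids M_1..M_k


def partition_cost(
    graph: WeightedDigraph,
    partition: Labeling,
    method: str = "median",
) -> PartitionCost:
    """Jaccard cost of a total partition: sum_i sum_{v in Ci} D_J(f(v), M_i).

    M_i is the coordinate-wise median (default) or mean of cluster i's
    embeddings.  Also reports the average cost (divided by n).  With the
    median method the cost is zero exactly when the partition is
    equitable; the mean method reports a cost but that equivalence only
    holds for odd cluster sizes.

    Raises on an empty cluster.
    """
    emb = compute_embeddings(graph, partition)
    clusters = partition.clusters(graph)
    M = cluster_centroids(emb, clusters, method)
    total = 0.0
    for i, members in enumerate(clusters):
        if len(members):
            total += float(
                pairwise_jaccard(emb[members], M[i][None, :]).sum()
            )
    n = graph.n
    return PartitionCost(total, total / n if n else 0.0, M)
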