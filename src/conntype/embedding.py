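"""Partition-dependent degree-count embeddings and weighted Jaccard distance.

Given a k-partition C1..Ck of the node set, the degree-count embedding of a
node u is the 2k-vector

    f(u) = [ e(u, C1), ..., e(u, Ck), e(C1, u), ..., e(Ck, u) ]

i.e. the total out-weight of u into each cluster followed by the total
in-weight of u from each cluster.  Embeddings are compared with the
weighted Jaccard (Ruzicka) distance

    D_J(a, b) = 1 - sum_i min(a_i, b_i) / sum_i max(a_i, b_i)

which is a metric on non-negative vectors.  Both quantities are the basic
currency of every algorithm in this package.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .graph import Labeling, WeightedDigraph

__all__ = [
    "compute_embeddings",
    "jaccard_distance",
    "pairwise_jaccard",
    "centroid",
    "cluster_centroids",
]

# Row-chunk size for the blocked pairwise computation; bounds the size of
# the (chunk, n_b, dim) broadcast intermediate.
_CHUNK_ELEMS = 4_000_000


def compute_embeddings(
    graph: WeightedDigraph, partition: Labeling
) -> np.ndarray:
    """Degree-count embeddings of all nodes w.r.t. a total partition.

    Returns an (n, 2k) array in graph node order: column j is the
    out-weight to cluster j, column j+k the in-weight from cluster j.
    Isolated nodes get the zero vector.  Self-loops contribute to both the
    out and the in coordinate of their own node.

    Raises if some graph node is missing from the partition.
    """
    idx = partition.label_indices(graph)  # raises on missing nodes
    k = partition.k
    n = graph.n
    onehot = sp.csr_matrix(
        (np.ones(n), (np.arange(n), idx)), shape=(n, k)
    )
    out_block = graph.adjacency @ onehot
    in_block = graph.adjacency_t @ onehot
    return np.hstack([np.asarray(out_block.todense()),
                      np.asarray(in_block.todense())])


def _check_nonneg(*arrays: np.ndarray) -> None:
    for a in arrays:
        if a.size and a.min() < 0:
            raise ValueError("Jaccard distance requires non-negative vectors")


def jaccard_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Weighted Jaccard distance between two non-negative vectors.

    By convention D_J(0, 0) = 0: two nodes with empty neighbourhoods are
    indistinguishable, so their distance is zero rather than the literal
    0/0 of the formula.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    _check_nonneg(a, b)
    smax = float(np.maximum(a, b).sum())
    if smax == 0.0:
        return 0.0
    smin = float(np.minimum(a, b).sum())
    return 1.0 - smin / smax


def pairwise_jaccard(rows_a: np.ndarray, rows_b: np.ndarray) -> np.ndarray:
    """All-pairs weighted Jaccard distances between two stacks of vectors.

    Entry (i, j) equals ``jaccard_distance(rows_a[i], rows_b[j])``; the
    blocked vectorized evaluation is exact up to float round-off (< 1e-12
    of the scalar form).  Uses the identity
    sum(max) = sum(a) + sum(b) - sum(min) to halve the work.
    """
    A = np.atleast_2d(np.asarray(rows_a, dtype=np.float64))
    B = np.atleast_2d(np.asarray(rows_b, dtype=np.float64))
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"dimension mismatch: {A.shape[1]} vs {B.shape[1]}")
    _check_nonneg(A, B)
    sa = A.sum(axis=1)
    sb = B.sum(axis=1)
    out = np.empty((A.shape[0], B.shape[0]), dtype=np.float64)
    step = max(1, _CHUNK_ELEMS // max(1, B.shape[0] * B.shape[1]))
    for lo in range(0, A.shape[0], step):
        hi = min(lo + step, A.shape[0])
        smin = np.minimum(A[lo:hi, None, :], B[None, :, :]).sum(axis=2)
        smax = sa[lo:hi, None] + sb[None, :] - smin
        with np.errstate(invalid="ignore", divide="ignore"):
            d = 1.0 - smin / smax
        d[smax == 0.0] = 0.0  # D_J(0, 0) := 0
        out[lo:hi] = d
    return out


def centroid(embeddings: np.ndarray, method: str = "median") -> np.ndarray:
    """Coordinate-wise median (default) or mean of a non-empty vector set.

    The coordinate-wise median approximates the Jaccard median (the
    NP-hard minimizer of summed Jaccard distances); for an even count it
    is the midpoint of the two central order statistics.
    """
    X = np.atleast_2d(np.asarray(embeddings, dtype=np.float64))
    if X.shape[0] == 0:
        raise ValueError("centroid of an empty set")
    if method == "median":
        return np.median(X, axis=0)
    if method == "mean":
        return X.mean(axis=0)
    raise ValueError(f"unknown centroid method {method!r}")


def cluster_centroids(
    embeddings: np.ndarray,
    clusters: list[np.ndarray],
    method: str = "median",
) -> np.ndarray:
    """Per-cluster centroids M_1..M_k of the embedding rows.

    Raises on an empty cluster.
    """
    k = len(clusters)
    M = np.empty((k, embeddings.shape[1]), dtype=np.float64)
    for i, members in enumerate(clusters):
        if len(members) == 0:
            raise ValueError(f"cluster {i} is empty")
        M[i] = centroid(embeddings[members], method)
    return M
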