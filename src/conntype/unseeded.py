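"""Unsupervised approximate equitable partitioning by greedy seed growth.

The solver grows a sequence of seed vertices s1..sk, one per cluster,
akin to a k-center sweep — except that node features (degree-count
embeddings) depend on the current partition, so after each new seed the
semi-supervised solver is re-run to produce the next partition:

1. start from the trivial one-cluster partition; the first seed is the
   node whose embedding is Jaccard-closest to the coordinate-wise median
   of all embeddings;
2. repeat until k seeds exist: score every candidate node by the total
   Jaccard-cost reduction it would yield as the center of a new cluster,
   pick the best, run the seeded solver with each seed carrying its own
   singleton label (capped at R iterations), and re-pick each cluster's
   best representative (member closest to the cluster median) as its
   seed.

Adding a cluster does not always lower cost, so with ``return_best`` the
solver also reports the minimum-cost partition among all intermediate
ones.  The whole procedure is deterministic; the optional T parameter
restricts seed candidates to the T-fraction of nodes farthest from their
cluster medians, trading a little optimization effort for speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np

from .embedding import cluster_centroids, compute_embeddings, pairwise_jaccard
from .equitable import PartitionCost, partition_cost
from .graph import Labeling, WeightedDigraph
from .seeded import SeededConfig, seeded_ntac

__all__ = [
    "UnseededConfig",
    "UnseededResult",
    "StepRecord",
    "unseeded_ntac",
    "select_next_seed",
    "candidate_pool",
    "best_representatives",
]


@dataclass(frozen=True)
class UnseededConfig:
    """Parameters of the unseeded solver.

    k: target number of clusters (1 <= k <= n).
    R: iteration cap for each seeded subproblem (default 12).
    T: fraction of nodes eligible as seed candidates, in (0, 1];
        T = 1 evaluates every node.
    return_best: also return the minimum-cost intermediate partition.
    centroid_method: 'median' (default) or 'mean' cluster centroids.
    """

    k: int
    R: int = 12
    T: float = 1.0
    return_best: bool = True
    centroid_method: str = "median"

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0 < self.T <= 1:
            raise ValueError("T must be in (0, 1]")
        if self.R < 1:
            raise ValueError("R must be >= 1")
        if self.centroid_method not in ("median", "mean"):
            raise ValueError(f"unknown centroid method {self.centroid_method!r}")


@dataclass(frozen=True)
class StepRecord:
    n_clusters: int
    cost: float
    seeds: tuple[str, ...]
    labeling: Labeling


@dataclass(frozen=True)
class UnseededResult:
    final: Labeling
    best: Labeling | None
    trace: tuple[StepRecord, ...] = field(default_factory=tuple)

    @property
    def best_cost(self) -> float:
        return min(rec.cost for rec in self.trace)

    @property
    def final_cost(self) -> float:
        return self.trace[-1].cost


def _cluster_state(
    graph: WeightedDigraph, partition: Labeling, method: str
) -> tuple[np.ndarray, list[np.ndarray], np.ndarray, np.ndarray]:
    """Embeddings, clusters, centroids, and D_J(f(u), M_cluster(u))."""
    emb = compute_embeddings(graph, partition)
    clusters = partition.clusters(graph)
    M = cluster_centroids(emb, clusters, method)
    idx = partition.label_indices(graph)
    d_med = np.empty(graph.n)
    for i, members in enumerate(clusters):
        if len(members):
            d_med[members] = pairwise_jaccard(emb[members], M[i][None, :])[:, 0]
    return emb, clusters, M, d_med


def best_representatives(
    graph: WeightedDigraph,
    partition: Labeling,
    method: str = "median",
) -> list[str]:
    """For each cluster, the member closest to the cluster median.

    Ties are broken by graph node order; clusters are reported in label
    order.  On the trivial partition this yields the first seed: the node
    nearest the coordinate-wise median of all embeddings.
    """
    emb, clusters, M, _ = _cluster_state(graph, partition, method)
    reps: list[str] = []
    for i, members in enumerate(clusters):
        if len(members) == 0:
            raise ValueError(f"cluster {i} is empty")
        d = pairwise_jaccard(emb[members], M[i][None, :])[:, 0]
        reps.append(graph.nodes[members[np.argmin(d)]])
    return reps


def candidate_pool(
    graph: WeightedDigraph,
    partition: Labeling,
    T: float = 1.0,
    method: str = "median",
) -> list[str]:
    """The ceil(T*n) seed candidates: nodes farthest from their medians.

    Collected round-robin over clusters — the farthest-from-median member
    of each cluster first, then the second-farthest of each, and so on,
    skipping exhausted clusters.  Within-cluster distance ties fall back
    to node order.
    """
    if not 0 < T <= 1:
        raise ValueError("T must be in (0, 1]")
    emb, clusters, M, _ = _cluster_state(graph, partition, method)
    size = ceil(T * graph.n)
    ranked: list[np.ndarray] = []
    for i, members in enumerate(clusters):
        if len(members) == 0:
            ranked.append(members)
            continue
        d = pairwise_jaccard(emb[members], M[i][None, :])[:, 0]
        # descending distance, then ascending node index
        order = np.lexsort((members, -d))
        ranked.append(members[order])
    pool: list[str] = []
    depth = 0
    while len(pool) < size:
        advanced = False
        for r in ranked:
            if depth < len(r):
                advanced = True
                pool.append(graph.nodes[r[depth]])
                if len(pool) == size:
                    break
        if not advanced:
            break
        depth += 1
    return pool


def select_next_seed(
    graph: WeightedDigraph,
    partition: Labeling,
    seeds: list[str],
    T: float = 1.0,
    method: str = "median",
) -> str:
    """The candidate whose new cluster would most reduce the Jaccard cost.

    score(v) = sum_u max(0, D_J(f(u), M_cluster(u)) - D_J(f(u), f(v))) —
    the cost saved by the nodes that would rather sit with v than with
    their current cluster median.  Returns the maximizer over the
    candidate pool minus current seeds; ties go to the earlier node in
    graph order.
    """
    emb, _, _, d_med = _cluster_state(graph, partition, method)
    seed_set = set(seeds)
    cand = [v for v in candidate_pool(graph, partition, T, method)
            if v not in seed_set]
    if not cand:
        raise ValueError("no seed candidates available")
    cand_idx = np.array([graph.index(v) for v in cand], dtype=np.intp)
    dist = pairwise_jaccard(emb, emb[cand_idx])  # (n, n_cand)
    scores = np.maximum(0.0, d_med[:, None] - dist).sum(axis=0)
    # strict > over candidates sorted by node order breaks ties by order
    order = np.argsort(cand_idx, kind="stable")
    best_c, best_s = order[0], scores[order[0]]
    for c in order[1:]:
        if scores[c] > best_s:
            best_c, best_s = c, scores[c]
    return cand[best_c]


def _seed_labeling(seeds: list[str], k_hint: int) -> Labeling:
    """Each seed carries its own singleton label; label sort = seed order."""
    width = max(2, len(str(max(k_hint - 1, 1))))
    assignment = {s: f"s{i:0{width}d}" for i, s in enumerate(seeds)}
    return Labeling(assignment, seed_set=frozenset(seeds))


def unseeded_ntac(
    graph: WeightedDigraph, config: UnseededConfig
) -> UnseededResult:
    """Grow k clusters by greedy seed selection; fully deterministic.

    Returns the k-cluster partition, the per-step trace of (cluster
    count, cost, seeds, partition), and — with ``return_best`` — the
    intermediate partition of minimum Jaccard cost (cost is not monotone
    in the number of clusters, so the best partition may have fewer).
    """
    n = graph.n
    if config.k > n:
        raise ValueError(f"k={config.k} exceeds node count n={n}")
    method = config.centroid_method

    width = max(2, len(str(max(config.k - 1, 1))))
    trivial = Labeling.from_indices(
        graph, np.zeros(n, dtype=np.intp), [f"s{0:0{width}d}"]
    )
    seeds = best_representatives(graph, trivial, method)
    cost = partition_cost(graph, trivial, method)
    trace = [StepRecord(1, cost.total, tuple(seeds), trivial)]
    current = trivial

    sub_cfg = SeededConfig(iterations=config.R, early_stop=True)
    for _ in range(1, config.k):
        new_seed = select_next_seed(graph, current, seeds, config.T, method)
        seed_lab = _seed_labeling(seeds + [new_seed], config.k)
        current = seeded_ntac(graph, seed_lab, sub_cfg).labeling
        seeds = best_representatives(graph, current, method)
        cost = partition_cost(graph, current, method)
        trace.append(
            StepRecord(current.k, cost.total, tuple(seeds), current)
        )

    best: Labeling | None = None
    if config.return_best:
        best = min(trace, key=lambda rec: rec.cost).labeling
    return UnseededResult(current, best, tuple(trace))
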