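"""Semi-supervised cell-type assignment by iterated nearest-seed search.

Starting from a partial labeling (the *seeds*), all unlabeled nodes are
initialized to one arbitrary label so the labeling is total, and the
following two steps alternate for a fixed number of iterations (with early
stop at a fixpoint):

1. compute degree-count embeddings w.r.t. the current labeling;
2. reassign every non-seed to the label of its Jaccard-nearest seed.

Seeds never change label.  Because the embedding depends on the labeling,
iterating lets label information propagate through the connectivity
structure.  The procedure is fully deterministic: the initialization label
is the first of the sorted label universe, and all nearest-seed ties are
broken by seed position in graph node order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .embedding import compute_embeddings, pairwise_jaccard
from .graph import Labeling, WeightedDigraph

__all__ = ["SeededConfig", "SeededResult", "seeded_ntac", "top_k_labels",
           "sample_seeds"]


@dataclass(frozen=True)
class SeededConfig:
    """Knobs of the seeded solver.

    iterations: maximum embedding/assignment rounds (default 15).
    early_stop: stop as soon as no non-seed changes label.
    init_label: label all non-seeds start from; None picks the first label
        of the sorted universe.  The choice is arbitrary in principle;
        the knob exists only for sensitivity checks.
    """

    iterations: int = 15
    early_stop: bool = True
    init_label: str | None = None

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass(frozen=True)
class SeededResult:
    labeling: Labeling
    changes_per_iteration: tuple[int, ...] = field(default_factory=tuple)

    @property
    def n_iterations(self) -> int:
        return len(self.changes_per_iteration)


def _seed_arrays(
    graph: WeightedDigraph, seeds: Labeling
) -> tuple[np.ndarray, np.ndarray]:
    """Seed node indices (graph order) and their label indices."""
    lut = {lab: i for i, lab in enumerate(seeds.label_universe)}
    pairs = []
    for u in seeds.seed_set:
        if u not in graph:
            raise ValueError(f"seed node {u!r} not present in graph")
        pairs.append((graph.index(u), lut[seeds.assignment[u]]))
    pairs.sort()
    seed_idx = np.array([p[0] for p in pairs], dtype=np.intp)
    seed_lab = np.array([p[1] for p in pairs], dtype=np.intp)
    return seed_idx, seed_lab


def seeded_ntac(
    graph: WeightedDigraph,
    seeds: Labeling,
    config: SeededConfig = SeededConfig(),
) -> SeededResult:
    """Propagate seed labels to all nodes; returns the total labeling.

    Every label of the universe should carry at least one seed; labels
    without seeds can never be predicted (a warning in the logs).  Output
    is deterministic given input.
    """
    if not seeds.seed_set:
        raise ValueError("at least one seed is required")
    labels = seeds.label_universe
    seed_idx, seed_lab = _seed_arrays(graph, seeds)
    seeded_labels = set(seed_lab.tolist())
    if len(seeded_labels) < len(labels):
        logging.getLogger("conntype").warning(
            "%d labels have no seed and can never be assigned",
            len(labels) - len(seeded_labels),
        )

    init = config.init_label if config.init_label is not None else labels[0]
    if init not in labels:
        raise ValueError(f"init_label {init!r} not in label universe")
    init_j = labels.index(init)

    n = graph.n
    y = np.full(n, init_j, dtype=np.intp)
    y[seed_idx] = seed_lab
    nonseed = np.setdiff1d(np.arange(n), seed_idx)

    trace: list[int] = []
    for _ in range(config.iterations):
        part = Labeling.from_indices(graph, y, labels)
        emb = compute_embeddings(graph, part)
        dist = pairwise_jaccard(emb[nonseed], emb[seed_idx])
        # argmin keeps the first (lowest node-order) seed on ties
        new = seed_lab[np.argmin(dist, axis=1)]
        changed = int((new != y[nonseed]).sum())
        y[nonseed] = new
        trace.append(changed)
        if config.early_stop and changed == 0:
            break

    final = Labeling.from_indices(
        graph, y, labels, seed_set=seeds.seed_set
    )
    return SeededResult(final, tuple(trace))


def top_k_labels(
    graph: WeightedDigraph,
    seeds: Labeling,
    final_labeling: Labeling,
    k_top: int,
) -> dict[str, list[tuple[str, float]]]:
    """Ranked list of the k_top closest unique seed labels per node.

    Distances are computed against the embeddings of ``final_labeling``
    (the labeling the solver converged to).  For each node, seed
    distances are sorted ascending (ties by seed node order), the first
    occurrence of each label is kept, and the list truncated to k_top.
    For non-seeds the rank-1 label equals the solver's assignment.
    """
    if k_top < 1:
        raise ValueError("k_top must be >= 1")
    seed_idx, seed_lab = _seed_arrays(graph, seeds)
    emb = compute_embeddings(graph, final_labeling)
    dist = pairwise_jaccard(emb, emb[seed_idx])
    labels = seeds.label_universe
    out: dict[str, list[tuple[str, float]]] = {}
    for i, node in enumerate(graph.nodes):
        order = np.argsort(dist[i], kind="stable")
        ranked: list[tuple[str, float]] = []
        seen: set[int] = set()
        for j in order:
            lab = int(seed_lab[j])
            if lab in seen:
                continue
            seen.add(lab)
            ranked.append((labels[lab], float(dist[i, j])))
            if len(ranked) == k_top:
                break
        out[node] = ranked
    return out


def sample_seeds(
    truth: Labeling,
    nodes: Sequence[str],
    fraction: float,
    rng: np.random.Generator,
) -> Labeling:
    """Uniform random seed sample (an experiment helper, not the solver).

    Draws ``ceil(fraction * len(nodes))`` nodes uniformly without
    replacement and exposes their true labels as seeds.  Does *not*
    guarantee one seed per class; classes that draw no seed cannot be
    recovered, mirroring realistic sparse annotation.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n_seeds = max(1, int(np.ceil(fraction * len(nodes))))
    chosen = rng.choice(len(nodes), size=n_seeds, replace=False)
    assignment = {nodes[i]: truth.assignment[nodes[i]] for i in chosen}
    return Labeling(
        assignment,
        seed_set=frozenset(assignment),
        label_universe=truth.label_universe,
    )
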