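"""Planted-partition generator: graphs with a known equitable partition.

The generator is the desk-scale stand-in for a connectome: k blocks of
neurons (cell types) where every node of block i sends a prescribed total
weight D[i][j] to block j and — thanks to a divisibility constraint —
every node of block j receives the same constant total from block i.  The
planted partition is therefore exactly equitable (Jaccard cost zero)
before noise.  Controlled noise (edge rewiring, multiplicative weight
jitter) then emulates biological variability and reconstruction errors.

Wiring is circulant by default: node r of block i targets nodes
(r*D[i][j] + t) mod n_j for t = 0..D[i][j]-1, which tiles the targets so
in-weights are exactly constant and the construction is reproducible
without randomness.  A seeded random-wiring mode preserves the same
exact in/out totals with shuffled target assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import Labeling, WeightedDigraph

__all__ = ["PlantedSpec", "generate_planted", "perturb", "random_spec"]


@dataclass(frozen=True)
class PlantedSpec:
    """Parameters of a planted near-equitable graph.

    block_sizes: nodes per block (length k).
    out_weight: k x k non-negative integer matrix D; D[i][j] is the total
        weight each block-i node sends to block j.
    edge_weight: weight multiplier per generated edge (synapse count
        scale), default 1.
    noise_p: probability that an edge is rewired to a uniform random
        target, default 0 (exactly equitable).
    weight_noise_sigma: sigma of multiplicative log-normal weight jitter,
        default 0 (off).
    rng_seed: seed for wiring (random mode) and noise.
    wiring: 'circulant' (deterministic) or 'random' (seeded shuffle, same
        exact block totals).
    """

    block_sizes: tuple[int, ...]
    out_weight: tuple[tuple[int, ...], ...]
    edge_weight: int = 1
    noise_p: float = 0.0
    weight_noise_sigma: float = 0.0
    rng_seed: int = 0
    wiring: str = "circulant"

    def __post_init__(self):
        object.__setattr__(self, "block_sizes", tuple(self.block_sizes))
        object.__setattr__(
            self, "out_weight",
            tuple(tuple(int(x) for x in row) for row in self.out_weight),
        )
        k = len(self.block_sizes)
        if k == 0 or any(s < 1 for s in self.block_sizes):
            raise ValueError("block sizes must be positive")
        if len(self.out_weight) != k or any(
            len(row) != k for row in self.out_weight
        ):
            raise ValueError("out_weight must be k x k")
        if any(x < 0 for row in self.out_weight for x in row):
            raise ValueError("out_weight entries must be non-negative")
        if self.edge_weight < 1:
            raise ValueError("edge_weight must be a positive integer")
        if not 0 <= self.noise_p <= 1:
            raise ValueError("noise_p must be in [0, 1]")
        if self.wiring not in ("circulant", "random"):
            raise ValueError(f"unknown wiring {self.wiring!r}")
        for i in range(k):
            for j in range(k):
                total = self.block_sizes[i] * self.out_weight[i][j]
                if total % self.block_sizes[j] != 0:
                    raise ValueError(
                        f"divisibility violated at block pair ({i}, {j}): "
                        f"{self.block_sizes[i]} * {self.out_weight[i][j]} "
                        f"is not a multiple of {self.block_sizes[j]}"
                    )

    @property
    def k(self) -> int:
        return len(self.block_sizes)

    @property
    def n(self) -> int:
        return sum(self.block_sizes)

    def is_generic(self) -> bool:
        """True when block connectivity profiles are pairwise distinct.

        The profile of block i concatenates its out row D[i][.] and its
        in column of per-node received weight; distinct profiles make the
        planted blocks distinguishable from connectivity alone.
        """
        D = np.array(self.out_weight, dtype=np.int64)
        sizes = np.array(self.block_sizes, dtype=np.int64)
        in_profile = (sizes[:, None] * D) / sizes[None, :]  # row j' -> block
        profiles = np.hstack([D, in_profile.T])
        return len({tuple(row) for row in profiles}) == self.k


def _node_names(sizes: tuple[int, ...]) -> tuple[list[str], list[str]]:
    """Node ids in block order and the matching truth labels."""
    kw = max(2, len(str(len(sizes) - 1)))
    nw = max(3, len(str(max(sizes) - 1)))
    names, labels = [], []
    for i, s in enumerate(sizes):
        for r in range(s):
            names.append(f"b{i:0{kw}d}n{r:0{nw}d}")
            labels.append(f"T{i:0{kw}d}")
    return names, labels


def generate_planted(spec: PlantedSpec) -> tuple[WeightedDigraph, Labeling]:
    """Build the planted graph and its ground-truth block labeling.

    Before noise the planted partition is exactly equitable; with
    ``spec.noise_p`` or ``spec.weight_noise_sigma`` set, the returned
    graph is perturbed accordingly (seeded by ``spec.rng_seed``).
    """
    sizes = spec.block_sizes
    D = spec.out_weight
    names, labels = _node_names(sizes)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    rng = np.random.default_rng(spec.rng_seed)

    edges: list[tuple[str, str, float]] = []
    for i in range(spec.k):
        for j in range(spec.k):
            d = D[i][j]
            if d == 0:
                continue
            si, sj = sizes[i], sizes[j]
            if spec.wiring == "circulant":
                for r in range(si):
                    for t in range(d):
                        q = (r * d + t) % sj
                        edges.append(
                            (names[offsets[i] + r],
                             names[offsets[j] + q],
                             float(spec.edge_weight))
                        )
            else:
                # random wiring with the same exact totals: each block-j
                # node appears si*d/sj times in a shuffled target list
                per_target = si * d // sj
                targets = np.repeat(np.arange(sj), per_target)
                rng.shuffle(targets)
                for r in range(si):
                    for q in targets[r * d:(r + 1) * d]:
                        edges.append(
                            (names[offsets[i] + r],
                             names[offsets[j] + int(q)],
                             float(spec.edge_weight))
                        )
    graph = WeightedDigraph.from_edges(edges, extra_nodes=names)
    truth = Labeling(dict(zip(names, labels)))
    if spec.noise_p > 0 or spec.weight_noise_sigma > 0:
        graph = perturb(
            graph,
            spec.noise_p,
            rng_seed=int(rng.integers(2**31)),
            weight_noise_sigma=spec.weight_noise_sigma,
        )
    return graph, truth


def perturb(
    graph: WeightedDigraph,
    noise_p: float,
    rng_seed: int,
    weight_noise_sigma: float = 0.0,
) -> WeightedDigraph:
    """Noise model: independent edge rewiring and weight jitter.

    Each edge is, with probability ``noise_p``, redirected to a target
    drawn uniformly from all nodes (weights merged on collision) —
    this breaks equitability while preserving the edge count and each
    node's out-strength.  With ``weight_noise_sigma`` > 0 every weight is
    additionally scaled by a log-normal factor exp(N(0, sigma^2)),
    perturbing weights but not topology.  Deterministic given
    ``rng_seed``.
    """
    if not 0 <= noise_p <= 1:
        raise ValueError("noise_p must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    records = graph.edge_records()
    nodes = graph.nodes
    out: list[tuple[str, str, float]] = []
    for src, tgt, w in records:
        if noise_p > 0 and rng.random() < noise_p:
            tgt = nodes[int(rng.integers(len(nodes)))]
        if weight_noise_sigma > 0:
            w = w * float(np.exp(rng.normal(0.0, weight_noise_sigma)))
        out.append((src, tgt, w))
    return WeightedDigraph.from_edges(out, extra_nodes=nodes)


def random_spec(
    k: int,
    block_size: int,
    rng: np.random.Generator,
    max_weight: int = 6,
    density: float = 0.6,
    **kwargs,
) -> PlantedSpec:
    """Draw a generic planted spec with equal block sizes.

    Equal sizes make the divisibility constraint automatic; the D matrix
    is resampled until the block profiles are pairwise distinct (generic),
    so the planted partition is recoverable in principle.
    """
    sizes = (block_size,) * k
    for _ in range(1000):
        D = rng.integers(1, max_weight + 1, size=(k, k))
        D[rng.random(size=(k, k)) > density] = 0
        spec = PlantedSpec(sizes, tuple(map(tuple, D)), **kwargs)
        if spec.is_generic():
            return spec
    raise RuntimeError("failed to draw a generic planted spec")
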