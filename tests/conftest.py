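from __future__ import annotations

import numpy as np
import pytest

from conntype import (
    Labeling,
    PlantedSpec,
    WeightedDigraph,
    generate_planted,
    random_spec,
)


@pytest.fixture
def triangle():
    """3-cycle with distinct weights: 1->2 (w2), 2->3 (w1), 3->1 (w4)."""
    return WeightedDigraph.from_edges(
        [("1", "2", 2), ("2", "3", 1), ("3", "1", 4)]
    )


@pytest.fixture
def four_cycle():
    """Directed 4-cycle with unit weights."""
    return WeightedDigraph.from_edges(
        [("1", "2", 1), ("2", "3", 1), ("3", "4", 1), ("4", "1", 1)]
    )


@pytest.fixture
def star():
    """One center sending unit edges to 3 leaves."""
    return WeightedDigraph.from_edges(
        [("c", "l1", 1), ("c", "l2", 1), ("c", "l3", 1)]
    )


@pytest.fixture
def bipartite_pairs():
    """A1,A2 each sending unit edges to B1,B2 (complete bipartite)."""
    g = WeightedDigraph.from_edges(
        [("A1", "B1", 1), ("A1", "B2", 1), ("A2", "B1", 1), ("A2", "B2", 1)]
    )
    seeds = Labeling({"A1": "X", "B1": "Y"}, seed_set={"A1", "B1"})
    truth = Labeling({"A1": "X", "A2": "X", "B1": "Y", "B2": "Y"})
    return g, seeds, truth


@pytest.fixture
def planted8():
    """The 8-node planted 2-block fixture: sizes (4,4), D=[[0,2],[1,0]]."""
    spec = PlantedSpec((4, 4), ((0, 2), (1, 0)))
    graph, truth = generate_planted(spec)
    return spec, graph, truth


def random_digraph(rng: np.random.Generator, n: int, p: float = 0.35,
                   max_w: int = 3) -> WeightedDigraph:
    """Random integer-weighted digraph on node ids v0..v{n-1}."""
    names = [f"v{i}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < p:
                edges.append((names[i], names[j],
                              float(rng.integers(1, max_w + 1))))
    return WeightedDigraph.from_edges(edges, extra_nodes=names)


def planted_graph(seed: int, k: int, block_size: int, **kwargs):
    """A generic planted graph drawn from the given seed."""
    rng = np.random.default_rng(seed)
    spec = random_spec(k, block_size, rng, **kwargs)
    return generate_planted(spec)


def one_seed_per_block(graph, truth) -> Labeling:
    """The first member of each ground-truth block, as seeds."""
    seed_nodes = {graph.nodes[c[0]] for c in truth.clusters(graph)}
    return Labeling(
        {u: truth.assignment[u] for u in seed_nodes},
        seed_set=seed_nodes,
        label_universe=truth.label_universe,
    )
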