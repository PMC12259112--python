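from __future__ import annotations

import numpy as np
import pytest

from conntype import (
    Labeling,
    UnseededConfig,
    WeightedDigraph,
    best_representatives,
    candidate_pool,
    compute_embeddings,
    match_clusters,
    partition_cost,
    select_next_seed,
    unseeded_ntac,
)

from conftest import planted_graph
from oracles import all_bipartitions


class TestUnseededNtac:
    def test_k1_is_trivial_partition(self, triangle):
        result = unseeded_ntac(triangle, UnseededConfig(k=1))
        assert result.final.k == 1
        assert result.final_cost == pytest.approx(13 / 12)

    def test_planted_two_block_fixture_problem_certificate(self, planted8):
        # exhaustive search over all 127 bipartitions: the planted one is
        # the unique 2-cluster partition of cost 0
        _, graph, truth = planted8
        zero_cost = []
        names = graph.nodes
        for blocks in all_bipartitions(graph.n):
            part = Labeling.from_indices(
                graph,
                np.array(
                    [0 if i in set(blocks[0]) else 1 for i in range(graph.n)]
                ),
                ["p", "q"],
            )
            if partition_cost(graph, part).total == 0.0:
                zero_cost.append(
                    frozenset(frozenset(names[i] for i in b) for b in blocks)
                )
        truth_blocks = frozenset(
            frozenset(u for u in names if truth.assignment[u] == lab)
            for lab in truth.label_universe
        )
        assert zero_cost == [truth_blocks]

    def test_complete_digraph_best_is_single_zero_cost_cluster(self):
        nodes = [f"v{i}" for i in range(6)]
        edges = [
            (u, v, 1.0) for u in nodes for v in nodes if u != v
        ]
        g = WeightedDigraph.from_edges(edges)
        result = unseeded_ntac(g, UnseededConfig(k=3, return_best=True))
        assert result.best is not None
        assert result.best.k == 1
        assert result.best_cost == 0.0

    def test_recovers_planted_blocks(self):
        graph, truth = planted_graph(101, k=4, block_size=30)
        result = unseeded_ntac(graph, UnseededConfig(k=4))
        match = match_clusters(result.best, truth)
        assert match.matched_accuracy == 1.0
        assert result.best_cost == 0.0

    def test_trace_has_l_nonempty_clusters_at_step_l(self):
        graph, truth = planted_graph(102, k=4, block_size=20)
        result = unseeded_ntac(graph, UnseededConfig(k=4))
        for step, rec in enumerate(result.trace, start=1):
            assert rec.n_clusters == step
            counts = [
                len(c) for c in rec.labeling.clusters(graph)
            ]
            assert all(c > 0 for c in counts)
            assert len(counts) == step
            assert len(rec.seeds) == step
            assert len(set(rec.seeds)) == step  # seeds distinct

    def test_return_best_is_min_over_trace(self):
        graph, truth = planted_graph(103, k=5, block_size=16)
        result = unseeded_ntac(graph, UnseededConfig(k=5))
        best = min(rec.cost for rec in result.trace)
        assert result.best_cost == best
        assert partition_cost(graph, result.best).total == pytest.approx(best)

    def test_fully_deterministic(self):
        graph, truth = planted_graph(104, k=3, block_size=15)
        r1 = unseeded_ntac(graph, UnseededConfig(k=3))
        r2 = unseeded_ntac(graph, UnseededConfig(k=3))
        assert r1.final.assignment == r2.final.assignment
        assert [rec.cost for rec in r1.trace] == [rec.cost for rec in r2.trace]

    def test_k_exceeding_n_rejected(self, triangle):
        with pytest.raises(ValueError):
            unseeded_ntac(triangle, UnseededConfig(k=4))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            UnseededConfig(k=0)
        with pytest.raises(ValueError):
            UnseededConfig(k=2, T=1.5)
        with pytest.raises(ValueError):
            UnseededConfig(k=2, R=0)
        with pytest.raises(ValueError):
            UnseededConfig(k=2, centroid_method="mode")


class TestSelectNextSeed:
    def test_all_zero_scores_returns_first_nonseed(self, four_cycle):
        part = Labeling({u: "a" for u in four_cycle.nodes})
        # equitable: every node's embedding equals the median
        chosen = select_next_seed(four_cycle, part, seeds=["1"])
        assert chosen == "2"

    def test_outlier_scores_highest(self):
        # one cluster, embeddings [1,0],[1,0],[0,1]: the outlier has
        # score 1, the others 0 (hand evaluation of the score sum)
        g = WeightedDigraph.from_edges(
            [("n1", "a", 1), ("n2", "a", 1), ("b", "n3", 1)],
            extra_nodes=[],
        )
        # cluster under test = {n1, n2, n3}; helpers a, b form their own
        # clusters so they do not disturb the embeddings of interest
        part = Labeling(
            {"n1": "c", "n2": "c", "n3": "c", "a": "x", "b": "y"}
        )
        chosen = select_next_seed(g, part, seeds=["n1"])
        assert chosen == "n3"

    def test_pool_of_one_returns_that_node(self):
        graph, truth = planted_graph(105, k=3, block_size=10)
        part = Labeling({u: "all" for u in graph.nodes})
        pool = candidate_pool(graph, part, T=1 / graph.n)
        assert len(pool) == 1
        assert select_next_seed(graph, part, seeds=[], T=1 / graph.n) == pool[0]

    def test_empty_candidate_pool_is_an_error(self, triangle):
        part = Labeling({u: "a" for u in triangle.nodes})
        with pytest.raises(ValueError):
            select_next_seed(
                triangle, part, seeds=["1", "2", "3"], T=1 / 3
            )


class TestCandidatePool:
    def test_full_pool_contains_all_nodes(self, triangle):
        part = Labeling({u: "a" for u in triangle.nodes})
        pool = candidate_pool(triangle, part, T=1.0)
        assert sorted(pool) == sorted(triangle.nodes)

    def test_round_robin_over_clusters(self):
        # clusters of sizes (3, 1); a pool of 4 interleaves:
        # farthest of C1, the only member of C2, then 2nd and 3rd of C1
        g = WeightedDigraph.from_edges(
            [("u1", "z", 1), ("u2", "z", 2), ("u3", "z", 8)],
            extra_nodes=[],
        )
        part = Labeling({"u1": "c1", "u2": "c1", "u3": "c1", "z": "c2"})
        pool = candidate_pool(g, part, T=1.0)
        # C1 out-weights to c2: 1, 2, 8; median 2 -> distances to the
        # median are 0.5, 0, 0.75: farthest u3, then u1, then u2
        assert pool == ["u3", "z", "u1", "u2"]

    def test_equidistant_members_fall_back_to_node_order(self, four_cycle):
        part = Labeling({u: "a" for u in four_cycle.nodes})
        pool = candidate_pool(four_cycle, part, T=1.0)
        assert pool == four_cycle.nodes

    def test_pool_size_is_ceil_T_n(self):
        graph, _ = planted_graph(106, k=3, block_size=10)
        for T in (0.1, 0.34, 0.5, 1.0):
            part = Labeling({u: "all" for u in graph.nodes})
            pool = candidate_pool(graph, part, T=T)
            assert len(pool) == int(np.ceil(T * graph.n))


class TestBestRepresentatives:
    def test_singleton_cluster_returns_its_member(self, star):
        part = Labeling(
            {"c": "hub", "l1": "leaf", "l2": "leaf", "l3": "leaf"}
        )
        reps = best_representatives(star, part)
        assert "c" in reps

    def test_outlier_cluster_picks_majority_embedding(self):
        # embeddings {[1,0],[1,0],[0,9]} -> distances to median [1,0]
        # are 0, 0, 1; the first majority node wins
        g = WeightedDigraph.from_edges(
            [("n1", "a", 1), ("n2", "a", 1), ("n3", "b", 9)]
        )
        part = Labeling(
            {"n1": "c", "n2": "c", "n3": "c", "a": "x", "b": "y"}
        )
        reps = best_representatives(g, part)
        assert reps[part.label_universe.index("c")] == "n1"

    def test_equitable_cluster_ties_to_lowest_order(self, four_cycle):
        part = Labeling({u: "a" for u in four_cycle.nodes})
        assert best_representatives(four_cycle, part) == ["1"]

    def test_first_seed_is_node_nearest_global_median(self, triangle):
        part = Labeling({u: "a" for u in triangle.nodes})
        # embeddings [2,4],[1,2],[4,1]; median [2,2];
        # distances 1/3, 1/4, 1/2 -> node 2
        assert best_representatives(triangle, part) == ["2"]

    def test_empty_cluster_is_an_error(self, triangle):
        part = Labeling(
            {u: "a" for u in triangle.nodes}, label_universe=("a", "ghost")
        )
        with pytest.raises(ValueError):
            best_representatives(triangle, part)


class TestPoolRestrictionFidelity:
    def test_small_T_matches_full_T_accuracy(self):
        diffs = []
        for seed in (110, 111, 112):
            graph, truth = planted_graph(seed, k=4, block_size=20)
            accs = {}
            for T in (0.5, 1.0):
                res = unseeded_ntac(graph, UnseededConfig(k=4, T=T))
                accs[T] = match_clusters(res.best, truth).matched_accuracy
            diffs.append(abs(accs[0.5] - accs[1.0]))
        assert np.mean(diffs) < 0.05
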