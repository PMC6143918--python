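import math
from itertools import combinations

import pytest

from modrec.benchmarks import planted_partition
from modrec.errors import ValidationError
from modrec.graph import WeightedGraph
from modrec.louvain import (
    Partition,
    aggregate,
    local_move_phase,
    louvain,
    modularity,
)

from ._oracles import max_modularity_exhaustive, modularity_direct
from .conftest import clique


class TestPartition:
    def test_singletons(self, triangle):
        p = Partition.singletons(triangle.nodes)
        assert p.number_of_blocks() == 3

    def test_from_blocks_rejects_overlap(self):
        with pytest.raises(ValidationError):
            Partition.from_blocks([{"a", "b"}, {"b", "c"}])

    def test_equality_up_to_relabeling(self):
        p = Partition({"a": 1, "b": 1, "c": 2})
        q = Partition({"a": "x", "b": "x", "c": "y"})
        assert p == q

    def test_validate_for_mismatch(self, triangle):
        with pytest.raises(ValidationError):
            Partition({"a": 0, "b": 0}).validate_for(triangle)


class TestModularity:
    def test_all_in_one_is_zero(self, barbell):
        p = Partition({v: 0 for v in barbell.nodes})
        assert modularity(barbell, p) == pytest.approx(0.0, abs=1e-12)

    def test_two_disjoint_cliques_half(self, two_triangles):
        p = Partition.from_blocks([{"a", "b", "c"}, {"d", "e", "f"}])
        assert modularity(two_triangles, p) == pytest.approx(0.5, abs=1e-12)

    def test_triangle_singletons_minus_third(self, triangle):
        p = Partition.singletons(triangle.nodes)
        assert modularity(triangle, p) == pytest.approx(-1.0 / 3.0, abs=1e-12)

    def test_matches_direct_formula_on_weighted_graph(self):
        g = WeightedGraph()
        g.add_edge("a", "b", 0.4)
        g.add_edge("b", "c", 0.9)
        g.add_edge("c", "d", 0.1)
        g.add_edge("a", "d", 0.7)
        g.add_edge("b", "b", 0.25)
        blocks = [{"a", "b"}, {"c", "d"}]
        p = Partition.from_blocks(blocks)
        assert modularity(g, p) == pytest.approx(
            modularity_direct(g, blocks), abs=1e-12
        )

    def test_matches_networkx(self):
        nx = pytest.importorskip("networkx")
        net = planted_partition([6, 6, 6], 0.8, 0.1, 0.3, 1.0, seed=4)
        g = net.graph
        gx = nx.Graph()
        gx.add_nodes_from(g.nodes)
        for u, v, w in g.edges():
            gx.add_edge(u, v, weight=w)
        blocks = [set(b) for b in net.truth.block_list()]
        expected = nx.algorithms.community.modularity(gx, blocks, weight="weight")
        assert modularity(g, net.truth) == pytest.approx(expected, abs=1e-10)

    def test_zero_weight_graph_rejected(self):
        g = WeightedGraph()
        g.add_node("a")
        with pytest.raises(ValidationError):
            modularity(g, Partition.singletons({"a"}))

    def test_range(self, barbell):
        for blocks in ([{v} for v in barbell.nodes], [set(barbell.nodes)]):
            q = modularity(barbell, Partition.from_blocks(blocks))
            assert -1.0 <= q <= 1.0


class TestLocalMovePhase:
    def test_barbell_from_singletons_reaches_cliques(self, barbell):
        p = local_move_phase(barbell, Partition.singletons(barbell.nodes), rng_seed=0)
        assert p == Partition.from_blocks([set("abcd"), set("efgh")])

    def test_local_optimum_unchanged(self, two_triangles):
        p_opt = Partition.from_blocks([{"a", "b", "c"}, {"d", "e", "f"}])
        assert local_move_phase(two_triangles, p_opt, rng_seed=1) == p_opt

    def test_single_edge_merges(self):
        g = WeightedGraph()
        g.add_edge("a", "b", 1.0)
        p = local_move_phase(g, Partition.singletons(g.nodes), rng_seed=0)
        assert p.number_of_blocks() == 1
        # oracle: merged Q = 0 beats split Q = -1/2
        assert modularity(g, p) == pytest.approx(0.0, abs=1e-12)

    def test_never_decreases_q(self, barbell):
        for seed in range(5):
            init = Partition.singletons(barbell.nodes)
            q0 = modularity(barbell, init)
            out = local_move_phase(barbell, init, rng_seed=seed)
            assert modularity(barbell, out) >= q0 - 1e-12

    def test_incremental_q_matches_recompute(self):
        net = planted_partition([10, 10, 10], 0.7, 0.1, 0.2, 1.0, seed=7)
        g = net.graph
        checks = []

        def on_move(graph, labels, q_tracked):
            q_true = modularity(graph, Partition(labels))
            checks.append(abs(q_tracked - q_true))

        local_move_phase(g, Partition.singletons(g.nodes), rng_seed=3, on_move=on_move)
        assert checks, "expected at least one accepted move"
        assert max(checks) < 1e-10


class TestAggregate:
    def test_two_triangles(self, two_triangles):
        p = Partition.from_blocks([{"a", "b", "c"}, {"d", "e", "f"}])
        agg, super_of = aggregate(two_triangles, p)
        assert agg.number_of_nodes() == 2
        assert all(agg.self_loop(v) == pytest.approx(3.0) for v in agg.nodes)
        assert sum(1 for u, v, _ in agg.edges() if u != v) == 0

    def test_singleton_partition_identity(self, barbell):
        p = Partition.singletons(barbell.nodes)
        agg, super_of = aggregate(barbell, p)
        assert agg.number_of_nodes() == barbell.number_of_nodes()
        assert agg.total_weight() == pytest.approx(barbell.total_weight(), abs=1e-12)

    def test_barbell_clique_partition(self, barbell):
        p = Partition.from_blocks([set("abcd"), set("efgh")])
        agg, super_of = aggregate(barbell, p)
        assert agg.number_of_nodes() == 2
        u, v = sorted(agg.nodes)
        assert agg.edge_weight(u, v) == pytest.approx(1.0)
        assert agg.self_loop(u) == pytest.approx(6.0)
        assert agg.self_loop(v) == pytest.approx(6.0)

    def test_total_weight_conserved(self):
        net = planted_partition([8, 8], 0.9, 0.2, 0.3, 0.9, seed=2)
        g = net.graph
        agg, _ = aggregate(g, net.truth)
        assert agg.total_weight() == pytest.approx(g.total_weight(), abs=1e-12)
        assert sum(agg.strength(v) for v in agg.nodes) == pytest.approx(
            sum(g.strength(v) for v in g.nodes), abs=1e-10
        )

    def test_modularity_invariant_under_aggregation(self, barbell):
        p = Partition.from_blocks([set("abcd"), set("efgh")])
        agg, super_of = aggregate(barbell, p)
        q_before = modularity(barbell, p)
        q_after = modularity(agg, Partition.singletons(agg.nodes))
        assert q_after == pytest.approx(q_before, abs=1e-12)


class TestLouvain:
    def test_barbell_reaches_exhaustive_optimum(self, barbell):
        q_max, blocks = max_modularity_exhaustive(barbell)
        result = louvain(barbell, rng_seed=11)
        assert result == Partition.from_blocks(blocks)
        assert modularity(barbell, result) == pytest.approx(q_max, abs=1e-12)

    def test_k5_single_community(self, k5):
        q_max, _ = max_modularity_exhaustive(k5)
        assert q_max == pytest.approx(0.0, abs=1e-12)
        result = louvain(k5, rng_seed=2)
        assert result.number_of_blocks() == 1

    def test_init_at_optimum_unchanged(self, two_triangles):
        init = Partition.from_blocks([{"a", "b", "c"}, {"d", "e", "f"}])
        assert louvain(two_triangles, init, rng_seed=0) == init

    def test_q_never_below_init(self):
        for seed in range(5):
            net = planted_partition([8, 8, 8], 0.8, 0.15, 0.4, 1.0, seed=seed)
            g = net.graph
            init = Partition.singletons(g.nodes)
            q0 = modularity(g, init)
            out = louvain(g, init, rng_seed=seed)
            assert modularity(g, out) >= q0 - 1e-12

    def test_never_beats_exhaustive_on_small_graphs(self):
        for seed in range(3):
            net = planted_partition([4, 4], 0.9, 0.2, 0.5, 1.0, seed=seed)
            g = net.graph
            if g.total_weight() == 0:
                continue
            q_max, _ = max_modularity_exhaustive(g)
            out = louvain(g, rng_seed=seed)
            assert modularity(g, out) <= q_max + 1e-12

    def test_deterministic_given_seed(self):
        net = planted_partition([10, 10, 10], 0.6, 0.1, 0.2, 1.0, seed=9)
        a = louvain(net.graph, rng_seed=42)
        b = louvain(net.graph, rng_seed=42)
        assert a == b

    def test_respects_initial_partition(self, barbell):
        # a seed that already groups the cliques survives verbatim
        init = Partition.from_blocks([set("abcd"), set("efgh")])
        assert louvain(barbell, init, rng_seed=5) == init

    def test_zero_weight_rejected(self):
        g = WeightedGraph()
        g.add_node("a")
        with pytest.raises(ValidationError):
            louvain(g, rng_seed=0)

    def test_weighted_two_cliques_with_weak_bridge(self):
        g = clique(["a", "b", "c"], weight=1.0)
        for u, v in combinations(["d", "e", "f"], 2):
            g.add_edge(u, v, 1.0)
        g.add_edge("c", "d", 0.05)
        result = louvain(g, rng_seed=1)
        assert result == Partition.from_blocks([{"a", "b", "c"}, {"d", "e", "f"}])
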