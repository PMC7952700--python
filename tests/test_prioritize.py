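"""Shortest-path and random-walk scoring, rank combination, expansion."""

import itertools

import numpy as np
import pytest

from prynt import (ConsistencyError, ConvergenceError, DPSet, EmptySeedError,
                   RWScore, SPScore, assign_disjoint_cliques, build_variant,
                   collapse_cliques, combine_ranks, direct_scores,
                   expand_cliques, prioritize, random_walk_scores,
                   random_walk_scores_closed_form, shortest_path_scores,
                   shortest_path_scores_bruteforce)
from conftest import make_net, random_net, random_seed_set


class TestShortestPath:
    def test_reciprocal_summed_distance(self):
        net = make_net([("X", "A"), ("A", "Y1"), ("X", "Y2")])
        dps = DPSet("d", frozenset({"Y1", "Y2"}))
        scores = {s.node: s for s in shortest_path_scores(net, dps)}
        assert scores["X"].sp == pytest.approx(1 / 3)
        assert scores["X"].reachable_dp_count == 2

    def test_adjacent_to_single_seed(self):
        net = make_net([("X", "Y")])
        scores = shortest_path_scores(net, DPSet("d", frozenset({"Y"})))
        assert scores == [SPScore(node="X", sp=1.0, reachable_dp_count=1)]

    def test_direction_is_candidate_to_seed(self):
        net = make_net([("Y", "X")])  # only seed -> candidate
        scores = shortest_path_scores(net, DPSet("d", frozenset({"Y"})))
        assert scores[0].sp == 0.0
        assert scores[0].reachable_dp_count == 0

    def test_matches_per_pair_bfs_oracle(self, rng):
        for _ in range(30):
            net = random_net(int(rng.integers(5, 51)), 0.1, rng)
            dps = random_seed_set(net, rng)
            assert shortest_path_scores(net, dps) == \
                shortest_path_scores_bruteforce(net, dps)

    def test_penalty_policy_charges_node_count(self):
        net = make_net([("X", "Y1")], nodes=["Y2"])
        dps = DPSet("d", frozenset({"Y1", "Y2"}))
        scores = {s.node: s for s in
                  shortest_path_scores(net, dps, unreachable="penalty")}
        assert scores["X"].sp == pytest.approx(1 / (1 + net.n_nodes))

    def test_no_seed_in_network_raises(self):
        net = make_net([("A", "B")])
        with pytest.raises(EmptySeedError):
            shortest_path_scores(net, DPSet("d", frozenset({"Z"})))

    def test_added_shortcut_never_worsens_any_candidate(self, rng):
        # monotonicity in the count-then-score order: a new edge onto a
        # seed can only shrink distances or open new seeds, never demote
        net = random_net(20, 0.1, rng)
        dps = random_seed_set(net, rng, k=3)
        before = {s.node: s for s in shortest_path_scores(net, dps)}
        seed = sorted(dps.members)[0]
        candidate = sorted(net.nodes - dps.members)[0]
        net.graph.add_edge(candidate, seed, score=950, contextual=False)
        after = {s.node: s for s in shortest_path_scores(net, dps)}
        for node, prev in before.items():
            new = after[node]
            assert new.reachable_dp_count >= prev.reachable_dp_count
            if new.reachable_dp_count == prev.reachable_dp_count:
                assert new.sp >= prev.sp - 1e-12


class TestRandomWalk:
    def test_restart_one_returns_seed_distribution(self, rng):
        net = random_net(10, 0.3, rng)
        dps = random_seed_set(net, rng, k=2)
        scores = {s.node: s.rw for s in random_walk_scores(net, dps, r=1.0)}
        for node, value in scores.items():
            expected = 1 / 2 if node in dps.members else 0.0
            assert value == pytest.approx(expected, abs=1e-15)

    def test_two_node_chain_closed_form(self):
        # A -> B, seed {A}, r = 0.7: p_A = 0.7, p_B = 0.3 * 0.7 = 0.21
        net = make_net([("A", "B")])
        dps = DPSet("d", frozenset({"A"}))
        iterated = {s.node: s.rw for s in random_walk_scores(net, dps, r=0.7)}
        assert iterated["A"] == pytest.approx(0.7, abs=1e-8)
        assert iterated["B"] == pytest.approx(0.21, abs=1e-8)

    def test_iteration_matches_linear_solve(self, rng):
        for _ in range(30):
            net = random_net(int(rng.integers(3, 21)), 0.25, rng)
            dps = random_seed_set(net, rng)
            iterated = {s.node: s.rw for s in random_walk_scores(net, dps)}
            solved = {s.node: s.rw
                      for s in random_walk_scores_closed_form(net, dps)}
            for node in iterated:
                assert iterated[node] == pytest.approx(solved[node],
                                                       abs=1e-7)

    def test_probability_conserved_without_dangling_nodes(self, rng):
        # cycle guarantees out-degree >= 1 everywhere
        net = random_net(15, 0.2, rng)
        nodes = sorted(net.nodes)
        for a, b in zip(nodes, nodes[1:] + nodes[:1]):
            net.graph.add_edge(a, b, score=950, contextual=False)
        dps = random_seed_set(net, rng, k=3)
        scores = random_walk_scores(net, dps)
        assert sum(s.rw for s in scores) == pytest.approx(1.0, abs=1e-9)

    def test_dangling_restart_policy_restores_mass(self):
        net = make_net([("A", "B")])  # B dangles
        dps = DPSet("d", frozenset({"A"}))
        scores = random_walk_scores(net, dps, dangling="restart")
        assert sum(s.rw for s in scores) == pytest.approx(1.0, abs=1e-9)

    def test_non_convergence_reports_residual(self):
        net = make_net([("A", "B"), ("B", "A")])
        dps = DPSet("d", frozenset({"A"}))
        with pytest.raises(ConvergenceError) as excinfo:
            random_walk_scores(net, dps, tol=1e-12, max_iter=2)
        assert excinfo.value.residual > 0

    def test_invalid_restart_probability(self):
        net = make_net([("A", "B")])
        with pytest.raises(ValueError):
            random_walk_scores(net, DPSet("d", frozenset({"A"})), r=0.0)


def _rw(node, value):
    return RWScore(node=node, rw=value, iterations=1, residual=0.0)


def _sp(node, value, count=1):
    return SPScore(node=node, sp=value, reachable_dp_count=count)


class TestCombineRanks:
    def test_combined_score_is_rank_product(self):
        result = combine_ranks(
            [_sp("P", 0.5), _sp("Q", 1.0), _sp("R", 0.25)],
            [_rw("P", 0.1), _rw("Q", 0.05), _rw("R", 0.2)],
        )
        by_node = {rec.node: rec for rec in result.records}
        assert by_node["P"].cs == by_node["P"].rank_sp * by_node["P"].rank_rw
        assert by_node["P"].rank_sp == 2 and by_node["P"].rank_rw == 2
        assert by_node["Q"].cs == 1 * 3

    def test_double_winner_ranks_first(self):
        result = combine_ranks([_sp("P", 1.0), _sp("Q", 0.5)],
                               [_rw("P", 0.2), _rw("Q", 0.1)])
        assert result.records[0].node == "P"
        assert result.records[0].cs == 1
        assert result.records[0].final_rank == 1

    def test_final_order_matches_sorted_products(self, rng):
        nodes = [f"C{i}" for i in range(8)]
        sp_ranks = rng.permutation(8) + 1
        rw_ranks = rng.permutation(8) + 1
        sp_scores = [_sp(n, 1.0 / sp_ranks[i]) for i, n in enumerate(nodes)]
        rw_scores = [_rw(n, 1.0 / rw_ranks[i]) for i, n in enumerate(nodes)]
        result = combine_ranks(sp_scores, rw_scores)
        oracle = sorted(nodes,
                        key=lambda n: (sp_ranks[nodes.index(n)]
                                       * rw_ranks[nodes.index(n)], n))
        assert result.nodes() == oracle

    def test_ties_share_better_rank(self):
        result = combine_ranks([_sp("P", 1.0), _sp("Q", 1.0), _sp("R", 0.5)],
                               [_rw("P", 0.3), _rw("Q", 0.2), _rw("R", 0.1)])
        by_node = {rec.node: rec for rec in result.records}
        assert by_node["P"].rank_sp == by_node["Q"].rank_sp == 1
        assert by_node["R"].rank_sp == 3

    def test_candidate_mismatch_is_error(self):
        with pytest.raises(ConsistencyError):
            combine_ranks([_sp("P", 1.0)], [_rw("Q", 0.1)])


class TestExpandCliques:
    def test_representative_is_best_ranked_member(self):
        collapsed_net = make_net([("A", "G")])
        partition = assign_disjoint_cliques([frozenset("PQ")],
                                            min_clique_size=2)
        gid = next(iter(partition.groups))
        collapsed = combine_ranks(
            [_sp("A", 1.0), _sp(gid, 0.5)],
            [_rw("A", 0.2), _rw(gid, 0.1)],
        )
        raw = combine_ranks(
            [_sp("A", 1.0), _sp("P", 0.2), _sp("Q", 0.6)],
            [_rw("A", 0.3), _rw("P", 0.01), _rw("Q", 0.2)],
        )
        expanded = expand_cliques(collapsed, partition, raw)
        nodes = expanded.nodes()
        assert "Q" in nodes and "P" not in nodes
        assert [rec.final_rank for rec in expanded.records] == [1, 2]

    def test_no_groups_is_identity(self):
        result = combine_ranks([_sp("A", 1.0)], [_rw("A", 0.1)])
        partition = assign_disjoint_cliques([], min_clique_size=3)
        assert expand_cliques(result, partition, result).nodes() == ["A"]

    def test_output_length_counts(self, rng):
        net = random_net(30, 0.35, rng)
        dps = random_seed_set(net, rng, k=3)
        built = build_variant(
            "c",
            [  # re-express the graph as interaction records
                __import__("prynt").RawInteraction(
                    source_id=u, target_id=v, is_directional=True,
                    a_is_acting=True, score=950)
                for u, v in sorted(net.edge_set())
            ],
            dps,
        )
        result = prioritize(built, dps)
        partition = built.partition
        n_candidates_collapsed = built.network.n_nodes - len(
            dps.members & built.network.nodes)
        assert len(result) == n_candidates_collapsed

    def test_seed_exclusion_everywhere(self, rng):
        net = random_net(25, 0.25, rng)
        dps = random_seed_set(net, rng, k=4)
        from prynt import RawInteraction
        interactions = [
            RawInteraction(source_id=u, target_id=v, is_directional=True,
                           a_is_acting=True, score=950)
            for u, v in sorted(net.edge_set())
        ]
        for variant in ("raw", "dp", "c", "dp_c"):
            built = build_variant(variant, interactions, dps)
            result = prioritize(built, dps)
            assert not set(result.nodes()) & dps.members
            ranks = [rec.final_rank for rec in result.records]
            assert ranks == list(range(1, len(result) + 1))
            for rec in result.records:
                assert rec.cs == rec.rank_sp * rec.rank_rw


class TestDirectBaseline:
    def test_counts_seed_out_neighbours(self):
        edges = [("X", f"Y{i}") for i in range(3)] + [("X", "Z")]
        net = make_net(edges, nodes=["Y3", "Y4"])
        dps = DPSet("d", frozenset({f"Y{i}" for i in range(5)}))
        scores = {s.node: s.direct for s in direct_scores(net, dps)}
        assert scores["X"] == 3
        assert scores["Z"] == 0

    def test_ranking_matches_neighbour_count_oracle(self, rng):
        net = random_net(20, 0.2, rng)
        dps = random_seed_set(net, rng, k=4)
        scores = direct_scores(net, dps)
        oracle = {
            n: sum(1 for v in net.graph.successors(n) if v in dps.members)
            for n in net.nodes - dps.members
        }
        for entry in scores:
            assert entry.direct == oracle[entry.node]
            assert entry.rank == 1 + sum(
                1 for v in oracle.values() if v > entry.direct)
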