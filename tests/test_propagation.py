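import math

import networkx as nx
import numpy as np
import pytest

from netprio.exceptions import ConvergenceError, ValidationError
from netprio.interactome import Interactome, transition_matrix
from netprio.propagation import (
    SeedSet,
    degree_adjusted_scores,
    leave_one_out_control,
    prioritize,
    rank_candidates,
    reference_distribution,
    rwr,
)

from conftest import random_connected, star


def linear_solve_rwr(net, seeds, restart):
    """Independent oracle: p = r (I - (1-r) W)^{-1} s by direct solve."""
    w, nodes = transition_matrix(net)
    s = np.zeros(len(nodes))
    for g in seeds:
        s[nodes.index(g)] = 1.0 / len(seeds)
    a = np.eye(len(nodes)) - (1.0 - restart) * w.toarray()
    p = restart * np.linalg.solve(a, s)
    return dict(zip(nodes, p))


class TestRwr:
    def test_restart_one_returns_seed_distribution(self, triangle):
        p = rwr(triangle, ["A", "B"], restart=1.0)
        assert p == {"A": 0.5, "B": 0.5, "C": 0.0}

    def test_regular_graph_all_seeds_uniform(self):
        net = Interactome.from_edges(
            (f"N{u}", f"N{v}") for u, v in nx.cycle_graph(8).edges
        )
        p = rwr(net, net.nodes, restart=0.5)
        assert all(abs(v - 1 / 8) < 1e-12 for v in p.values())

    @pytest.mark.parametrize("seed", range(4))
    @pytest.mark.parametrize("restart", [0.3, 0.7])
    def test_matches_linear_solve_oracle(self, seed, restart):
        net = random_connected(50, 0.12, seed)
        rng = np.random.default_rng(seed)
        seeds = [net.nodes[i] for i in rng.choice(net.n_nodes, 5, replace=False)]
        p = rwr(net, seeds, restart=restart)
        oracle = linear_solve_rwr(net, seeds, restart)
        assert max(abs(p[g] - oracle[g]) for g in p) < 1e-8

    def test_probabilities_sum_to_one(self):
        net = random_connected(30, 0.2, 7)
        p = rwr(net, [net.nodes[0]], restart=0.7)
        assert sum(p.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for v in p.values())

    def test_absent_seeds_dropped_with_warning(self, triangle, caplog):
        with caplog.at_level("WARNING"):
            p = rwr(triangle, ["A", "NOT_THERE"], restart=1.0)
        assert p["A"] == 1.0
        assert "dropped" in caplog.text

    def test_no_seed_overlap_rejected(self, triangle):
        with pytest.raises(ValidationError, match="no seed"):
            rwr(triangle, ["X", "Y"])

    def test_non_convergence_raises_with_residual(self):
        net = random_connected(50, 0.12, 3)
        with pytest.raises(ConvergenceError) as err:
            rwr(net, [net.nodes[0]], restart=0.05, tol=1e-14, max_iter=2)
        assert err.value.residual is not None

    def test_invalid_restart_rejected(self, triangle):
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(ValidationError):
                rwr(triangle, ["A"], restart=bad)

    def test_permutation_equivariance(self):
        net = random_connected(25, 0.2, 11)
        relabel = {g: f"X{g}" for g in net.nodes}
        relabeled = Interactome(nx.relabel_nodes(net.graph, relabel))
        seeds = net.nodes[:3]
        p = rwr(net, seeds, restart=0.6)
        q = rwr(relabeled, [relabel[g] for g in seeds], restart=0.6)
        assert all(abs(p[g] - q[relabel[g]]) < 1e-12 for g in p)

    def test_edge_to_seed_increases_probability(self):
        # adding an edge from a non-seed to the seed raises its visitation
        base = Interactome.from_edges([("S", "A"), ("A", "B"), ("B", "C")])
        more = Interactome.from_edges(
            [("S", "A"), ("A", "B"), ("B", "C"), ("C", "S")]
        )
        p0 = rwr(base, ["S"], restart=0.7)
        p1 = rwr(more, ["S"], restart=0.7)
        assert p1["C"] > p0["C"]


class TestReferenceDistribution:
    def test_regular_graph_uniform(self):
        net = Interactome.from_edges(
            (f"N{u}", f"N{v}") for u, v in nx.cycle_graph(6).edges
        )
        ref = reference_distribution(net, restart=0.4)
        assert all(abs(v - 1 / 6) < 1e-12 for v in ref.values())

    def test_star_hub_exceeds_leaves(self):
        net = star(6)
        ref = reference_distribution(net, restart=0.5)
        assert all(ref["HUB"] > ref[f"L{i}"] for i in range(6))

    def test_restart_one_uniform(self):
        net = star(4)
        ref = reference_distribution(net, restart=1.0)
        assert all(v == pytest.approx(1 / 5) for v in ref.values())


class TestDegreeAdjustedScores:
    def test_identity_gives_zero(self):
        p = {"A": 0.3, "B": 0.7}
        assert degree_adjusted_scores(p, p) == {"A": 0.0, "B": 0.0}

    def test_doubling_probability_adds_log_two(self):
        ref = {"A": 0.25, "B": 0.75}
        s1 = degree_adjusted_scores({"A": 0.2, "B": 0.8}, ref)
        s2 = degree_adjusted_scores({"A": 0.4, "B": 0.6}, ref)
        assert s2["A"] - s1["A"] == pytest.approx(math.log(2))

    def test_mismatched_keys_rejected(self):
        with pytest.raises(ValidationError):
            degree_adjusted_scores({"A": 1.0}, {"B": 1.0})

    def test_zero_reference_rejected(self):
        with pytest.raises(ValidationError):
            degree_adjusted_scores({"A": 1.0}, {"A": 0.0})

    def test_star_adjustment_demotes_hub(self):
        # one leaf seed: raw probability favors the hub over other leaves;
        # the adjusted score strips that degree advantage
        net = star(8)
        p = rwr(net, ["L0"], restart=0.6)
        ref = reference_distribution(net, restart=0.6)
        adj = degree_adjusted_scores(p, ref)
        others = [f"L{i}" for i in range(1, 8)]
        raw_margin = math.log(p["HUB"]) - max(math.log(p[g]) for g in others)
        adj_margin = adj["HUB"] - max(adj[g] for g in others)
        assert raw_margin > 0  # hub dominates raw visitation
        # adjustment subtracts the hub's reference advantage, shrinking the gap
        assert adj_margin < raw_margin


class TestRankCandidates:
    def test_descending_scores(self):
        ranking, _ = rank_candidates({"A": 2, "B": 5, "C": 1}, {"A", "B", "C"}, [])
        assert ranking == [("B", 1), ("A", 2), ("C", 3)]

    def test_seed_excluded(self):
        ranking, _ = rank_candidates({"A": 2, "B": 5}, {"A", "B"}, ["B"])
        assert ranking == [("A", 1)]

    def test_tie_breaks_lexicographically(self):
        ranking, _ = rank_candidates({"B": 1, "A": 1}, {"A", "B"}, [])
        assert ranking == [("A", 1), ("B", 2)]

    def test_unrankable_reported(self):
        ranking, unrankable = rank_candidates({"A": 1}, {"A", "GHOST"}, [])
        assert ranking == [("A", 1)] and unrankable == frozenset({"GHOST"})


class TestLeaveOneOut:
    def seeds(self, genes):
        return SeedSet.from_genes(genes)

    def test_heldout_adjacent_to_seeds_ranks_first(self):
        # heldout H touches 3 remaining seeds; decoys sit >=3 hops away
        edges = [
            ("S1", "H"), ("S2", "H"), ("S3", "H"), ("S1", "S2"), ("S2", "S3"),
            ("S3", "A"), ("A", "B"), ("B", "C"), ("C", "D1"), ("C", "D2"),
        ]
        net = Interactome.from_edges(edges)
        result = leave_one_out_control(
            net, self.seeds(["S1", "S2", "S3", "H"]), "H", {"D1", "D2"},
            restart=0.7,
        )
        assert result.rank == 1 and result.n_ranked == 3

    def test_distant_heldout_ranks_behind_adjacent_decoy(self):
        # heldout far down a path; decoy adjacent to the remaining seed
        edges = [("S", "DECOY"), ("S", "A"), ("A", "B"), ("B", "C"), ("C", "H")]
        net = Interactome.from_edges(edges)
        result = leave_one_out_control(
            net, self.seeds(["S", "H"]), "H", {"DECOY"}, restart=0.7
        )
        assert result.rank == 2

    def test_single_seed_neighbor_on_path(self):
        # path D2-D1-S-H: heldout adjacent to the only remaining seed
        net = Interactome.from_edges([("D2", "D1"), ("D1", "S"), ("S", "H")])
        result = leave_one_out_control(
            net, self.seeds(["S", "H"]), "H", {"D1", "D2"}, restart=0.7
        )
        assert result.rank == 1

    def test_non_seed_heldout_rejected(self, triangle):
        with pytest.raises(ValidationError):
            leave_one_out_control(triangle, self.seeds(["A"]), "B", set())


class TestPrioritize:
    def test_result_is_consistent(self):
        net = random_connected(40, 0.15, 2)
        seeds = SeedSet.from_genes(net.nodes[:4])
        candidates = set(net.nodes[10:20])
        result = prioritize(net, seeds, candidates, restart=0.7)
        assert sum(result.probabilities.values()) == pytest.approx(1.0, abs=1e-9)
        ranked_genes = [g for g, _ in result.candidate_ranks]
        assert set(ranked_genes) == candidates - set(seeds.genes)
        ranks = [r for _, r in result.candidate_ranks]
        assert ranks == list(range(1, len(ranks) + 1))
        scores = [result.adjusted_score[g] for g in ranked_genes]
        assert scores == sorted(scores, reverse=True)
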