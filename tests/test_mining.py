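"""Growth, pruning, redundancy filtering and the end-to-end detector."""

from itertools import combinations

import networkx as nx
import pytest

from minecomplex.mining import (
    CandidateComplex,
    MineParams,
    grow_candidate,
    matching_score,
    mine,
    prune_coupling,
    redundancy_filter,
    swd,
    weighted_density,
)
from minecomplex.synthetic import coupling_removal_example
from conftest import random_weighted_graph


def wnet(edges, relation="PPIN"):
    g = nx.Graph(relation=relation)
    for a, b, w in edges:
        g.add_edge(a, b, weight=w)
    return g


def brute_density(members, network):
    """Independent recomputation of weighted density by pair enumeration."""
    members = sorted(members)
    weights = [
        network[u][v]["weight"]
        for u, v in combinations(members, 2)
        if network.has_edge(u, v)
    ]
    if len(members) < 2 or not weights:
        return 0.0
    n = len(members)
    return sum(weights) * 2 / (max(weights) * n * (n - 1))


class TestWeightedDensity:
    def test_single_edge_is_one(self):
        g = wnet([("u", "v", 0.37)])
        assert weighted_density({"u", "v"}, g) == pytest.approx(1.0)

    def test_weighted_triangle(self):
        g = wnet([("a", "b", 0.5), ("b", "c", 0.5), ("a", "c", 1.0)])
        assert weighted_density({"a", "b", "c"}, g) == pytest.approx(2 / 3, abs=1e-12)

    def test_uniform_clique_is_one(self):
        g = wnet([(a, b, 0.4) for a, b in combinations("abcde", 2)])
        assert weighted_density(set("abcde"), g) == pytest.approx(1.0)

    @pytest.mark.parametrize("members", [set(), {"a"}, {"a", "z"}])
    def test_degenerate_sets_are_zero(self, members):
        g = wnet([("a", "b", 1.0)])
        assert weighted_density(members, g) == 0.0

    def test_agrees_with_brute_force_on_random_subsets(self, rng):
        for _ in range(40):
            g = random_weighted_graph(rng, 8, p=0.5)
            nodes = sorted(g)
            k = int(rng.integers(2, len(nodes) + 1))
            members = set(rng.choice(nodes, size=k, replace=False))
            assert weighted_density(members, g) == pytest.approx(
                brute_density(members, g), abs=1e-12
            )


class TestSwd:
    def test_worked_coupling_example(self):
        ex = coupling_removal_example()
        assert swd("D", ex.neighbor_set, ex.network) == pytest.approx(0.7)
        assert swd("D", ex.candidate - {"D"}, ex.network) == pytest.approx(0.2)

    def test_empty_targets_and_missing_vertex(self):
        g = wnet([("a", "b", 1.0)])
        assert swd("a", set(), g) == 0.0
        assert swd("ghost", {"a", "b"}, g) == 0.0


class TestGrowCandidate:
    def test_zero_threshold_takes_closed_neighbourhood(self):
        g = wnet([("s", x, 0.5) for x in "abcd"])
        cand = grow_candidate("s", g, MineParams(wdt=0.0))
        assert cand.members == {"s", "a", "b", "c", "d"}

    def test_maximal_threshold_keeps_best_neighbour_only(self):
        # beyond the first (density-1) edge, an uneven triangle drops below 1
        g = wnet([("a", "b", 1.0), ("b", "c", 0.5), ("a", "c", 0.5)])
        cand = grow_candidate("a", g, MineParams(wdt=1.0))
        assert cand.members == {"a", "b"}
        assert cand.wd == pytest.approx(1.0)

    def test_greedy_insertion_matches_hand_trace(self):
        # order from a: A(1.0), B(0.8), C(0.1); adding C sinks WD to 0.4667
        g = wnet(
            [("s", "a", 1.0), ("s", "b", 0.8), ("s", "c", 0.1), ("a", "b", 0.9)]
        )
        cand = grow_candidate("s", g, MineParams(wdt=0.5))
        assert cand.members == {"s", "a", "b"}
        assert cand.wd == pytest.approx(2.7 * 2 / (1.0 * 6), abs=1e-12)

    def test_absent_seed_rejected(self):
        g = wnet([("a", "b", 1.0)])
        with pytest.raises(KeyError):
            grow_candidate("zz", g, MineParams())

    def test_every_acceptance_respected_threshold(self, rng):
        # growth soundness: replay the insertion sequence of the result
        for _ in range(20):
            g = random_weighted_graph(rng, 10, p=0.45)
            params = MineParams(wdt=0.3)
            for seed in sorted(g):
                cand = grow_candidate(seed, g, params)
                order = sorted(g[seed], key=lambda v: (-g[seed][v]["weight"], v))
                ccs = {seed}
                for v in order:
                    if v in cand.members:
                        ccs.add(v)
                        assert weighted_density(ccs, g) >= params.wdt


class TestPruneCoupling:
    def test_removes_exactly_the_high_coupling_node(self):
        ex = coupling_removal_example()
        cand = CandidateComplex(ex.candidate, seed=ex.seed, relation="PPIN", wd=0.0)
        pruned = prune_coupling(cand, ex.network)
        assert pruned.members == ex.candidate - {"D"}

    def test_isolated_candidate_unchanged(self):
        g = wnet([("a", "b", 0.9), ("b", "c", 0.9), ("a", "c", 0.9)])
        cand = CandidateComplex(frozenset("abc"), seed="a", relation="PPIN", wd=1.0)
        assert prune_coupling(cand, g).members == {"a", "b", "c"}

    def test_tie_retains_member(self):
        # swd inside == swd outside: strict inequality keeps the node
        g = wnet([("a", "b", 0.5), ("b", "x", 0.5)])
        cand = CandidateComplex(frozenset("ab"), seed="a", relation="PPIN", wd=1.0)
        assert prune_coupling(cand, g).members == {"a", "b"}

    def test_seed_is_never_removed(self):
        g = wnet([("s", "a", 0.1), ("s", "x", 0.9), ("s", "y", 0.9), ("a", "b", 1.0)])
        cand = CandidateComplex(frozenset({"s", "a"}), seed="s", relation="PPIN", wd=1.0)
        pruned = prune_coupling(cand, g)
        assert "s" in pruned.members


class TestMatchingScore:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({"a", "b", "c"}, {"a", "b", "c"}, 1.0),
            ({"a", "b"}, {"x", "y"}, 0.0),
            ({"a", "b"}, {"b", "c"}, 0.25),
        ],
    )
    def test_known_values(self, a, b, expected):
        assert matching_score(a, b) == pytest.approx(expected, abs=1e-12)
        assert matching_score(b, a) == matching_score(a, b)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            matching_score(set(), {"a"})


class TestRedundancyFilter:
    def cc(self, members, wd, relation="PPIN"):
        m = frozenset(members)
        return CandidateComplex(m, seed=min(m), relation=relation, wd=wd)

    def test_identical_complexes_collapse(self):
        out = redundancy_filter([self.cc("abc", 0.5), self.cc("abc", 0.5)])
        assert len(out) == 1

    def test_size_beats_density_at_threshold(self):
        # MS({a..e},{a..d}) = 16/20 = 0.8 -> the 4-set is discarded even
        # though it is denser
        big, small = self.cc("abcde", 0.6), self.cc("abcd", 0.9)
        out = redundancy_filter([small, big], overlap_threshold=0.8)
        assert [c.members for c in out] == [big.members]

    def test_overlap_below_threshold_keeps_both(self):
        # |A∩B|=11, sizes 14 and 11: MS = 121/154 ≈ 0.786 < 0.8
        a = self.cc([f"p{i}" for i in range(14)], 0.5)
        b = self.cc([f"p{i}" for i in range(11)], 0.9)
        assert matching_score(a.members, b.members) < 0.8
        assert len(redundancy_filter([a, b], overlap_threshold=0.8)) == 2

    def test_equal_size_discards_lower_density(self):
        x = self.cc("abcd", 0.9)
        y = self.cc("abce", 0.4)
        out = redundancy_filter([y, x], overlap_threshold=0.5)
        assert [c.members for c in out] == [x.members]


class TestMine:
    def test_two_disjoint_triangles_found(self):
        g = wnet(
            [("a", "b", 0.6), ("b", "c", 0.6), ("a", "c", 0.6),
             ("x", "y", 0.4), ("y", "z", 0.4), ("x", "z", 0.4)]
        )
        found = mine([g], MineParams(wdt=0.05))
        assert {c.members for c in found} == {frozenset("abc"), frozenset("xyz")}
        assert all(c.wd == pytest.approx(1.0) for c in found)

    def test_empty_network_yields_nothing(self):
        assert mine([nx.Graph(relation="PPIN")], MineParams()) == []

    def test_no_networks_rejected(self):
        with pytest.raises(ValueError):
            mine([], MineParams())

    def test_deterministic_across_runs(self, rng):
        g = random_weighted_graph(rng, 25, p=0.2)
        a = mine([g], MineParams())
        b = mine([g.copy()], MineParams())
        assert a == b

    def test_outputs_satisfy_contracts(self, rng):
        params = MineParams(wdt=0.1, overlap_threshold=0.8, min_size=2)
        g = random_weighted_graph(rng, 30, p=0.2)
        found = mine([g], params)
        for c in found:
            assert len(c.members) >= params.min_size
            assert c.wd > 0.0
            assert c.wd == pytest.approx(weighted_density(c.members, g), abs=1e-12)
        for i, a in enumerate(found):
            for b in found[i + 1:]:
                assert matching_score(a.members, b.members) < params.overlap_threshold

    def test_accumulated_set_is_global_across_networks(self):
        # the second network's triangle is a subset of a complex already
        # accepted from the first network, so it is screened out
        g1 = wnet(
            [("a", "b", 0.5), ("b", "c", 0.5), ("a", "c", 0.5),
             ("a", "d", 0.5), ("b", "d", 0.5), ("c", "d", 0.5)],
            relation="PPIN",
        )
        g2 = wnet([("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0)], relation="BPN")
        found = mine([g1, g2], MineParams(wdt=0.05))
        assert {c.members for c in found} == {frozenset("abcd")}
        assert found[0].relation == "PPIN"

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            MineParams(wdt=1.5)
        with pytest.raises(ValueError):
            MineParams(overlap_threshold=-0.1)
        with pytest.raises(ValueError):
            MineParams(min_size=0)
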