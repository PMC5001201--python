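"""Ripple centrality, epicenter ranking and LSCC reporting."""

import numpy as np
import pytest

import epitracer as et
from epitracer.centrality import _competition_rank, lscc_report
from epitracer.errors import EpitracerError

from _oracles import brute_ripple
from conftest import make_cshan, random_cost_graph


def unit_cshan(edges, condition="x"):
    return make_cshan({e: 1.0 for e in edges}, condition)


class TestClosenessAndReachability:
    def test_sink_scores_zero(self):
        scores = et.ripple_centrality(unit_cshan([("A", "B"), ("B", "C")]))
        assert scores.raw_closeness["C"] == 0.0
        assert scores.raw_reachability["C"] == 0
        assert scores.ripple["C"] == 0.0

    def test_out_star_center(self):
        c = unit_cshan([("S", "a"), ("S", "b"), ("S", "c")])
        scores = et.ripple_centrality(c)
        assert scores.raw_closeness["S"] == pytest.approx(1 / 3)
        assert scores.closeness["S"] == 1.0
        assert all(scores.raw_closeness[x] == 0.0 for x in "abc")

    def test_chain_raw_closeness(self):
        scores = et.ripple_centrality(unit_cshan([("A", "B"), ("B", "C")]))
        assert scores.raw_closeness["A"] == pytest.approx(1 / 3)  # 1/(1+2)
        assert scores.raw_closeness["B"] == pytest.approx(1.0)

    def test_chain_reachability(self):
        scores = et.ripple_centrality(unit_cshan([("A", "B"), ("B", "C")]))
        assert scores.raw_reachability["A"] == 2
        assert scores.reachability["A"] == pytest.approx(1.0)

    def test_cycle_full_reachability(self):
        n = 5
        edges = [(f"v{i}", f"v{(i + 1) % n}") for i in range(n)]
        scores = et.ripple_centrality(unit_cshan(edges))
        assert all(scores.raw_reachability[f"v{i}"] == n - 1 for i in range(n))
        assert all(scores.reachability[f"v{i}"] == pytest.approx(1.0)
                   for i in range(n))


class TestRippleCentrality:
    def test_high_activity_wide_reach_wins(self):
        # 15 nodes: Acl sources very active paths to only 2 nodes; Aor
        # reaches all 14 others but through low-activity (costly) paths;
        # Arc sources active paths to 7 nodes — the best epicenter.
        cost = {}
        others = [f"t{i}" for i in range(12)]
        cost[("Acl", others[0])] = 0.02
        cost[("Acl", others[1])] = 0.02
        for t in others[2:9]:
            cost[("Arc", t)] = 0.01
        for t in others + ["Acl", "Arc"]:
            cost[("Aor", t)] = 5.0
        scores = et.ripple_centrality(make_cshan(cost))
        assert scores.ripple["Arc"] > scores.ripple["Acl"]
        assert scores.ripple["Arc"] > scores.ripple["Aor"]

    def test_degenerate_single_edge_graph_scores_zero(self):
        scores = et.ripple_centrality(make_cshan({("A", "B"): 1.0}))
        assert scores.ripple == {"A": 0.0, "B": 0.0}

    def test_chain_matches_brute_force_oracle(self):
        cost = {("A", "B"): 1.0, ("B", "C"): 1.0}
        scores = et.ripple_centrality(make_cshan(cost))
        close, reach, ripple = brute_ripple("ABC", cost)
        for u in "ABC":
            assert scores.ripple[u] == pytest.approx(ripple[u], abs=1e-12)
        assert scores.ripple["A"] == pytest.approx(scores.closeness["A"] * 1.0)
        assert scores.ripple["C"] == 0.0

    def test_random_graphs_match_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            cost, _ = random_cost_graph(rng, int(rng.integers(4, 9)))
            if not cost:
                continue
            graph_nodes = sorted({x for e in cost for x in e})
            scores = et.ripple_centrality(make_cshan(cost))
            _, _, ripple = brute_ripple(graph_nodes, cost)
            for u in graph_nodes:
                assert scores.ripple[u] == pytest.approx(ripple[u], abs=1e-9)

    def test_logical_and_zero_factor_zeroes_ripple(self):
        scores = et.ripple_centrality(unit_cshan([("A", "B"), ("B", "C")]))
        for u, r in scores.ripple.items():
            if scores.closeness[u] == 0 or scores.reachability[u] == 0:
                assert r == 0.0
            assert r == scores.closeness[u] * scores.reachability[u]

    def test_monotone_in_activity_with_reach_fixed(self):
        # two out-stars with equal reach; the more active one (cheaper
        # edges) must get the higher ripple score
        cost = {("H", "a"): 0.1, ("H", "b"): 0.1,
                ("L", "c"): 1.0, ("L", "d"): 1.0}
        scores = et.ripple_centrality(make_cshan(cost))
        assert scores.reachability["H"] == scores.reachability["L"]
        assert scores.ripple["H"] > scores.ripple["L"]


class TestRanking:
    def test_competition_ranking_skips_after_tie(self):
        ranked = _competition_rank([("a", 5.0), ("b", 5.0), ("c", 1.0)])
        assert [(r, n) for r, n, _ in ranked] == [(1, "a"), (1, "b"), (3, "c")]

    def test_near_equal_scores_share_rank(self):
        s = 0.123456789
        ranked = _competition_rank([("a", s * (1 + 1e-12)), ("b", s), ("c", 0.1)])
        assert [r for r, _, _ in ranked] == [1, 1, 3]

    def test_bit_identical_scores_from_symmetric_graph(self):
        # two mirror-image branches from one hub: the two branch heads get
        # bit-identical ripple scores and must share a rank
        edges = [("S", "L"), ("L", "l1"), ("L", "l2"),
                 ("S", "R"), ("R", "r1"), ("R", "r2")]
        specific, _ = et.get_epicenters(unit_cshan(edges), unit_cshan([]), top_k=10)
        rl = specific.rank_of("L")
        assert rl is not None and rl == specific.rank_of("R")

    def test_empty_other_cshan_puts_everything_specific(self):
        c = unit_cshan([("A", "B"), ("B", "C")])
        specific, global_ = et.get_epicenters(c, unit_cshan([]), top_k=2)
        assert global_.entries == []
        assert set(specific.nodes()) <= {"A", "B", "C"}
        assert all(e.rank <= 2 for e in specific)

    def test_membership_split(self):
        analyzed = unit_cshan([("A", "B"), ("B", "C")])
        other = unit_cshan([("B", "X"), ("X", "C")])
        specific, global_ = et.get_epicenters(analyzed, other, top_k=10)
        assert set(specific.nodes()) == {"A"}
        assert set(global_.nodes()) == {"B", "C"}

    def test_whole_tie_group_kept_at_truncation(self):
        # 3 sinks tie at ripple 0; truncating at top_k=2 keeps rank-1 node
        # only (the tie group at rank 2 would overflow, it is kept whole)
        edges = [("S", "a"), ("S", "b"), ("S", "c")]
        specific, _ = et.get_epicenters(unit_cshan(edges), unit_cshan([]), top_k=2)
        ranks = [e.rank for e in specific]
        assert ranks.count(2) in (0, 3)  # tie group never split

    def test_empty_analyzed_cshan_is_error(self):
        with pytest.raises(EpitracerError, match="percentile"):
            et.get_epicenters(unit_cshan([]), unit_cshan([]), top_k=5)

    def test_planted_epicenter_ranks_high(self, default_case):
        res = et.run_stages(default_case.base, default_case.control,
                            default_case.perturbed)
        specific, _ = res.rankings["perturbed"]
        rank = specific.rank_of(default_case.manifest["planted_epicenter"])
        assert rank is not None and rank <= 3


class TestLSCC:
    def ranking_for(self, cshan):
        specific, _ = et.get_epicenters(cshan, unit_cshan([]), top_k=100)
        return specific

    def test_cycle_is_entirely_in_lscc(self):
        edges = [("a", "b"), ("b", "c"), ("c", "a")]
        c = unit_cshan(edges)
        rep = lscc_report(c, self.ranking_for(c))
        assert rep.lscc_size == 3
        assert rep.table["in_lscc"].all()

    def test_dag_has_trivial_lscc(self):
        c = unit_cshan([("a", "b"), ("b", "c"), ("a", "c")])
        rep = lscc_report(c, self.ranking_for(c))
        assert rep.lscc_size == 1
        assert not rep.table["in_lscc"].any()

    def test_pendant_node_flagged_false(self):
        edges = [("a", "b"), ("b", "c"), ("c", "a"), ("c", "p")]
        c = unit_cshan(edges)
        rep = lscc_report(c, self.ranking_for(c))
        row = rep.table[rep.table["gene"] == "p"]
        assert not row["in_lscc"].item()
        assert rep.lscc == {"a", "b", "c"}
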