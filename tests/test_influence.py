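"""Influence-zone extraction and the dysregulation summary table."""

import networkx as nx
import numpy as np
import pytest

import epitracer as et
from epitracer.errors import EpitracerError, ParameterError
from epitracer.influence import (read_influence_rows, which_network_label,
                                 write_influence_report)

from conftest import make_cshan


def digraph(edges):
    g = nx.DiGraph()
    g.add_edges_from(edges)
    return g


def fc_table(ratios, cutoff=2.0):
    control = et.ExpressionProfile("control", {g: 1.0 for g in ratios})
    perturbed = et.ExpressionProfile("perturbed", dict(ratios))
    return et.fold_changes(control, perturbed, cutoff=cutoff)


class TestInfluenceZone:
    def test_isolated_epicenter_has_only_input_row(self):
        g = digraph([("X", "Y")])
        g.add_node("E")
        rep = et.influence_zone("E", g, fc_table({"E": 1.0, "X": 4.0, "Y": 1.0}))
        assert len(rep.rows) == 1
        row = rep.rows.iloc[0]
        assert row["Node"] == "E" and row["Direction"] == "input_node"
        assert row["Num_hops"] == 0

    def test_direct_downstream_neighbor(self):
        rep = et.influence_zone("E", digraph([("E", "X")]),
                                fc_table({"E": 1.0, "X": 4.0}))
        assert len(rep.rows) == 2
        row = rep.rows.iloc[1]
        assert (row["Node"], row["Direction"], row["Num_hops"]) == ("X", "down_E", 1)
        assert row["Fold_change"] == pytest.approx(4.0)
        assert row["Intermediate_node_1"] == ""  # direct neighbor: no intermediate

    def test_two_hop_with_insignificant_intermediate(self):
        rep = et.influence_zone("E", digraph([("E", "M"), ("M", "X")]),
                                fc_table({"E": 1.0, "M": 1.2, "X": 0.25}))
        row = rep.rows.iloc[1]
        assert (row["Node"], row["Direction"], row["Num_hops"]) == ("X", "down_E", 2)
        assert row["Fold_change"] == pytest.approx(0.25)
        assert row["Intermediate_node_1"] == "M"
        assert row["Fold_change_1"] == pytest.approx(1.2)
        assert row["Significant_fc_1"] is False
        # M itself fails the cutoff, so it gets no row of its own
        assert "M" not in set(rep.rows["Node"][1:])

    def test_upstream_direction_label(self):
        rep = et.influence_zone("E", digraph([("X", "E")]),
                                fc_table({"E": 1.0, "X": 4.0}))
        row = rep.rows.iloc[1]
        assert (row["Node"], row["Direction"]) == ("X", "up_E")

    def test_node_in_both_directions_gets_two_rows(self):
        g = digraph([("E", "X"), ("X", "E")])
        rep = et.influence_zone("E", g, fc_table({"E": 1.0, "X": 4.0}))
        dirs = set(rep.rows["Direction"][1:])
        assert dirs == {"down_E", "up_E"}

    def test_zone_respects_hop_limit_and_is_monotone(self):
        chain = digraph([("E", "a"), ("a", "b"), ("b", "c")])
        ratios = {"E": 1.0, "a": 4.0, "b": 4.0, "c": 4.0}
        zone1 = et.influence_zone("E", chain, fc_table(ratios), hops=1)
        zone2 = et.influence_zone("E", chain, fc_table(ratios), hops=2)
        assert set(zone1.zone.nodes) <= set(zone2.zone.nodes)
        assert zone2.rows["Num_hops"].max() == 2

    def test_lower_cutoff_never_removes_rows(self):
        g = digraph([("E", "a"), ("E", "b")])
        ratios = {"E": 1.0, "a": 2.5, "b": 8.0}
        strict = et.influence_zone("E", g, fc_table(ratios, 2.0), fc_cutoff=3.0)
        loose = et.influence_zone("E", g, fc_table(ratios, 2.0), fc_cutoff=2.0)
        key = set(zip(strict.rows["Node"], strict.rows["Direction"]))
        assert key <= set(zip(loose.rows["Node"], loose.rows["Direction"]))

    def test_missing_epicenter_names_containing_graphs(self):
        cshan_p = make_cshan({("E", "x"): 1.0, ("x", "y"): 1.0})
        with pytest.raises(EpitracerError, match="perturbed CSHAN"):
            et.influence_zone("E", digraph([("a", "b")]),
                              fc_table({"E": 1.0, "a": 1.0, "b": 1.0}),
                              cshan_perturbed=cshan_p)

    def test_bad_parameters(self):
        g = digraph([("E", "X")])
        fc = fc_table({"E": 1.0, "X": 4.0})
        with pytest.raises(ParameterError):
            et.influence_zone("E", g, fc, hops=0)
        with pytest.raises(ParameterError):
            et.influence_zone("E", g, fc, fc_cutoff=1.0)

    def test_which_network_labels(self):
        cp = make_cshan({("E", "a"): 1.0, ("a", "s"): 1.0})
        cc = make_cshan({("b", "a"): 1.0, ("a", "E"): 1.0})
        assert which_network_label("E", cp, cc) == "common to both CSHANs"
        assert which_network_label("s", cp, cc) == "unique to perturbed CSHAN"
        assert which_network_label("b", cp, cc) == "unique to control CSHAN"
        assert which_network_label("zz", cp, cc) == "not in any CSHAN"

    def test_augmentation_adds_downregulated_from_full_network(self):
        cshan_graph = digraph([("E", "a"), ("a", "b")])
        full = digraph([("E", "a"), ("a", "b"), ("E", "d")])
        ratios = {"E": 1.0, "a": 1.0, "b": 1.0, "d": 0.2}
        none = et.influence_zone("E", cshan_graph, fc_table(ratios),
                                 augment_from_full="none", full_network=full)
        down = et.influence_zone("E", cshan_graph, fc_table(ratios),
                                 augment_from_full="down", full_network=full)
        assert "d" not in set(none.rows["Node"])
        assert "d" in set(down.rows["Node"])
        assert "d" in down.zone.nodes

    def test_bfs_distances_match_networkx(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            n = int(rng.integers(6, 15))
            nodes = [f"n{i}" for i in range(n)]
            g = digraph([(u, v) for u in nodes for v in nodes
                         if u != v and rng.random() < 0.25])
            if "n0" not in g:
                continue
            ratios = {u: 4.0 for u in g.nodes}
            ratios["n0"] = 1.0
            rep = et.influence_zone("n0", g, fc_table(ratios), hops=3)
            rg = g.reverse()
            for _, row in rep.rows.iloc[1:].iterrows():
                ref = g if row["Direction"].startswith("down") else rg
                assert row["Num_hops"] == nx.shortest_path_length(
                    ref, "n0", row["Node"])


class TestCombinedZone:
    def test_single_epicenter_matches_plain_zone(self):
        g = digraph([("E", "a"), ("a", "b")])
        fc = fc_table({"E": 1.0, "a": 4.0, "b": 4.0})
        single = et.influence_zone("E", g, fc)
        combined = et.combined_influence_zone(["E"], g, fc)
        assert set(single.zone.nodes) == set(combined.zone.nodes)
        assert single.rows.equals(combined.rows)

    def test_disjoint_zones_union_with_singleton_provenance(self):
        g = digraph([("E1", "a"), ("E2", "b")])
        fc = fc_table({"E1": 1.0, "E2": 1.0, "a": 4.0, "b": 4.0})
        rep = et.combined_influence_zone(["E1", "E2"], g, fc)
        assert rep.provenance["a"] == ("E1",)
        assert rep.provenance["b"] == ("E2",)
        assert set(rep.zone.nodes) == {"E1", "E2", "a", "b"}

    def test_keep_list_retains_connectors(self):
        g = digraph([("E", "a"), ("a", "T")])
        fc = fc_table({"E": 1.0, "a": 1.0, "T": 4.0})
        rep = et.combined_influence_zone(["E"], g, fc, keep=["E", "T"])
        assert set(rep.zone.nodes) == {"E", "a", "T"}  # a kept as connector


class TestSerialization:
    def test_roundtrip_is_identical(self, tmp_path):
        g = digraph([("E", "M"), ("M", "X"), ("Y", "E")])
        fc = fc_table({"E": 1.1, "M": 1.2, "X": 0.25, "Y": 5.0})
        rep = et.influence_zone("E", g, fc)
        f = tmp_path / "zone.tsv"
        write_influence_report(rep, f)
        back = read_influence_rows(f)
        assert list(back.columns) == list(rep.rows.columns)
        for col in rep.rows.columns:
            for a, b in zip(rep.rows[col], back[col]):
                assert a == b
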