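"""Interaction filtering, core/shell assembly and network surgery."""

import networkx as nx
import pytest

from phenonet import (InteractionRecord, annotate, assemble_network,
                      build_reference_census_network, connected_components,
                      core_shell_split, filter_interactions,
                      induce_subnetwork, remove_node, to_undirected_simple,
                      topology_summary)


def binding(a, b, score=0.95, evidence="experimental"):
    return InteractionRecord(a, b, "binding", "none", score, evidence)


class TestInteractionRecord:
    def test_binding_must_be_undirected(self):
        with pytest.raises(ValueError):
            InteractionRecord("a", "b", "binding", "ab", 0.9)

    def test_directed_kinds_need_direction(self):
        with pytest.raises(ValueError):
            InteractionRecord("a", "b", "activation", "none", 0.9)
        rec = InteractionRecord("a", "b", "ptm:phosphorylation", "ba", 0.9)
        assert rec.direction == "ba"

    def test_score_bounds(self):
        with pytest.raises(ValueError):
            InteractionRecord("a", "b", "binding", "none", 1.5)


class TestFilterInteractions:
    def test_score_threshold_inclusive(self):
        records = [binding("a", "b", 0.9), binding("a", "c", 0.89)]
        kept = filter_interactions(records)
        assert [r.node_b for r in kept] == ["b"]

    def test_evidence_requirement(self):
        records = [binding("a", "b", 0.99, evidence="other")]
        assert filter_interactions(records) == []
        assert filter_interactions(records, required_evidence=None) == records


class TestAssembly:
    def test_first_shell_only(self):
        records = [binding("A", "B"), binding("B", "C"), binding("C", "D")]
        net = assemble_network({"A"}, records)
        assert set(net.nodes) == {"A", "B"}
        assert len(net.edges) == 1

    def test_no_records_leaves_isolated_core(self):
        net = assemble_network({"A", "B"}, [])
        assert set(net.nodes) == {"A", "B"} and net.edges == []

    def test_core_core_edge_kept(self):
        net = assemble_network({"A", "B"}, [binding("A", "B")])
        assert net.core_nodes() == {"A", "B"}
        assert len(net.edges) == 1

    def test_empty_core_rejected(self):
        with pytest.raises(ValueError):
            assemble_network(set(), [binding("A", "B")])

    def test_idempotence(self):
        records = [binding("A", "B"), binding("B", "C"), binding("A", "C"),
                   InteractionRecord("B", "D", "activation", "ab", 0.92)]
        net = assemble_network({"A", "D"}, records)
        again = assemble_network(net.core_nodes(), net.edges)
        assert set(again.nodes) == set(net.nodes)
        assert sorted(map(repr, again.edges)) == sorted(map(repr, net.edges))

    def test_shell_minimality(self):
        records = [binding("A", "B"), binding("B", "C"), binding("C", "D"),
                   binding("A", "C")]
        net = assemble_network({"A"}, records)
        core = net.core_nodes()
        for node in set(net.nodes) - core:
            assert any(e.touches(node) and (core & e.endpoints)
                       for e in net.edges)


class TestRemoveNode:
    def _toy(self):
        net = assemble_network({"H"}, [binding("H", f"n{i}") for i in range(7)])
        return net

    def test_incident_edge_count_drops(self):
        net = self._toy()
        out = remove_node(net, "H")
        assert out.n_edges == 0 and "H" not in out.nodes

    def test_conservation_with_extra_edges(self):
        records = [binding("H", "a"), binding("H", "b"), binding("a", "b"),
                   binding("a", "c"), binding("b", "c")]
        net = assemble_network({"H", "a", "b", "c"}, records)
        out = remove_node(net, "H", extra_edges=[("a", "b")])
        assert net.n_edges - out.n_edges == 2 + 1

    def test_isolate_removal_keeps_edges(self):
        net = assemble_network({"A", "Z"}, [binding("A", "B")])
        out = remove_node(net, "Z")
        assert out.n_edges == net.n_edges

    def test_absent_node_rejected(self):
        with pytest.raises(KeyError):
            remove_node(self._toy(), "missing")


class TestComponents:
    def test_single_component(self):
        net = assemble_network({"A"}, [binding("A", "B"), binding("A", "C")])
        assert len(connected_components(net)) == 1

    def test_component_census_and_order(self):
        records = ([binding("a1", "a2"), binding("b1", "b2")]
                   + [binding(f"p{i}", f"p{i+1}") for i in range(3)]
                   + [binding(f"m{i}", f"m{j}") for i in range(6)
                      for j in range(i + 1, 6)])
        core = {n for r in records for n in (r.node_a, r.node_b)}
        net = assemble_network(core, records)
        comps = connected_components(net)
        assert [c.n_nodes for c in comps] == [6, 4, 2, 2]
        total_nodes = sum(c.n_nodes for c in comps)
        total_edges = sum(c.n_edges for c in comps)
        assert total_nodes == net.n_nodes and total_edges == net.n_edges


class TestCoreShellSplit:
    def test_hand_counts(self):
        records = [binding("c1", "c2"), binding("c2", "c3"),
                   binding("c1", "s1"), binding("c2", "s2"), binding("c3", "s1")]
        net = assemble_network({"c1", "c2", "c3"}, records)
        core_net, shell_net = core_shell_split(net)
        assert core_net.n_edges == 2 and shell_net.n_edges == 3
        assert len(net.edges) == core_net.n_edges + shell_net.n_edges

    def test_all_core_network(self):
        net = assemble_network({"a", "b"}, [binding("a", "b")])
        core_net, shell_net = core_shell_split(net)
        assert shell_net.n_edges == 0 and core_net.n_edges == 1


class TestInduceSubnetwork:
    def _path(self):
        recs = [binding(f"n{i}", f"n{i+1}") for i in range(4)]
        return assemble_network({f"n{i}" for i in range(5)}, recs)

    def test_identity(self):
        net = self._path()
        sub = induce_subnetwork(net, set(net.nodes))
        assert set(sub.nodes) == set(net.nodes)
        assert sub.n_edges == net.n_edges

    def test_disjoint_union_warns_empty(self):
        with pytest.warns(UserWarning):
            sub = induce_subnetwork(self._path(), {"zzz"})
        assert sub.n_nodes == 0

    def test_path_ends_stay_isolated(self):
        sub = induce_subnetwork(self._path(), {"n0", "n4"})
        assert set(sub.nodes) == {"n0", "n4"} and sub.n_edges == 0


class TestAnnotate:
    def test_defaults_are_none(self):
        net = assemble_network({"A"}, [binding("A", "B")])
        out = annotate(net)
        assert all(a["regulation"] == "none" for a in out.nodes.values())

    def test_regulation_and_magnitude(self):
        net = assemble_network({"A"}, [binding("A", "B")])
        out = annotate(net, calls={"A": ("up", 3.32)})
        assert out.nodes["A"]["regulation"] == "up"
        assert out.nodes["A"]["magnitude"] == pytest.approx(3.32)

    def test_drug_overlay(self):
        net = assemble_network({"A"}, [binding("A", "B")])
        out = annotate(net, drug_targets={"drugX": {"A"}, "drugY": {"missing"}})
        assert out.nodes["A"]["drug_targets"] == ["drugX"]


class TestUndirectedSimple:
    def test_parallel_records_collapse(self):
        records = [binding("a", "b"),
                   InteractionRecord("a", "b", "activation", "ab", 0.95)]
        net = assemble_network({"a", "b"}, records)
        g = to_undirected_simple(net)
        assert g.number_of_edges() == 1

    def test_hand_multigraph_collapse(self):
        records = [binding("a", "b"), binding("a", "b"), binding("b", "c"),
                   InteractionRecord("c", "a", "inhibition", "ba", 0.91),
                   InteractionRecord("b", "c", "activation", "ab", 0.93)]
        net = assemble_network({"a", "b", "c"}, records)
        g = to_undirected_simple(net)
        assert g.number_of_edges() == 3


class TestTopology:
    def test_complete_graph(self):
        stats = topology_summary(nx.complete_graph(4))
        assert stats["density"] == pytest.approx(1.0)
        assert stats["mean_clustering"] == pytest.approx(1.0)

    def test_empty_graph(self):
        stats = topology_summary(nx.Graph())
        assert stats["node_count"] == 0 and stats["edge_count"] == 0

    def test_hand_computed_toy(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")])
        stats = topology_summary(g)
        assert stats["edge_count"] == 4
        assert stats["avg_degree"] == pytest.approx(2.0)
        # clustering: a=1, b=1, c=1/3, d=0 -> mean 7/12
        assert stats["mean_clustering"] == pytest.approx(7 / 12)
        assert stats["degree_distribution"] == {2: 2, 3: 1, 1: 1}


class TestReferenceCensus:
    def test_published_scale_bookkeeping(self):
        """Hub + curated removal leaves the printed component census."""
        net, hub, extra, small = build_reference_census_network()
        assert (net.n_nodes, net.n_edges) == (433, 1790)
        assert net.degree(hub) == 175
        assert len(connected_components(net)) == 3
        pruned = remove_node(net, hub, extra_edges=extra)
        assert (pruned.n_nodes, pruned.n_edges) == (432, 1595)
        comps = connected_components(pruned)
        assert [c.n_nodes for c in comps] == [424, 4, 2, 2]
        assert comps[0].n_edges == 1589
        assert len(comps[0].core_nodes()) == 82
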