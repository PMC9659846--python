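"""SCCs, clustering coefficients, bidirectional edges, attribute overlays."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcatnet.measures import (
    COMBINED,
    EXCLUSIVE_HETEROGENEOUS,
    EXCLUSIVE_HOMOGENEOUS,
    AnnotationTable,
    bidirectional_edges,
    clustering_coefficient,
    global_clustering,
    influence_mixing,
    strongly_connected_components,
    subnetwork,
)

from conftest import random_digraph, scc_partition_by_reachability


def flags_for(graph, attribute="se", seed=0):
    rng = np.random.default_rng(seed)
    return AnnotationTable({n: {attribute: bool(rng.integers(2))} for n in graph.nodes})


class TestScc:
    def test_cycle_is_one_component(self):
        g = nx.DiGraph([(1, 2), (2, 3), (3, 1)])
        assert strongly_connected_components(g) == [{1, 2, 3}]

    def test_path_gives_singletons(self):
        g = nx.DiGraph([(1, 2), (2, 3)])
        assert strongly_connected_components(g) == [{1}, {2}, {3}]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_partition_matches_reachability_oracle(self, seed):
        g = random_digraph(seed, n=40, p=0.05)
        ours = {frozenset(c) for c in strongly_connected_components(g)}
        assert ours == scc_partition_by_reachability(g)

    def test_partition_covers_nodes_and_condensation_is_dag(self):
        g = random_digraph(7, n=35, p=0.07)
        comps = strongly_connected_components(g)
        seen = [n for c in comps for n in c]
        assert sorted(seen) == sorted(g.nodes)
        assert len(seen) == len(set(seen))
        assert nx.is_directed_acyclic_graph(nx.condensation(g))

    def test_output_order_by_smallest_member(self):
        g = nx.DiGraph([(5, 6), (6, 5), (1, 2), (2, 1), (5, 1)])
        comps = strongly_connected_components(g)
        assert [min(c) for c in comps] == sorted(min(c) for c in comps)


class TestClustering:
    def test_fully_mutual_neighbors_give_one(self):
        g = nx.DiGraph([(0, 1), (0, 2), (1, 2), (2, 1)])
        assert clustering_coefficient(g, 0) == 1.0

    def test_unlinked_neighbors_give_zero(self):
        g = nx.DiGraph([(0, 1), (0, 2)])
        assert clustering_coefficient(g, 0) == 0.0

    def test_fewer_than_two_neighbors_gives_zero(self):
        g = nx.DiGraph([(0, 1)])
        assert clustering_coefficient(g, 0) == 0.0
        assert clustering_coefficient(g, 1) == 0.0

    def test_one_way_link_gives_half(self):
        g = nx.DiGraph([(0, 1), (0, 2), (1, 2)])
        assert clustering_coefficient(g, 0) == pytest.approx(0.5)

    def test_complete_bidirected_triangle_global_cc_is_one(self):
        g = nx.DiGraph()
        for u in range(3):
            for v in range(3):
                if u != v:
                    g.add_edge(u, v)
        assert global_clustering(g) == 1.0

    @pytest.mark.parametrize("seed", [0, 4, 9])
    def test_matches_neighbor_pair_brute_force(self, seed):
        g = random_digraph(seed, n=30, p=0.12)
        for node in g.nodes:
            nbrs = sorted(set(g.predecessors(node)) | set(g.successors(node)) - {node})
            nbrs = [n for n in nbrs if n != node]
            k = len(nbrs)
            expected = 0.0
            if k >= 2:
                realized = sum(
                    int(g.has_edge(u, v)) + int(g.has_edge(v, u))
                    for i, u in enumerate(nbrs)
                    for v in nbrs[i + 1 :]
                )
                expected = realized / (k * (k - 1))
            value = clustering_coefficient(g, node)
            assert value == pytest.approx(expected)
            assert 0.0 <= value <= 1.0

    def test_global_is_mean_of_node_values(self):
        g = random_digraph(2, n=25, p=0.1)
        values = [clustering_coefficient(g, n) for n in g.nodes]
        assert global_clustering(g) == pytest.approx(float(np.mean(values)))

    def test_unknown_node_errors(self):
        with pytest.raises(KeyError):
            clustering_coefficient(nx.DiGraph([(0, 1)]), 99)


class TestBidirectional:
    def test_reciprocal_pair_found_once(self):
        g = nx.DiGraph([(1, 2), (2, 1)])
        assert bidirectional_edges(g) == {frozenset((1, 2))}

    def test_one_way_edge_is_not_mutual(self):
        assert bidirectional_edges(nx.DiGraph([(1, 2)])) == set()

    @pytest.mark.parametrize("seed", [0, 5])
    def test_matches_reciprocal_scan(self, seed):
        g = random_digraph(seed, n=30, p=0.15)
        expected = {
            frozenset((u, v))
            for u in g.nodes
            for v in g.nodes
            if u != v and g.has_edge(u, v) and g.has_edge(v, u)
        }
        found = bidirectional_edges(g)
        assert found == expected
        assert len(found) <= g.number_of_edges() / 2


class TestSubnetwork:
    def test_uniform_flag_returns_whole_graph(self):
        g = random_digraph(1, n=15, p=0.1)
        ann = AnnotationTable({n: {"se": True} for n in g.nodes})
        sub = subnetwork(g, ann, "se", True)
        assert set(sub.nodes) == set(g.nodes)
        assert set(sub.edges) == set(g.edges)

    def test_alternating_flags_on_bipartite_influences_give_edgeless_subgraphs(self):
        g = nx.DiGraph([(0, 1), (2, 3), (1, 2)])
        ann = AnnotationTable({n: {"se": n % 2 == 0} for n in g.nodes})
        for value in (True, False):
            sub = subnetwork(g, ann, "se", value)
            assert sub.number_of_edges() == 0

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_matches_brute_force_filter_and_partitions_nodes(self, seed):
        g = random_digraph(seed, n=25, p=0.1)
        ann = flags_for(g, seed=seed)
        true_sub = subnetwork(g, ann, "se", True)
        false_sub = subnetwork(g, ann, "se", False)
        assert set(true_sub.nodes) | set(false_sub.nodes) == set(g.nodes)
        assert set(true_sub.nodes) & set(false_sub.nodes) == set()
        expected_edges = {
            (u, v) for u, v in g.edges if ann.get(u, "se") and ann.get(v, "se")
        }
        assert set(true_sub.edges) == expected_edges

    def test_missing_annotation_errors_with_position(self):
        g = nx.DiGraph([(1, 2)])
        ann = AnnotationTable({1: {"se": True}})
        with pytest.raises(ValueError, match="2"):
            subnetwork(g, ann, "se", True)


class TestInfluenceMixing:
    def test_exclusive_and_combined_classes(self):
        # 1(se) -> 2(se): homogeneous only; 3(se) -> 4(bu): heterogeneous only;
        # 5(se) -> 2(se) and 5 -> 4(bu): combined.
        g = nx.DiGraph([(1, 2), (3, 4), (5, 2), (5, 4)])
        ann = AnnotationTable(
            {1: {"se": True}, 2: {"se": True}, 3: {"se": True}, 4: {"se": False}, 5: {"se": True}}
        )
        report = influence_mixing(g, ann, "se", value=True)
        assert report.node_influence_class[1] == EXCLUSIVE_HOMOGENEOUS
        assert report.node_influence_class[2] == EXCLUSIVE_HOMOGENEOUS
        assert report.node_influence_class[3] == EXCLUSIVE_HETEROGENEOUS
        assert report.node_influence_class[5] == COMBINED

    def test_bidirectional_partner_classes(self):
        g = nx.DiGraph([(1, 2), (2, 1), (1, 3), (3, 1)])
        ann = AnnotationTable({1: {"se": True}, 2: {"se": True}, 3: {"se": False}})
        report = influence_mixing(g, ann, "se", value=True)
        assert report.bidirectional_class[1] == COMBINED
        assert report.bidirectional_class[2] == EXCLUSIVE_HOMOGENEOUS
        assert report.n_bidirectional_nodes == 2

    def test_classes_cover_flagged_nodes_with_edges(self):
        g = random_digraph(3, n=30, p=0.08)
        ann = flags_for(g, seed=3)
        report = influence_mixing(g, ann, "se", value=True)
        flagged_with_edges = {
            n for n in g.nodes
            if ann.get(n, "se") and (g.in_degree(n) + g.out_degree(n)) > 0
        }
        assert set(report.node_influence_class) == flagged_with_edges
        assert set(report.node_influence_class.values()) <= {
            EXCLUSIVE_HOMOGENEOUS, EXCLUSIVE_HETEROGENEOUS, COMBINED,
        }

    def test_subnetwork_stats_are_induced(self):
        g = nx.DiGraph([(1, 2), (2, 1), (2, 3), (3, 4), (4, 3)])
        ann = AnnotationTable({1: {"f": True}, 2: {"f": True}, 3: {"f": False}, 4: {"f": False}})
        report = influence_mixing(g, ann, "f", value=True)
        assert report.n_nodes == 2
        assert report.n_edges == 2  # the 1<->2 reciprocal pair only
        assert report.n_scc == 1


class TestAnnotationCsv:
    def test_round_trip_and_blank_is_false(self, tmp_path):
        path = tmp_path / "ann.csv"
        path.write_text(
            "residue_id,se,sector,fsp,hotspot\n"
            "A301,1,true,,0\n"
            "A302,,yes,1,\n"
        )
        table = AnnotationTable.from_csv(path)
        from gcatnet.structure_io import ResidueId

        assert table.get(ResidueId("A", 301), "se") is True
        assert table.get(ResidueId("A", 301), "sector") is True
        assert table.get(ResidueId("A", 301), "fsp") is False
        assert table.get(ResidueId("A", 302), "se") is False
        assert table.get(ResidueId("A", 302), "fsp") is True
        assert table.attributes() == ["fsp", "hotspot", "se", "sector"]

    def test_missing_residue_id_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,se\nA1,1\n")
        with pytest.raises(ValueError, match="residue_id"):
            AnnotationTable.from_csv(path)
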