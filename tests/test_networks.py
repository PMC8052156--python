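"""Graph metrics, core-node selection, bipartite/tripartite construction."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from oracles import closeness_by_bfs
from phytonet import (
    NODE_CLASS,
    AnnotationDatabase,
    GeneSet,
    build_bipartite,
    build_tripartite,
    closeness_profile,
    degree_profile,
    network_summary,
    select_core_nodes,
)


def named(graph):
    return nx.relabel_nodes(graph, {n: f"N{n}" for n in graph.nodes()})


class TestDegree:
    def test_triangle(self):
        deg = degree_profile(named(nx.complete_graph(3)))
        assert set(deg.values()) == {2}
        assert np.mean(list(deg.values())) == 2.0

    def test_star_hub_and_leaves(self):
        deg = degree_profile(named(nx.star_graph(4)))  # 1 hub + 4 leaves
        assert deg["N0"] == 4
        assert all(deg[f"N{i}"] == 1 for i in range(1, 5))
        assert np.mean(list(deg.values())) == pytest.approx(1.6)

    def test_degree_sum_is_twice_edges(self):
        for seed in range(5):
            g = nx.gnp_random_graph(20, 0.2, seed=seed)
            assert sum(degree_profile(g).values()) == 2 * g.number_of_edges()


class TestCloseness:
    def test_complete_graph_is_one(self):
        clo = closeness_profile(named(nx.complete_graph(4)), variant="standard")
        assert all(c == pytest.approx(1.0) for c in clo.values())

    def test_path_graph_standard(self):
        g = nx.Graph([("A", "B"), ("B", "C")])
        clo = closeness_profile(g, variant="standard")
        assert clo["B"] == pytest.approx(1.0)
        assert clo["A"] == pytest.approx(2 / 3)

    def test_disconnected_edges_wf_scaled(self):
        g = nx.Graph([("A", "B"), ("C", "D")])
        clo = closeness_profile(g, variant="wf_scaled")
        assert all(c == pytest.approx(1 / 3) for c in clo.values())

    def test_isolated_node_scores_zero(self):
        g = nx.Graph()
        g.add_nodes_from(["A", "B"])
        g.add_edge("A", "B")
        g.add_node("Z")
        for variant in ("standard", "wf_scaled"):
            assert closeness_profile(g, variant=variant)["Z"] == 0.0

    @pytest.mark.parametrize("variant", ["standard", "wf_scaled"])
    def test_matches_bfs_oracle_on_random_graphs(self, variant):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = int(rng.integers(2, 13))
            g = nx.gnp_random_graph(n, float(rng.uniform(0.1, 0.9)), seed=int(rng.integers(2**31)))
            got = closeness_profile(g, variant=variant)
            expect = closeness_by_bfs(g, variant=variant)
            for node in expect:
                assert got[node] == pytest.approx(expect[node], abs=1e-12)

    def test_adding_edge_never_decreases_endpoint_metrics(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            g = nx.gnp_random_graph(10, 0.3, seed=int(rng.integers(2**31)))
            non_edges = list(nx.non_edges(g))
            if not non_edges:
                continue
            u, v = non_edges[int(rng.integers(len(non_edges)))]
            before_deg, before_clo = degree_profile(g), closeness_profile(g)
            g.add_edge(u, v)
            after_deg, after_clo = degree_profile(g), closeness_profile(g)
            for node in (str(u), str(v)):
                assert after_deg[node] >= before_deg[node]
                assert after_clo[node] >= before_clo[node] - 1e-12


class TestCoreSelection:
    def test_complete_graph_all_core(self):
        sel = select_core_nodes(named(nx.complete_graph(5)))
        assert sel.core_nodes == frozenset(f"N{i}" for i in range(5))

    def test_star_core_is_exactly_the_hub(self):
        # Hand computation: degrees (4,1,1,1,1) mean 1.6; only the hub also
        # reaches every node in one hop, so only it clears both means.
        sel = select_core_nodes(named(nx.star_graph(4)))
        assert sel.core_nodes == frozenset({"N0"})
        assert sel.mean_degree == pytest.approx(1.6)

    def test_vertex_transitive_graph_returns_all_nodes(self):
        sel = select_core_nodes(named(nx.cycle_graph(7)))
        assert len(sel.core_nodes) == 7

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            select_core_nodes(nx.Graph())

    def test_core_invariant_holds(self):
        g = nx.gnp_random_graph(30, 0.15, seed=5)
        sel = select_core_nodes(g)
        table = sel.metrics.set_index("node_id")
        for node in sel.core_nodes:
            assert table.loc[node, "degree"] >= sel.mean_degree
            assert table.loc[node, "closeness"] >= sel.mean_closeness


class TestBipartite:
    def test_two_ingredients_three_shared_targets(self):
        df = pd.DataFrame(
            [(m, g, "") for m in ("M1", "M2") for g in ("G1", "G2", "G3")],
            columns=["mol_id", "gene", "provenance"],
        )
        net = build_bipartite(df)
        assert net.number_of_nodes() == 5 and net.number_of_edges() == 6
        classes = nx.get_node_attributes(net, NODE_CLASS)
        assert classes["M1"] == "ingredient" and classes["G1"] == "target"

    def test_empty_associations(self):
        df = pd.DataFrame(columns=["mol_id", "gene", "provenance"])
        net = build_bipartite(df)
        assert net.number_of_nodes() == 0 and net.number_of_edges() == 0

    def test_synthetic_map_node_count_matches_truth(self, synth17):
        net = build_bipartite(synth17.associations)
        n_ingredients = synth17.associations["mol_id"].nunique()
        assert net.number_of_nodes() == n_ingredients + len(synth17.truth.drug_union)
        assert net.number_of_edges() == len(synth17.associations)


def small_db(**terms):
    return AnnotationDatabase(
        terms={t: GeneSet.from_iterable(t, gs) for t, gs in terms.items()},
        namespace="pathway",
    )


class TestTripartite:
    def test_single_term_single_hit(self):
        df = pd.DataFrame([("M1", "G1", "")], columns=["mol_id", "gene", "provenance"])
        net = build_tripartite(df, small_db(T1={"G1"}), ["T1"])
        assert net.number_of_nodes() == 3 and net.number_of_edges() == 2

    def test_no_ingredient_hits_leaves_pathway_nodes_only(self):
        df = pd.DataFrame([("M1", "G9", "")], columns=["mol_id", "gene", "provenance"])
        net = build_tripartite(df, small_db(T1={"G1"}), ["T1"])
        assert set(net.nodes()) == {"T1"} and net.number_of_edges() == 0

    def test_missing_term_named_in_error(self):
        df = pd.DataFrame([("M1", "G1", "")], columns=["mol_id", "gene", "provenance"])
        with pytest.raises(KeyError, match="T9"):
            build_tripartite(df, small_db(T1={"G1"}), ["T9"])

    def test_node_classes_partition_node_set(self):
        df = pd.DataFrame(
            [("M1", "G1", ""), ("M1", "G2", ""), ("M2", "G2", "")],
            columns=["mol_id", "gene", "provenance"],
        )
        net = build_tripartite(df, small_db(T1={"G1"}, T2={"G2", "G3"}), ["T1", "T2"])
        classes = nx.get_node_attributes(net, NODE_CLASS)
        assert set(classes) == set(net.nodes())
        assert set(classes.values()) == {"ingredient", "target", "pathway"}

    def test_planted_scenario_counts(self, synth17):
        """On the synthetic study, tripartite class counts are recomputable
        from the association table and term memberships alone."""
        terms = synth17.truth.planted_terms
        net = build_tripartite(synth17.associations, synth17.annotation, terms)
        classes = nx.get_node_attributes(net, NODE_CLASS)
        assoc_genes = set(synth17.associations["gene"])
        expected_targets = set()
        for t in terms:
            expected_targets |= synth17.annotation.terms[t].genes & assoc_genes
        assert sum(1 for c in classes.values() if c == "target") == len(expected_targets)
        assert sum(1 for c in classes.values() if c == "pathway") == len(terms)


class TestSummary:
    def test_triangle_summary(self):
        report = network_summary(named(nx.complete_graph(3)))
        assert report["n_nodes"] == 3 and report["n_edges"] == 3
        assert report["mean_degree"] == pytest.approx(2.0)

    def test_empty_graph_all_zero(self):
        report = network_summary(nx.Graph())
        assert report["n_nodes"] == 0 and report["n_edges"] == 0
        assert report["mean_degree"] == 0.0 and report["top_by_degree"] == []

    def test_top_k_ties_break_lexicographically(self):
        g = nx.Graph([("B", "C"), ("A", "C"), ("A", "B")])
        report = network_summary(g, top_k=2)
        assert [e["node_id"] for e in report["top_by_degree"]] == ["A", "B"]

    def test_per_class_counts_on_bipartite(self, synth17):
        net = build_bipartite(synth17.associations)
        report = network_summary(net)
        assert report["class_counts"]["target"] == len(synth17.truth.drug_union)
        assert report["class_counts"]["ingredient"] == synth17.associations["mol_id"].nunique()
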