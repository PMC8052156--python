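"""Network construction and topology: PPI metrics, core-target selection,
and the bipartite / tripartite pharmacology networks.

All graphs are simple and undirected (:class:`networkx.Graph`); nodes carry
a ``node_class`` attribute in {ingredient, target, pathway}.  Two per-node
centralities drive hub selection: degree, and closeness centrality in one
of two normalizations:

``standard``
    |R(v)| / sum of shortest-path distances from v to its reachable set
    R(v) (v excluded); an isolated node scores 0.
``wf_scaled`` (default)
    the standard value additionally scaled by |R(v)| / (N - 1)
    (Wasserman-Faust), which keeps scores comparable across components of
    a disconnected graph.

The core-selection rule keeps every node whose degree AND closeness are
both at least the corresponding all-node network means (comparisons
inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .datatypes import NODE_CLASS, AnnotationDatabase, GeneSet

CLOSENESS_VARIANTS = ("standard", "wf_scaled")


@dataclass(frozen=True)
class NodeMetrics:
    """Degree and closeness of one node."""

    node_id: str
    degree: int
    closeness: float


@dataclass
class CoreSelection:
    """Result of the joint >=-average core-node rule."""

    mean_degree: float
    mean_closeness: float
    core_nodes: frozenset[str]
    metrics: pd.DataFrame  # columns: node_id, degree, closeness, is_core


def degree_profile(net: nx.Graph) -> dict[str, int]:
    """Per-node degree; the values sum to twice the edge count."""
    return {str(n): d for n, d in net.degree()}


def closeness_profile(net: nx.Graph, variant: str = "wf_scaled") -> dict[str, float]:
    """Per-node closeness centrality under the chosen normalization."""
    if variant not in CLOSENESS_VARIANTS:
        raise ValueError(f"variant must be one of {CLOSENESS_VARIANTS}, got {variant!r}")
    wf = variant == "wf_scaled"
    cc = nx.closeness_centrality(net, wf_improved=wf)
    return {str(n): float(c) for n, c in cc.items()}


def node_metrics_table(net: nx.Graph, variant: str = "wf_scaled") -> pd.DataFrame:
    """Degree and closeness for every node, sorted by node id."""
    deg = degree_profile(net)
    clo = closeness_profile(net, variant=variant)
    rows = [(n, deg[n], clo[n]) for n in sorted(deg)]
    return pd.DataFrame(rows, columns=["node_id", "degree", "closeness"])


def select_core_nodes(net: nx.Graph, variant: str = "wf_scaled") -> CoreSelection:
    """Nodes with degree and closeness both >= the all-node means.

    Raises
    ------
    ValueError
        On an empty graph (the means are undefined).
    """
    if net.number_of_nodes() == 0:
        raise ValueError("select_core_nodes: empty graph")
    table = node_metrics_table(net, variant=variant)
    mean_degree = float(table["degree"].mean())
    mean_closeness = float(table["closeness"].mean())
    is_core = (table["degree"] >= mean_degree) & (table["closeness"] >= mean_closeness)
    table = table.assign(is_core=is_core)
    core = frozenset(table.loc[is_core, "node_id"])
    return CoreSelection(
        mean_degree=mean_degree,
        mean_closeness=mean_closeness,
        core_nodes=core,
        metrics=table,
    )


def build_bipartite(assocs: pd.DataFrame) -> nx.Graph:
    """Ingredient-target network: one edge per (mol_id, gene) association.

    Node classes are ``ingredient`` and ``target``; ingredient node degree
    in this graph is the basis for ranking core ingredients.
    """
    net = nx.Graph()
    for row in assocs.itertuples(index=False):
        net.add_node(row.mol_id, **{NODE_CLASS: "ingredient"})
        net.add_node(row.gene, **{NODE_CLASS: "target"})
        net.add_edge(row.mol_id, row.gene)
    return net


def build_tripartite(
    assocs: pd.DataFrame,
    pathway_membership: AnnotationDatabase | dict[str, GeneSet],
    selected_terms: list[str],
) -> nx.Graph:
    """Ingredient-target-pathway network restricted to selected pathways.

    Retained targets are the genes of the selected terms that occur in the
    association table.  Retained ingredients are those with at least one
    association to a retained target.  Edges are the ingredient-target
    associations plus the target-pathway memberships.  Pathway nodes are
    always present; ingredients/targets with no retained edge are dropped.

    Raises
    ------
    KeyError
        If a selected term is absent from the membership database.
    """
    terms = (
        pathway_membership.terms
        if isinstance(pathway_membership, AnnotationDatabase)
        else pathway_membership
    )
    for term in selected_terms:
        if term not in terms:
            raise KeyError(f"selected term {term!r} not present in the pathway membership")

    assoc_genes = set(assocs["gene"]) if len(assocs) else set()
    net = nx.Graph()
    for term in selected_terms:
        net.add_node(term, **{NODE_CLASS: "pathway"})

    retained: set[str] = set()
    for term in selected_terms:
        for gene in terms[term].genes & assoc_genes:
            retained.add(gene)
            net.add_node(gene, **{NODE_CLASS: "target"})
            net.add_edge(gene, term)

    if retained and len(assocs):
        hits = assocs[assocs["gene"].isin(retained)]
        for row in hits.itertuples(index=False):
            net.add_node(row.mol_id, **{NODE_CLASS: "ingredient"})
            net.add_edge(row.mol_id, row.gene)
    return net


def network_summary(
    net: nx.Graph, variant: str = "wf_scaled", top_k: int = 10
) -> dict:
    """Topological report: size, means, per-class counts, top-degree nodes.

    Ties in the degree ranking are broken lexicographically by node id.
    An empty graph yields an all-zero report.
    """
    n = net.number_of_nodes()
    e = net.number_of_edges()
    if n == 0:
        return {
            "n_nodes": 0,
            "n_edges": 0,
            "mean_degree": 0.0,
            "mean_closeness": 0.0,
            "class_counts": {},
            "top_by_degree": [],
        }
    deg = degree_profile(net)
    clo = closeness_profile(net, variant=variant)
    class_counts: dict[str, int] = {}
    for _, data in net.nodes(data=True):
        cls = data.get(NODE_CLASS, "target")
        class_counts[cls] = class_counts.get(cls, 0) + 1
    ranked = sorted(deg.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
    return {
        "n_nodes": n,
        "n_edges": e,
        "mean_degree": 2.0 * e / n,
        "mean_closeness": sum(clo.values()) / n,
        "class_counts": dict(sorted(class_counts.items())),
        "top_by_degree": [{"node_id": k, "degree": v} for k, v in ranked],
    }
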