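"""Readers and writers for the delimited formats the pipeline touches.

Tab-separated values is the canonical tabular dialect (delimiter
configurable).  Gene-set databases travel as GMT, networks as two-column
TSV edge lists, SIF, or GraphML.  Every writer sorts its output so that
identical in-memory objects always serialize to identical bytes.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .datatypes import (
    NODE_CLASS,
    AnnotationDatabase,
    ConsistencyError,
    GeneSet,
    Ingredient,
    ParseError,
    SchemaError,
    SymbolMap,
)

logger = logging.getLogger(__name__)

#: Default column names for ingredient tables.
INGREDIENT_COLUMNS = {"mol_id": "mol_id", "name": "name", "ob": "ob", "dl": "dl"}


# ---------------------------------------------------------------------------
# Ingredient tables
# ---------------------------------------------------------------------------

def read_ingredient_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sep: str = "\t",
    default_source: str = "database",
) -> list[Ingredient]:
    """Read a compound table (one row per candidate ingredient).

    Parameters
    ----------
    path
        Delimited text file with a header row.
    dialect
        Mapping from the logical column names ``mol_id``, ``name``, ``ob``,
        ``dl`` to the actual column names in the file.  An optional
        ``source`` entry names a column holding ``database``/``literature``
        provenance flags.
    sep
        Field delimiter (default tab).
    default_source
        Provenance assigned to rows when the file has no source column.

    Raises
    ------
    SchemaError
        If a required column is missing (the message names it).
    ParseError
        If an OB or DL value is non-numeric (the message gives the row).
    ValueError
        If a molecule id occurs more than once.
    """
    cols = dict(INGREDIENT_COLUMNS)
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    for logical in ("mol_id", "name", "ob", "dl"):
        if cols[logical] not in df.columns:
            raise SchemaError(
                f"{path}: missing required column {cols[logical]!r} (for {logical})"
            )
    source_col = cols.get("source")
    has_source = source_col is not None and source_col in df.columns

    out: list[Ingredient] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        rec = dict(zip(df.columns, row))
        mol_id = str(rec[cols["mol_id"]]).strip()
        if mol_id in seen:
            raise ValueError(f"{path}: duplicate mol_id {mol_id!r} at row {i}")
        seen.add(mol_id)
        values = {}
        for attr in ("ob", "dl"):
            raw = rec[cols[attr]]
            try:
                values[attr] = float(raw)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: non-numeric {attr.upper()} value {raw!r} at row {i}"
                ) from None
        source = str(rec[source_col]).strip() if has_source else default_source
        out.append(
            Ingredient(
                mol_id=mol_id,
                name=str(rec[cols["name"]]).strip(),
                ob=values["ob"],
                dl=values["dl"],
                source=source,
            )
        )
    return out


def write_ingredient_table(
    ingredients: Iterable[Ingredient], path: str | Path, sep: str = "\t"
) -> None:
    """Write ingredients as a TSV with columns mol_id, name, ob, dl, source."""
    df = pd.DataFrame(
        [(i.mol_id, i.name, i.ob, i.dl, i.source) for i in ingredients],
        columns=["mol_id", "name", "ob", "dl", "source"],
    )
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Packaged reference compound tables
# ---------------------------------------------------------------------------

def load_plantaginis_ingredients() -> list[Ingredient]:
    """The packaged Plantaginis Herba compound table (15 database entries)."""
    ref = resources.files("phytonet") / "data" / "plantaginis_ingredients.tsv"
    with resources.as_file(ref) as p:
        return read_ingredient_table(p)


def load_plantaginis_literature() -> list[Ingredient]:
    """The five literature-reported anti-hyperuricemia compounds."""
    ref = resources.files("phytonet") / "data" / "plantaginis_literature.tsv"
    with resources.as_file(ref) as p:
        return read_ingredient_table(p, default_source="literature")


# ---------------------------------------------------------------------------
# Gene lists and symbol maps
# ---------------------------------------------------------------------------

def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain gene list: one symbol per line, ``#`` comments ignored."""
    out: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            out.append(line.split("\t")[0])
    return out


def write_gene_set(genes: GeneSet | Iterable[str], path: str | Path) -> None:
    """Write gene symbols one per line in lexicographic order."""
    symbols = genes.sorted_genes() if isinstance(genes, GeneSet) else sorted(set(genes))
    with open(path, "w") as fh:
        for g in symbols:
            fh.write(g + "\n")


def read_symbol_map(path: str | Path, sep: str = "\t") -> SymbolMap:
    """Read a two-column raw-id -> normalized-symbol mapping table."""
    entries: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split(sep)
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            entries[fields[0]] = fields[1]
    return SymbolMap(entries)


def write_symbol_map(symbol_map: SymbolMap, path: str | Path, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        for raw in sorted(symbol_map.entries):
            fh.write(f"{raw}{sep}{symbol_map.entries[raw]}\n")


# ---------------------------------------------------------------------------
# GMT gene-set databases
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, namespace: str = "pathway") -> AnnotationDatabase:
    """Read a GMT file (term <tab> description <tab> gene...).

    Raises
    ------
    ParseError
        For any line with fewer than three fields (the message gives the
        line number).
    ValueError
        For a duplicated term id.
    """
    terms: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >= 3 fields, got {len(fields)}"
                )
            term_id, description = fields[0], fields[1]
            if term_id in terms:
                raise ValueError(f"{path}:{lineno}: duplicate term id {term_id!r}")
            terms[term_id] = GeneSet.from_iterable(term_id, fields[2:], source=description)
    return AnnotationDatabase(terms=terms, namespace=namespace)


def write_gmt(db: AnnotationDatabase, path: str | Path) -> None:
    """Write an annotation database as GMT, terms and genes sorted."""
    with open(path, "w") as fh:
        for term_id in sorted(db.terms):
            gs = db.terms[term_id]
            desc = gs.source or db.namespace
            fh.write("\t".join([term_id, desc] + gs.sorted_genes()) + "\n")


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

def simplify_graph(graph: nx.Graph) -> nx.Graph:
    """Return a simple undirected copy: self-loops removed (count logged),
    duplicate/reversed edges collapsed.  Idempotent."""
    simple = nx.Graph()
    simple.add_nodes_from(graph.nodes(data=True))
    n_loops = 0
    for u, v, data in graph.edges(data=True):
        if u == v:
            n_loops += 1
            continue
        simple.add_edge(u, v, **data)
    if n_loops:
        logger.info("simplify_graph: dropped %d self-loop(s)", n_loops)
    return simple


def read_edge_list(
    path: str | Path,
    format: str = "tsv",
    min_score: float | None = None,
    node_class: str = "target",
) -> nx.Graph:
    """Read an undirected network from a TSV edge list or a SIF file.

    TSV lines are ``node_a <tab> node_b`` with an optional third numeric
    score column (STRING-style); ``min_score`` filters on it before graph
    construction, and by default all edges are kept.  SIF lines are
    ``node_a <interaction> node_b``.  The result is a simple graph: self
    loops are dropped (logged) and duplicate or reversed edges collapsed.
    """
    if format not in ("tsv", "sif"):
        raise ValueError(f"format must be 'tsv' or 'sif', got {format!r}")
    graph = nx.Graph()
    n_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if format == "sif":
                if len(fields) == 1:
                    graph.add_node(fields[0])
                    continue
                if len(fields) < 3:
                    raise ParseError(
                        f"{path}:{lineno}: SIF line needs 1 or >= 3 tokens"
                    )
                a, b = fields[0], fields[2]
            else:
                if len(fields) < 2:
                    raise ParseError(f"{path}:{lineno}: edge line needs 2 columns")
                a, b = fields[0], fields[1]
                if len(fields) >= 3 and min_score is not None:
                    try:
                        score = float(fields[2])
                    except ValueError:
                        raise ParseError(
                            f"{path}:{lineno}: non-numeric score {fields[2]!r}"
                        ) from None
                    if score < min_score:
                        continue
            if a == b:
                n_loops += 1
                graph.add_node(a)
                continue
            graph.add_edge(a, b)
    if n_loops:
        logger.info("read_edge_list: dropped %d self-loop(s)", n_loops)
    nx.set_node_attributes(graph, node_class, NODE_CLASS)
    return graph


def export_network(
    net: nx.Graph,
    path: str | Path,
    format: str = "tsv",
    interaction: str = "pp",
) -> None:
    """Write a network as a TSV edge list, SIF, or GraphML file.

    Isolated nodes are preserved in SIF (single-token lines) and GraphML;
    the TSV edge list carries edges only.  Edges are written with sorted
    endpoints in lexicographic order for reproducible output.
    """
    if format not in ("tsv", "sif", "graphml"):
        raise ValueError(f"format must be tsv, sif or graphml, got {format!r}")
    if format == "graphml":
        nx.write_graphml(net, path)
        return
    edges = sorted(tuple(sorted((str(u), str(v)))) for u, v in net.edges())
    with open(path, "w") as fh:
        if format == "tsv":
            for a, b in edges:
                fh.write(f"{a}\t{b}\n")
        else:
            for a, b in edges:
                fh.write(f"{a}\t{interaction}\t{b}\n")
            connected = {u for e in edges for u in e}
            for node in sorted(str(n) for n in net.nodes() if str(n) not in connected):
                fh.write(node + "\n")


def read_node_classes(path: str | Path, graph: nx.Graph, sep: str = "\t") -> None:
    """Attach node classes from a two-column sidecar (id <tab> class).

    Raises
    ------
    ConsistencyError
        If the sidecar references a node absent from the graph.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(sep)
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            node, cls = fields[0], fields[1]
            if node not in graph:
                raise ConsistencyError(
                    f"{path}:{lineno}: node {node!r} not present in the network"
                )
            graph.nodes[node][NODE_CLASS] = cls


# ---------------------------------------------------------------------------
# Target-association tables
# ---------------------------------------------------------------------------

def read_target_associations(
    path: str | Path, sep: str = "\t"
) -> pd.DataFrame:
    """Read an ingredient-target association table.

    Expects columns ``mol_id`` and ``gene`` (optional ``provenance``).
    Duplicate (mol_id, gene) pairs are collapsed; symbols are uppercased.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    for col in ("mol_id", "gene"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    if "provenance" not in df.columns:
        df["provenance"] = ""
    df = df.fillna({"provenance": ""})
    df["gene"] = df["gene"].str.upper()
    df = df.drop_duplicates(subset=["mol_id", "gene"]).reset_index(drop=True)
    return df[["mol_id", "gene", "provenance"]]


def write_target_associations(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    df = df.sort_values(["mol_id", "gene"]).reset_index(drop=True)
    df.to_csv(path, sep=sep, index=False)
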