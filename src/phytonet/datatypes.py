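"""Domain types shared by every pipeline stage.

The pipeline moves four kinds of objects between stages: candidate herbal
ingredients with their screening attributes, deduplicated gene-symbol sets,
annotation term databases (pathway or GO namespaces), and undirected networks
whose nodes are tagged as ingredient, target or pathway.  Networks themselves
are plain :class:`networkx.Graph` objects carrying a ``node_class`` attribute;
see :mod:`phytonet.networks`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

logger = logging.getLogger(__name__)

#: Node-attribute key holding the class tag of a network node.
NODE_CLASS = "node_class"

#: Legal node classes for tagged networks.
NODE_CLASSES = ("ingredient", "target", "pathway")

#: Legal annotation namespaces.
NAMESPACES = ("pathway", "go_bp", "go_mf", "go_cc")


class SchemaError(ValueError):
    """A tabular input is missing a required column."""


class ParseError(ValueError):
    """A value or line in an input file could not be parsed."""


class ConsistencyError(ValueError):
    """Cross-file references do not line up (e.g. dangling node ids)."""


@dataclass(frozen=True)
class Ingredient:
    """One candidate compound with its admissibility attributes.

    Parameters
    ----------
    mol_id : str
        Opaque molecule identifier, unique within a library.
    name : str
        Compound name (free text; may differ between sources).
    ob : float
        Oral bioavailability, percent on a 0-100 scale.
    dl : float
        Drug-likeness, unitless score >= 0.
    source : str
        Either ``"database"`` (screened from a compound database) or
        ``"literature"`` (added from published reports).
    """

    mol_id: str
    name: str
    ob: float
    dl: float
    source: str = "database"

    def __post_init__(self) -> None:
        if not self.mol_id:
            raise ValueError("mol_id must be non-empty")
        if self.ob < 0:
            raise ValueError(f"ob must be >= 0, got {self.ob}")
        if self.dl < 0:
            raise ValueError(f"dl must be >= 0, got {self.dl}")
        if self.source not in ("database", "literature"):
            raise ValueError(f"unknown ingredient source {self.source!r}")


@dataclass(frozen=True)
class GeneSet:
    """A named, deduplicated collection of normalized gene symbols."""

    set_id: str
    genes: frozenset[str]
    source: str = ""

    @classmethod
    def from_iterable(cls, set_id: str, genes: Iterable[str], source: str = "") -> "GeneSet":
        """Build a GeneSet, uppercasing and deduplicating symbols."""
        return cls(set_id=set_id, genes=frozenset(g.upper() for g in genes), source=source)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.genes)

    def __contains__(self, gene: object) -> bool:
        return gene in self.genes

    def sorted_genes(self) -> list[str]:
        """Lexicographically sorted symbols, the canonical serialization order."""
        return sorted(self.genes)


@dataclass
class AnnotationDatabase:
    """A collection of annotation terms (gene sets) in one namespace."""

    terms: dict[str, GeneSet]
    namespace: str = "pathway"

    def __post_init__(self) -> None:
        if self.namespace not in NAMESPACES:
            raise ValueError(
                f"namespace must be one of {NAMESPACES}, got {self.namespace!r}"
            )

    def __len__(self) -> int:
        return len(self.terms)

    def gene_universe(self) -> frozenset[str]:
        """Union of all genes annotated to any term."""
        out: set[str] = set()
        for gs in self.terms.values():
            out |= gs.genes
        return frozenset(out)


@dataclass
class SymbolMap:
    """Flat many-to-one lookup from raw identifiers to normalized gene symbols.

    Stand-in for an identifier-normalization service: the table is supplied by
    the user as data, and lookups are case-insensitive on the raw identifier.
    """

    entries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: dict[str, str] = {}
        for raw, sym in self.entries.items():
            if not sym:
                raise ValueError(f"empty normalized symbol for raw id {raw!r}")
            cleaned[raw.upper()] = sym.upper()
        self.entries = cleaned

    def get(self, raw: str) -> str | None:
        return self.entries.get(raw.upper())

    def __len__(self) -> int:
        return len(self.entries)


def normalize_symbols(
    raw: Iterable[str],
    symbol_map: SymbolMap | Mapping[str, str] | None = None,
    policy: str = "drop",
    set_id: str = "normalized",
    source: str = "",
) -> GeneSet:
    """Map raw identifiers to normalized symbols and deduplicate.

    Unmapped identifiers are dropped (``policy="drop"``, the default, which
    keeps the downstream intersection conservative) or kept verbatim but
    uppercased (``policy="keep"``).  Counts of mapped and unmapped inputs are
    logged.
    """
    if policy not in ("drop", "keep"):
        raise ValueError(f"policy must be 'drop' or 'keep', got {policy!r}")
    if symbol_map is None:
        symbol_map = SymbolMap({})
    elif not isinstance(symbol_map, SymbolMap):
        symbol_map = SymbolMap(dict(symbol_map))

    mapped: set[str] = set()
    n_mapped = 0
    n_unmapped = 0
    for ident in raw:
        sym = symbol_map.get(ident)
        if sym is None:
            # Identity mapping: an already-normalized symbol maps to itself.
            if ident.upper() in symbol_map.entries.values():
                sym = ident.upper()
        if sym is not None:
            mapped.add(sym)
            n_mapped += 1
        else:
            n_unmapped += 1
            if policy == "keep":
                mapped.add(ident.upper())
    logger.info(
        "normalize_symbols: %d mapped, %d unmapped (%s)", n_mapped, n_unmapped, policy
    )
    return GeneSet(set_id=set_id, genes=frozenset(mapped), source=source)
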