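"""Target-set assembly: disease-gene aggregation and the drug/disease overlap.

Disease genes arrive as one plain gene list per source database; they are
unioned with per-source bookkeeping.  Compound targets arrive as an
ingredient-target association table.  The overlap of the two sets — the
Venn-diagram stage of a network-pharmacology analysis — is the candidate
set of therapeutic targets carried into the interaction-network and
enrichment stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd

from .datatypes import GeneSet


@dataclass
class SourceReport:
    """Per-source sizes and the deduplicated union size."""

    sizes: dict[str, int] = field(default_factory=dict)
    union_size: int = 0

    def to_dict(self) -> dict:
        return {"sizes": dict(self.sizes), "union_size": self.union_size}


def aggregate_sources(sources: Sequence[GeneSet]) -> tuple[GeneSet, SourceReport]:
    """Union disease-gene sources, removing duplicates across sources.

    Returns the union (set_id ``"union"``) and a report of per-source sizes.
    At least one source is required.  The union is independent of source
    order; duplicate source ids are disambiguated positionally.
    """
    if not sources:
        raise ValueError("aggregate_sources requires at least one source")
    sizes: dict[str, int] = {}
    union: set[str] = set()
    for i, src in enumerate(sources):
        label = src.set_id or f"source_{i + 1}"
        if label in sizes:
            label = f"{label}_{i + 1}"
        sizes[label] = len(src)
        union |= src.genes
    report = SourceReport(sizes=sizes, union_size=len(union))
    return GeneSet(set_id="union", genes=frozenset(union)), report


def compound_target_union(assocs: pd.DataFrame) -> GeneSet:
    """Unique target genes across all ingredients of an association table."""
    if len(assocs) == 0:
        return GeneSet(set_id="drug_targets", genes=frozenset())
    return GeneSet.from_iterable("drug_targets", assocs["gene"])


def intersect_targets(drug: GeneSet, disease: GeneSet) -> GeneSet:
    """Exact intersection of drug and disease target sets."""
    return GeneSet(set_id="common_targets", genes=drug.genes & disease.genes)


def venn_report(named_sets: dict[str, GeneSet]) -> dict:
    """Counts for every non-empty intersection region of 2..n sets.

    Region keys join set ids with ``&``; values are exclusive region sizes
    (genes in exactly those sets).  Also reports per-set sizes and the
    overall union, so a two-set call reproduces the classic Venn diagram
    and the five-way disease aggregation is reportable the same way.
    """
    ids = sorted(named_sets)
    universe: set[str] = set()
    for gs in named_sets.values():
        universe |= gs.genes
    regions: dict[str, int] = {}
    for r in range(1, len(ids) + 1):
        for combo in combinations(ids, r):
            inside = set(universe)
            for sid in combo:
                inside &= named_sets[sid].genes
            for sid in ids:
                if sid not in combo:
                    inside -= named_sets[sid].genes
            if inside:
                regions["&".join(combo)] = len(inside)
    return {
        "sizes": {sid: len(named_sets[sid]) for sid in ids},
        "union_size": len(universe),
        "exclusive_regions": regions,
    }


def gene_sets_from_lists(named_lists: dict[str, Iterable[str]]) -> list[GeneSet]:
    """Convenience: build normalized GeneSets from raw symbol lists."""
    return [
        GeneSet.from_iterable(name, genes, source=name)
        for name, genes in named_lists.items()
    ]
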