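"""Synthetic study-data generators with recorded ground truth.

Every input the pipeline consumes — compound library, ingredient-target
associations, disease-gene source lists, interactome edge list, annotation
gene sets (GMT), and a symbol map — can be generated here with planted,
fully known structure: a planted drug/disease overlap, planted interactome
hubs, and planted enriched annotation terms.  The accompanying
:class:`SyntheticTruth` record determines the expected output of every
pipeline stage, which makes the whole pipeline testable offline.

Default magnitudes mirror a typical single-herb network-pharmacology
study: 15 active ingredients (10 screened + 5 literature-reported) drawing
~30 targets each from a 300-gene druggable pool (expected target union
~230); five disease sources sized 65/196/668/6/0 drawn from a 1200-gene
disease pool (expected union ~770); a planted drug-disease overlap of 41
genes; an Erdos-Renyi interactome on those 41 with 188 expected edges
(mean degree ~9.2) and 3 planted hubs boosted by 20 extra edges each; and
an annotation database of 100 background terms plus 3 planted terms whose
membership over-samples the query eightfold.

Determinism: every generator is a pure function of (config, seed).  A
single top-level seed is expanded per stage through
``numpy.random.SeedSequence(seed, spawn_key=(stage,))`` with fixed stage
indices (0 universe partition, 1 compound library, 2 target map, 3
disease sources, 4 interactome, 5 annotation database), so each dataset
component is reproducible on its own.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import AnnotationDatabase, GeneSet, Ingredient, SymbolMap
from .io import (
    write_gene_set,
    write_gmt,
    write_ingredient_table,
    write_symbol_map,
    write_target_associations,
    export_network,
)
from .screen import ScreenConfig

# Stage indices for per-generator sub-seed derivation.
_STAGE_PARTITION = 0
_STAGE_LIBRARY = 1
_STAGE_TARGETS = 2
_STAGE_SOURCES = 3
_STAGE_INTERACTOME = 4
_STAGE_ANNOTATION = 5


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic study.

    Counts must be positive where a component is enabled; fractions lie in
    [0, 1]; the seed is always passed separately to the generator calls.
    """

    # gene universe
    n_genes: int = 2000
    # compound library
    n_ingredients: int = 15          # final merged count (screened + literature)
    n_literature: int = 5
    n_screen_fail: int = 10          # decoy compounds failing the OB/DL screen
    # ingredient-target associations
    target_pool_size: int = 300
    targets_per_ingredient_mean: float = 30.0
    targets_per_ingredient_dispersion: float = 10.0
    # disease sources
    source_sizes: tuple[int, ...] = (65, 196, 668, 6, 0)
    source_overlap: float = 0.2      # fraction of a source drawn from earlier sources
    disease_pool_size: int = 1200
    # planted drug/disease overlap
    n_common: int = 41
    # interactome
    interactome_model: str = "erdos_renyi"
    expected_edges: float = 188.0
    edge_p: float | None = None      # overrides expected_edges when set
    n_hubs: int = 3
    hub_extra_edges: int = 20
    # annotation database
    n_terms: int = 100               # background terms
    n_planted_terms: int = 3
    term_size_min: int = 100
    term_size_max: int = 200
    enrichment_factor: float = 8.0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_literature > self.n_ingredients:
            raise ValueError("n_literature cannot exceed n_ingredients")
        if any(s < 0 for s in self.source_sizes):
            raise ValueError("source sizes must be >= 0")
        if not 0 <= self.source_overlap <= 1:
            raise ValueError("source_overlap must lie in [0, 1]")
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor must be >= 1")
        if self.interactome_model not in ("erdos_renyi", "configuration"):
            raise ValueError(f"unknown interactome model {self.interactome_model!r}")
        if self.n_common > min(self.target_pool_size, self.disease_pool_size):
            raise ValueError("n_common must fit inside both gene pools")
        if self.target_pool_size + self.disease_pool_size - self.n_common > self.n_genes:
            raise ValueError("target and disease pools do not fit the gene universe")
        if self.source_sizes and self.n_common > max(self.source_sizes):
            raise ValueError("n_common must fit inside the largest disease source")
        if not 0 < self.term_size_min <= self.term_size_max <= self.n_genes:
            raise ValueError("term sizes must satisfy 0 < min <= max <= n_genes")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside every generated dataset."""

    seed: int
    config: dict
    planted_overlap: list[str] = field(default_factory=list)
    planted_hubs: list[str] = field(default_factory=list)
    planted_terms: list[str] = field(default_factory=list)
    source_members: dict[str, list[str]] = field(default_factory=dict)
    drug_union: list[str] = field(default_factory=list)
    disease_union: list[str] = field(default_factory=list)
    per_ingredient_counts: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class _Partition:
    """Deterministic split of the gene universe into structural pools."""

    genes: tuple[str, ...]           # full universe
    planted: tuple[str, ...]         # drug-AND-disease genes (the overlap)
    target_pool: tuple[str, ...]     # druggable genes (includes planted)
    disease_pool: tuple[str, ...]    # disease genes (includes planted)


def gene_universe(cfg: GeneratorConfig) -> list[str]:
    """Synthetic symbols G000001..; deliberately not real HGNC names."""
    return [f"G{i:06d}" for i in range(1, cfg.n_genes + 1)]


def _partition(cfg: GeneratorConfig, seed: int) -> _Partition:
    rng = _rng(seed, _STAGE_PARTITION)
    genes = gene_universe(cfg)
    perm = rng.permutation(cfg.n_genes)
    shuffled = [genes[i] for i in perm]
    planted = tuple(sorted(shuffled[: cfg.n_common]))
    t_extra = shuffled[cfg.n_common : cfg.target_pool_size]
    d_lo = cfg.target_pool_size
    d_hi = cfg.target_pool_size + cfg.disease_pool_size - cfg.n_common
    d_extra = shuffled[d_lo:d_hi]
    return _Partition(
        genes=tuple(genes),
        planted=planted,
        target_pool=tuple(sorted(planted + tuple(t_extra))),
        disease_pool=tuple(sorted(planted + tuple(d_extra))),
    )


# ---------------------------------------------------------------------------
# Compound library
# ---------------------------------------------------------------------------

def _make_compounds(
    rng: np.random.Generator,
    n: int,
    ob_range: tuple[float, float],
    dl_range: tuple[float, float],
    source: str,
    prefix: str,
    start: int = 1,
) -> list[Ingredient]:
    obs = rng.uniform(*ob_range, size=n)
    dls = rng.uniform(*dl_range, size=n)
    return [
        Ingredient(
            mol_id=f"{prefix}{start + i:04d}",
            name=f"compound-{prefix.lower()}{start + i:04d}",
            ob=float(obs[i]),
            dl=float(dls[i]),
            source=source,
        )
        for i in range(n)
    ]


def gen_compound_library(
    cfg: GeneratorConfig,
    seed: int,
    n: int | None = None,
    ob_range: tuple[float, float] = (0.0, 100.0),
    dl_range: tuple[float, float] = (0.0, 1.0),
) -> list[Ingredient]:
    """Random compound table: OB ~ U(0, 100), DL ~ U(0, 1) by default.

    Under the default screen (OB >= 30, DL >= 0.18) the expected pass
    fraction is 0.70 * 0.82 = 0.574.
    """
    n = cfg.n_ingredients if n is None else n
    rng = _rng(seed, _STAGE_LIBRARY)
    return _make_compounds(rng, n, ob_range, dl_range, "database", "SYN")


def _study_library(
    cfg: GeneratorConfig, seed: int, screen: ScreenConfig
) -> tuple[list[Ingredient], list[Ingredient]]:
    """Database compounds (passers + decoys, id order) and literature list.

    Constructed so the screen retains exactly ``n_ingredients -
    n_literature`` compounds and the literature merge brings the total to
    ``n_ingredients``.
    """
    rng = _rng(seed, _STAGE_LIBRARY)
    n_pass = cfg.n_ingredients - cfg.n_literature
    passers = _make_compounds(
        rng, n_pass, (screen.ob_min, 100.0), (screen.dl_min, 1.0), "database", "SYN"
    )
    decoys = _make_compounds(
        rng, cfg.n_screen_fail, (0.0, screen.ob_min * 0.999), (0.0, 1.0),
        "database", "SYN", start=n_pass + 1,
    )
    literature = _make_compounds(
        rng, cfg.n_literature, (0.0, screen.ob_min * 0.999), (0.0, 1.0),
        "literature", "LIT",
    )
    return passers + decoys, literature


def study_mol_ids(cfg: GeneratorConfig) -> list[str]:
    """Molecule ids of the final merged ingredient set (screen + literature)."""
    n_pass = cfg.n_ingredients - cfg.n_literature
    return [f"SYN{i:04d}" for i in range(1, n_pass + 1)] + [
        f"LIT{i:04d}" for i in range(1, cfg.n_literature + 1)
    ]


# ---------------------------------------------------------------------------
# Ingredient-target associations
# ---------------------------------------------------------------------------

def gen_target_map(
    cfg: GeneratorConfig, seed: int, mol_ids: Sequence[str] | None = None
) -> tuple[pd.DataFrame, dict]:
    """Ingredient-target association table plus bookkeeping truth.

    Per-ingredient target counts follow a negative-binomial distribution
    (configured mean and dispersion, clipped to >= 1); targets are drawn
    without replacement from the druggable pool.  Every planted-overlap
    gene is assigned to at least one ingredient so the drug-target union
    provably contains the planted drug/disease overlap.
    """
    part = _partition(cfg, seed)
    rng = _rng(seed, _STAGE_TARGETS)
    ids = list(mol_ids) if mol_ids is not None else study_mol_ids(cfg)
    m = cfg.targets_per_ingredient_mean
    r = cfg.targets_per_ingredient_dispersion
    counts = rng.negative_binomial(r, r / (r + m), size=len(ids))
    counts = np.maximum(counts, 1)

    forced: dict[str, list[str]] = {i: [] for i in ids}
    for j, gene in enumerate(part.planted):
        forced[ids[j % len(ids)]].append(gene)

    rows: list[tuple[str, str, str]] = []
    pool = list(part.target_pool)
    for i, mol in enumerate(ids):
        chosen = set(forced[mol])
        want = max(int(counts[i]), len(chosen))
        remaining = sorted(set(pool) - chosen)
        extra = want - len(chosen)
        if extra > 0:
            picks = rng.choice(len(remaining), size=min(extra, len(remaining)), replace=False)
            chosen |= {remaining[p] for p in sorted(picks)}
        for gene in sorted(chosen):
            rows.append((mol, gene, "synthetic"))
    df = pd.DataFrame(rows, columns=["mol_id", "gene", "provenance"])
    truth = {
        "drug_union": sorted(df["gene"].unique()),
        "per_ingredient_counts": {k: int(v) for k, v in df.groupby("mol_id").size().items()},
        "planted_overlap": list(part.planted),
    }
    return df, truth


# ---------------------------------------------------------------------------
# Disease sources
# ---------------------------------------------------------------------------

def gen_disease_sources(
    cfg: GeneratorConfig, seed: int
) -> tuple[dict[str, list[str]], dict]:
    """Per-source disease gene lists with configured sizes and overlap.

    Sources are drawn from the disease pool; after the first non-empty
    source, a ``source_overlap`` fraction of each source is re-drawn from
    the union of earlier sources.  All planted-overlap genes are forced
    into the largest source, so the disease union provably contains them.

    Raises
    ------
    ValueError
        If a requested source size exceeds the disease pool.
    """
    part = _partition(cfg, seed)
    rng = _rng(seed, _STAGE_SOURCES)
    pool = list(part.disease_pool)
    sizes = cfg.source_sizes
    for s in sizes:
        if s > len(pool):
            raise ValueError(f"source size {s} exceeds the disease pool ({len(pool)})")
    largest = int(np.argmax(sizes)) if sizes else -1

    sources: dict[str, list[str]] = {}
    prev_union: set[str] = set()
    for i, s in enumerate(sizes):
        name = f"source_{i + 1}"
        members: set[str] = set(part.planted) if i == largest else set()
        if s < len(members):
            raise ValueError(f"source {name} (size {s}) cannot hold the planted overlap")
        candidates = sorted(prev_union - members)
        n_over = min(int(round(cfg.source_overlap * s)), len(candidates), s - len(members))
        if n_over > 0:
            picks = rng.choice(len(candidates), size=n_over, replace=False)
            members |= {candidates[p] for p in sorted(picks)}
        fresh = sorted(set(pool) - members)
        n_fresh = s - len(members)
        if n_fresh > 0:
            picks = rng.choice(len(fresh), size=n_fresh, replace=False)
            members |= {fresh[p] for p in sorted(picks)}
        sources[name] = sorted(members)
        prev_union |= members

    truth = {
        "source_members": {k: list(v) for k, v in sources.items()},
        "disease_union": sorted(prev_union),
        "planted_overlap": list(part.planted),
    }
    return sources, truth


# ---------------------------------------------------------------------------
# Interactome
# ---------------------------------------------------------------------------

def gen_interactome(
    nodes: Sequence[str] | GeneSet,
    cfg: GeneratorConfig,
    seed: int,
) -> tuple[nx.Graph, list[str]]:
    """Random simple undirected interactome on the given nodes.

    Under ``erdos_renyi`` each pair is an edge independently with
    probability ``edge_p`` (or ``expected_edges / C(N, 2)``); under
    ``configuration`` a Poisson degree sequence of matching mean is
    realized and simplified.  ``n_hubs`` planted hubs then each gain
    ``hub_extra_edges`` edges to uniformly chosen non-neighbors, pushing
    their degree well above the graph mean.  Returns the graph and the
    planted hub ids.

    Raises
    ------
    ValueError
        If the node set is empty or the requested edges exceed N(N-1)/2.
    """
    node_list = sorted(nodes.genes) if isinstance(nodes, GeneSet) else sorted(nodes)
    n = len(node_list)
    if n == 0:
        raise ValueError("gen_interactome: empty node set")
    max_edges = n * (n - 1) // 2
    if cfg.edge_p is None and cfg.expected_edges > max_edges:
        raise ValueError(
            f"expected_edges={cfg.expected_edges} exceeds the {max_edges} possible edges"
        )
    rng = _rng(seed, _STAGE_INTERACTOME)
    graph = nx.Graph()
    graph.add_nodes_from(node_list)

    if cfg.interactome_model == "erdos_renyi":
        p = cfg.edge_p if cfg.edge_p is not None else cfg.expected_edges / max(max_edges, 1)
        if max_edges > 0:
            draws = rng.random(max_edges)
            idx = 0
            for i in range(n):
                for j in range(i + 1, n):
                    if draws[idx] < p:
                        graph.add_edge(node_list[i], node_list[j])
                    idx += 1
    else:  # configuration model
        mean_degree = 2.0 * cfg.expected_edges / n
        degrees = rng.poisson(mean_degree, size=n)
        if degrees.sum() % 2:
            degrees[-1] += 1
        multigraph = nx.configuration_model(degrees.tolist(), seed=int(rng.integers(2**31)))
        simple = nx.Graph()
        simple.add_nodes_from(range(n))
        simple.add_edges_from((u, v) for u, v in multigraph.edges() if u != v)
        graph = nx.relabel_nodes(simple, dict(enumerate(node_list)))

    hubs: list[str] = []
    if cfg.n_hubs > 0:
        picks = rng.choice(n, size=min(cfg.n_hubs, n), replace=False)
        hubs = sorted(node_list[p] for p in sorted(picks))
        for hub in hubs:
            non_neighbors = sorted(set(node_list) - set(graph.neighbors(hub)) - {hub})
            k = min(cfg.hub_extra_edges, len(non_neighbors))
            if k > 0:
                chosen = rng.choice(len(non_neighbors), size=k, replace=False)
                for c in sorted(chosen):
                    graph.add_edge(hub, non_neighbors[c])
    return graph, hubs


# ---------------------------------------------------------------------------
# Annotation database
# ---------------------------------------------------------------------------

def gen_annotation_db(
    cfg: GeneratorConfig,
    query: GeneSet | Sequence[str],
    seed: int,
    namespace: str = "pathway",
) -> tuple[AnnotationDatabase, list[str]]:
    """Annotation gene sets with optionally planted enrichment.

    Background terms sample genes uniformly from the universe; planted
    terms sample with the query genes over-weighted by
    ``enrichment_factor``, which makes them genuinely over-represented in
    the query.  With ``enrichment_factor == 1`` no term is planted (a null
    database).  Returns the database and the planted term ids.
    """
    if cfg.enrichment_factor < 1:
        raise ValueError("enrichment_factor must be >= 1")
    rng = _rng(seed, _STAGE_ANNOTATION)
    universe = gene_universe(cfg)
    query_set = query.genes if isinstance(query, GeneSet) else frozenset(query)
    n_planted = cfg.n_planted_terms if cfg.enrichment_factor > 1 else 0
    total = cfg.n_terms + n_planted

    weights = np.ones(len(universe))
    if n_planted:
        in_query = np.array([g in query_set for g in universe])
        weights[in_query] = cfg.enrichment_factor
    weights /= weights.sum()

    sizes = rng.integers(cfg.term_size_min, cfg.term_size_max + 1, size=total)
    terms: dict[str, GeneSet] = {}
    planted_ids: list[str] = []
    for t in range(total):
        term_id = f"T{t + 1:04d}"
        planted = t >= cfg.n_terms
        if planted:
            idx = rng.choice(len(universe), size=int(sizes[t]), replace=False, p=weights)
            planted_ids.append(term_id)
        else:
            idx = rng.choice(len(universe), size=int(sizes[t]), replace=False)
        terms[term_id] = GeneSet.from_iterable(
            term_id, (universe[i] for i in sorted(idx)),
            source="planted" if planted else "background",
        )
    return AnnotationDatabase(terms=terms, namespace=namespace), planted_ids


# ---------------------------------------------------------------------------
# Whole datasets
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """All generated inputs plus their ground truth."""

    config: GeneratorConfig
    seed: int
    database_compounds: list[Ingredient]
    literature_compounds: list[Ingredient]
    associations: pd.DataFrame
    sources: dict[str, list[str]]
    interactome: nx.Graph
    annotation: AnnotationDatabase
    symbol_map: SymbolMap
    truth: SyntheticTruth
    paths: dict[str, Path] = field(default_factory=dict)


def generate_dataset(
    cfg: GeneratorConfig | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
    screen: ScreenConfig | None = None,
) -> SyntheticDataset:
    """Generate a complete synthetic study (optionally written to disk).

    The emitted files (when ``outdir`` is given): ``ingredients.tsv``,
    ``literature.tsv``, ``associations.tsv``, ``source_*.tsv``,
    ``ppi_edges.tsv``, ``pathways.gmt``, ``symbol_map.tsv`` and
    ``truth.json``.  Identical (config, seed) pairs produce byte-identical
    files.
    """
    cfg = cfg or GeneratorConfig()
    screen = screen or ScreenConfig()
    part = _partition(cfg, seed)
    database_compounds, literature_compounds = _study_library(cfg, seed, screen)
    mol_ids = study_mol_ids(cfg)
    assocs, t_truth = gen_target_map(cfg, seed, mol_ids=mol_ids)
    sources, s_truth = gen_disease_sources(cfg, seed)
    interactome, hubs = gen_interactome(part.planted, cfg, seed)
    annotation, planted_terms = gen_annotation_db(cfg, part.planted, seed)
    symbol_map = SymbolMap({g: g for g in part.genes})

    truth = SyntheticTruth(
        seed=seed,
        config=asdict(cfg),
        planted_overlap=list(part.planted),
        planted_hubs=hubs,
        planted_terms=planted_terms,
        source_members=s_truth["source_members"],
        drug_union=t_truth["drug_union"],
        disease_union=s_truth["disease_union"],
        per_ingredient_counts=t_truth["per_ingredient_counts"],
    )
    ds = SyntheticDataset(
        config=cfg,
        seed=seed,
        database_compounds=database_compounds,
        literature_compounds=literature_compounds,
        associations=assocs,
        sources=sources,
        interactome=interactome,
        annotation=annotation,
        symbol_map=symbol_map,
        truth=truth,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "ingredients": outdir / "ingredients.tsv",
            "literature": outdir / "literature.tsv",
            "associations": outdir / "associations.tsv",
            "ppi_edges": outdir / "ppi_edges.tsv",
            "gmt": outdir / "pathways.gmt",
            "symbol_map": outdir / "symbol_map.tsv",
            "truth": outdir / "truth.json",
        }
        write_ingredient_table(database_compounds, paths["ingredients"])
        write_ingredient_table(literature_compounds, paths["literature"])
        write_target_associations(assocs, paths["associations"])
        for name, members in sources.items():
            p = outdir / f"{name}.tsv"
            paths[name] = p
            write_gene_set(members, p)
        export_network(interactome, paths["ppi_edges"], format="tsv")
        write_gmt(annotation, paths["gmt"])
        write_symbol_map(symbol_map, paths["symbol_map"])
        truth.save(paths["truth"])
        ds.paths = paths
    return ds
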