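"""End-to-end orchestration of the network-pharmacology stages.

Stage order follows the study design: compound screen -> literature merge
-> compound-target union -> disease-source aggregation -> drug/disease
intersection -> interaction-network metrics and core-target selection ->
over-representation enrichment -> tripartite ingredient-target-pathway
network.  Each stage writes its output file before the next stage begins,
every serialized artifact is sorted, and a rerun with identical inputs
reproduces identical bytes.  The run report records every stage count,
the configuration echo and SHA-256 checksums of the inputs, so a report
is auditable against the files it describes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import networkx as nx

from ._version import __version__
from .datatypes import NODE_CLASS, GeneSet, normalize_symbols
from .enrich import EnrichConfig, enrich, records_to_frame
from .io import (
    export_network,
    read_edge_list,
    read_gene_list,
    read_gmt,
    read_ingredient_table,
    read_symbol_map,
    read_target_associations,
    write_gene_set,
    write_ingredient_table,
)
from .networks import (
    build_tripartite,
    network_summary,
    select_core_nodes,
)
from .screen import ScreenConfig, merge_with_literature, screen_ingredients
from .targets import (
    aggregate_sources,
    compound_target_union,
    intersect_targets,
    venn_report,
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated inputs and options for one pipeline run."""

    ingredient_table: str
    association_table: str
    disease_sources: list[str]
    ppi_edges: str
    gmt: str
    outdir: str
    literature_table: str | None = None
    symbol_map: str | None = None
    gmt_namespace: str = "pathway"
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    enrich: EnrichConfig = field(default_factory=EnrichConfig)
    selected_terms: list[str] | None = None
    top_k: int = 6
    closeness_variant: str = "wf_scaled"
    min_score: float | None = None
    seed: int = 0

    def validate(self) -> None:
        """Check every referenced input path exists before any stage runs."""
        paths = [self.ingredient_table, self.association_table, self.ppi_edges, self.gmt]
        paths += list(self.disease_sources)
        if self.literature_table:
            paths.append(self.literature_table)
        if self.symbol_map:
            paths.append(self.symbol_map)
        missing = [p for p in paths if not Path(p).is_file()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {', '.join(map(str, missing))}")
        if not self.disease_sources:
            raise ValueError("at least one disease source is required")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        if "screen" in raw and isinstance(raw["screen"], dict):
            raw["screen"] = ScreenConfig(**raw["screen"])
        if "enrich" in raw and isinstance(raw["enrich"], dict):
            enr = dict(raw["enrich"])
            if enr.get("background"):
                enr["background"] = frozenset(enr["background"])
            raw["enrich"] = EnrichConfig(**enr)
        return cls(**raw)

    def to_dict(self) -> dict:
        out = asdict(self)
        if out["enrich"].get("background"):
            out["enrich"]["background"] = sorted(out["enrich"]["background"])
        # the output location is not part of the scientific configuration,
        # and keeping it out makes reruns into fresh directories byte-identical
        out.pop("outdir")
        return out


@dataclass
class RunReport:
    """Machine-readable record of every stage's counts."""

    version: str = __version__
    config: dict = field(default_factory=dict)
    input_checksums: dict[str, str] = field(default_factory=dict)
    stages: dict[str, Any] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        return cls(**json.loads(text))

    def to_text(self) -> str:
        lines = [f"phytonet {self.version} run report"]
        for stage, info in self.stages.items():
            if isinstance(info, dict):
                parts = ", ".join(f"{k}={v}" for k, v in sorted(info.items()))
            else:
                parts = str(info)
            lines.append(f"  {stage}: {parts}")
        return "\n".join(lines) + "\n"


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute every stage in order, writing outputs under ``cfg.outdir``.

    On a stage failure the partial report written so far is saved and a
    :class:`PipelineError` naming the stage is raised.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    report = RunReport(config=cfg.to_dict())
    for key in ("ingredient_table", "association_table", "ppi_edges", "gmt",
                "literature_table", "symbol_map"):
        path = getattr(cfg, key)
        if path:
            report.input_checksums[key] = _sha256(path)
    for i, src in enumerate(cfg.disease_sources):
        report.input_checksums[f"disease_source_{i + 1}"] = _sha256(src)

    def _write_partial() -> None:
        (outdir / "report.json").write_text(report.to_json() + "\n")

    symbol_map = read_symbol_map(cfg.symbol_map) if cfg.symbol_map else None

    stage = "screen"
    try:
        library = read_ingredient_table(cfg.ingredient_table)
        screened = screen_ingredients(library, cfg.screen)
        write_ingredient_table(screened, outdir / "screened.tsv")
        report.stages["screen"] = {"library": len(library), "screened": len(screened)}

        stage = "merge"
        literature = (
            read_ingredient_table(cfg.literature_table, default_source="literature")
            if cfg.literature_table
            else []
        )
        merged = merge_with_literature(screened, literature)
        write_ingredient_table(merged, outdir / "merged.tsv")
        report.stages["merge"] = {"literature": len(literature), "merged": len(merged)}

        stage = "drug_targets"
        assocs = read_target_associations(cfg.association_table)
        merged_ids = {i.mol_id for i in merged}
        assocs = assocs[assocs["mol_id"].isin(merged_ids)].reset_index(drop=True)
        if symbol_map is not None:
            mapped = assocs["gene"].map(lambda g: symbol_map.get(g))
            assocs = assocs.assign(gene=mapped).dropna(subset=["gene"])
            assocs = assocs.drop_duplicates(subset=["mol_id", "gene"]).reset_index(drop=True)
        drug = compound_target_union(assocs)
        write_gene_set(drug, outdir / "drug_targets.tsv")
        report.stages["drug_targets"] = {
            "associations": len(assocs), "unique_targets": len(drug),
        }

        stage = "disease"
        sources = []
        for i, src in enumerate(cfg.disease_sources):
            name = Path(src).stem
            raw = read_gene_list(src)
            gs = (
                normalize_symbols(raw, symbol_map, set_id=name, source=name)
                if symbol_map is not None
                else GeneSet.from_iterable(name, raw, source=name)
            )
            sources.append(gs)
        disease, src_report = aggregate_sources(sources)
        write_gene_set(disease, outdir / "disease_targets.tsv")
        report.stages["disease"] = {
            "sources": src_report.sizes, "union": src_report.union_size,
        }

        stage = "intersect"
        common = intersect_targets(drug, disease)
        write_gene_set(common, outdir / "common_targets.tsv")
        venn = venn_report({"drug": drug, "disease": disease})
        (outdir / "venn.json").write_text(json.dumps(venn, indent=2, sort_keys=True) + "\n")
        report.stages["intersect"] = {"common_targets": len(common)}
        if len(common) == 0:
            raise PipelineError(
                "intersect",
                "drug and disease target sets share no genes; "
                "cannot build the interaction network",
            )

        stage = "ppi"
        full = read_edge_list(cfg.ppi_edges, format="tsv", min_score=cfg.min_score)
        ppi = nx.Graph(full.subgraph(common.genes))
        ppi.add_nodes_from(common.genes)  # keep isolated common targets
        nx.set_node_attributes(ppi, "target", NODE_CLASS)
        core = select_core_nodes(ppi, variant=cfg.closeness_variant)
        metrics = core.metrics
        metrics.to_csv(outdir / "ppi_metrics.tsv", sep="\t", index=False)
        with open(outdir / "core_targets.txt", "w") as fh:
            for node in sorted(core.core_nodes):
                fh.write(node + "\n")
        export_network(ppi, outdir / "ppi_network.sif", format="sif")
        report.stages["ppi"] = {
            "nodes": ppi.number_of_nodes(),
            "edges": ppi.number_of_edges(),
            "mean_degree": round(core.mean_degree, 6),
            "mean_closeness": round(core.mean_closeness, 6),
            "core_targets": len(core.core_nodes),
        }

        stage = "enrich"
        db = read_gmt(cfg.gmt, namespace=cfg.gmt_namespace)
        records = enrich(common, db, cfg.enrich)
        records_to_frame(records).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        report.stages["enrich"] = {
            "terms_tested": len(records),
            "pass_p": sum(r.pass_p for r in records),
            "pass_fdr": sum(r.pass_fdr for r in records),
        }

        stage = "tripartite"
        if cfg.selected_terms is not None:
            selected = list(cfg.selected_terms)
        else:
            selected = [r.term_id for r in records[: cfg.top_k]]
        tri = build_tripartite(assocs, db, selected)
        export_network(tri, outdir / "tripartite.graphml", format="graphml")
        nodes_rows = sorted(
            (str(n), d.get(NODE_CLASS, ""), tri.degree(n)) for n, d in tri.nodes(data=True)
        )
        with open(outdir / "tripartite_nodes.tsv", "w") as fh:
            fh.write("node_id\tnode_class\tdegree\n")
            for nid, cls, deg in nodes_rows:
                fh.write(f"{nid}\t{cls}\t{deg}\n")
        summary = network_summary(tri, variant=cfg.closeness_variant)
        report.stages["tripartite"] = {
            "selected_terms": selected,
            "nodes": summary["n_nodes"],
            "edges": summary["n_edges"],
            "class_counts": summary["class_counts"],
        }
    except PipelineError:
        _write_partial()
        raise
    except Exception as exc:
        _write_partial()
        raise PipelineError(stage, str(exc)) from exc

    (outdir / "report.json").write_text(report.to_json() + "\n")
    (outdir / "report.txt").write_text(report.to_text())
    return report
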