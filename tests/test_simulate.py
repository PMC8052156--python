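"""Synthetic-data generators: determinism, configured sizes, planted truth."""

import filecmp

import networkx as nx
import numpy as np
import pytest

from phytonet import (
    GeneSet,
    generate_dataset,
    select_core_nodes,
)
from phytonet.simulate import (
    GeneratorConfig,
    gen_annotation_db,
    gen_compound_library,
    gen_disease_sources,
    gen_interactome,
    gen_target_map,
)
from phytonet.screen import ScreenConfig, screen_ingredients


class TestCompoundLibrary:
    def test_screen_pass_rate_near_uniform_product(self):
        """OB ~ U(0,100), DL ~ U(0,1): pass fraction of the default screen
        is P(OB>=30)*P(DL>=0.18) = 0.7*0.82 = 0.574."""
        cfg = GeneratorConfig()
        lib = gen_compound_library(cfg, seed=1, n=1000)
        rate = len(screen_ingredients(lib, ScreenConfig())) / 1000
        assert abs(rate - 0.574) < 0.05

    def test_empty_library(self):
        assert gen_compound_library(GeneratorConfig(), seed=1, n=0) == []

    def test_same_seed_identical(self):
        cfg = GeneratorConfig()
        assert gen_compound_library(cfg, seed=9) == gen_compound_library(cfg, seed=9)


class TestTargetMap:
    def test_union_bounded_by_total_draws(self):
        cfg = GeneratorConfig()
        df, truth = gen_target_map(cfg, seed=2)
        assert len(truth["drug_union"]) <= len(df)
        assert set(truth["drug_union"]) == set(df["gene"])

    def test_counts_recount_from_table(self):
        df, truth = gen_target_map(GeneratorConfig(), seed=3)
        recount = df.groupby("mol_id").size().to_dict()
        assert truth["per_ingredient_counts"] == recount

    def test_planted_overlap_genes_all_assigned(self):
        df, truth = gen_target_map(GeneratorConfig(), seed=4)
        assert set(truth["planted_overlap"]) <= set(df["gene"])

    def test_pairs_unique(self):
        df, _ = gen_target_map(GeneratorConfig(), seed=5)
        assert not df.duplicated(subset=["mol_id", "gene"]).any()


class TestDiseaseSources:
    def test_sizes_exactly_as_configured(self):
        sources, _ = gen_disease_sources(GeneratorConfig(), seed=1)
        assert [len(m) for m in sources.values()] == [65, 196, 668, 6, 0]

    def test_zero_overlap_disjoint_sum(self):
        cfg = GeneratorConfig(source_sizes=(50, 60, 70), source_overlap=0.0,
                              n_common=41, disease_pool_size=1200)
        sources, truth = gen_disease_sources(cfg, seed=2)
        # overlap can still arise by chance from the shared pool, but the
        # union equals a brute-force recount regardless
        brute = set()
        for m in sources.values():
            brute |= set(m)
        assert set(truth["disease_union"]) == brute

    def test_oversized_source_rejected(self):
        cfg = GeneratorConfig(source_sizes=(1300,), disease_pool_size=1200)
        with pytest.raises(ValueError):
            gen_disease_sources(cfg, seed=1)

    def test_planted_overlap_inside_largest_source(self):
        sources, truth = gen_disease_sources(GeneratorConfig(), seed=6)
        largest = max(sources.values(), key=len)
        assert set(truth["planted_overlap"]) <= set(largest)


class TestInteractome:
    def test_expected_mean_degree_across_seeds(self):
        """ER with 188 expected edges on 41 nodes: realized mean degree
        stays within 1.5 of 2*188/41 = 9.17 across seeds (no hubs)."""
        cfg = GeneratorConfig(n_hubs=0)
        nodes = [f"G{i:03d}" for i in range(41)]
        means = []
        for seed in range(100):
            g, _ = gen_interactome(nodes, cfg, seed)
            means.append(2 * g.number_of_edges() / 41)
        assert abs(np.mean(means) - 9.17) < 1.5
        assert all(abs(m - 9.17) < 5 for m in means)

    def test_p_one_gives_complete_graph(self):
        cfg = GeneratorConfig(edge_p=1.0, n_hubs=0)
        g, _ = gen_interactome([f"N{i}" for i in range(10)], cfg, seed=0)
        assert g.number_of_edges() == 45

    def test_planted_hub_lands_in_core(self):
        cfg = GeneratorConfig(edge_p=0.08, n_hubs=1, hub_extra_edges=20)
        g, hubs = gen_interactome([f"N{i:02d}" for i in range(41)], cfg, seed=3)
        assert set(hubs) <= select_core_nodes(g).core_nodes

    def test_too_many_edges_rejected(self):
        cfg = GeneratorConfig(expected_edges=1000.0)
        with pytest.raises(ValueError):
            gen_interactome([f"N{i}" for i in range(10)], cfg, seed=0)

    def test_empty_node_set_rejected(self):
        with pytest.raises(ValueError):
            gen_interactome([], GeneratorConfig(), seed=0)

    def test_configuration_model_is_simple(self):
        cfg = GeneratorConfig(interactome_model="configuration", n_hubs=0)
        g, _ = gen_interactome([f"N{i:02d}" for i in range(41)], cfg, seed=1)
        assert not any(u == v for u, v in g.edges())
        assert isinstance(g, nx.Graph)


class TestAnnotationDb:
    def test_factor_one_plants_nothing(self):
        cfg = GeneratorConfig(enrichment_factor=1.0)
        db, planted = gen_annotation_db(cfg, GeneSet.from_iterable("q", ["G000001"]), seed=1)
        assert planted == []
        assert len(db.terms) == cfg.n_terms

    def test_factor_below_one_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(enrichment_factor=0.5)

    def test_same_seed_identical_terms(self):
        cfg = GeneratorConfig()
        q = GeneSet.from_iterable("q", [f"G{i:06d}" for i in range(1, 42)])
        db1, p1 = gen_annotation_db(cfg, q, seed=7)
        db2, p2 = gen_annotation_db(cfg, q, seed=7)
        assert p1 == p2
        assert {t: gs.genes for t, gs in db1.terms.items()} == {
            t: gs.genes for t, gs in db2.terms.items()
        }

    def test_term_sizes_within_configured_range(self):
        cfg = GeneratorConfig()
        db, _ = gen_annotation_db(cfg, GeneSet.from_iterable("q", ["G000001"]), seed=2)
        assert all(
            cfg.term_size_min <= len(gs) <= cfg.term_size_max for gs in db.terms.values()
        )


class TestWholeDataset:
    def test_byte_identical_files_for_same_seed(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        ds1 = generate_dataset(seed=5, outdir=d1)
        ds2 = generate_dataset(seed=5, outdir=d2)
        for key in ds1.paths:
            assert filecmp.cmp(ds1.paths[key], ds2.paths[key], shallow=False), key

    def test_truth_counts_equal_file_recounts(self, synth17):
        ds = synth17
        import pandas as pd

        assocs = pd.read_csv(ds.paths["associations"], sep="\t", dtype=str)
        assert sorted(assocs["gene"].unique()) == ds.truth.drug_union
        union = set()
        for i in range(1, 6):
            with open(ds.paths[f"source_{i}"]) as fh:
                union |= {line.strip() for line in fh if line.strip()}
        assert sorted(union) == ds.truth.disease_union

    def test_screen_and_merge_recover_configured_count(self, synth17):
        from phytonet import merge_with_literature

        screened = screen_ingredients(synth17.database_compounds, ScreenConfig())
        merged = merge_with_literature(screened, synth17.literature_compounds)
        assert len(merged) == synth17.config.n_ingredients
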