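"""The synthetic-data generator: determinism, planted structure, recovery."""

import numpy as np
import pytest

from gwas2drug.benchmarks import citation_benchmark, mann_whitney_auc
from gwas2drug.drug_db import parse_drug_export, venn_regions
from gwas2drug.gene_prediction import (
    predict_cmp,
    predict_cps,
    predict_crt,
    predict_mir,
    predict_ppi,
)
from gwas2drug.gwas_loci import build_all_search_spaces, stratify_snps
from gwas2drug.synthetic import (
    STRATUM_P_RANGES,
    generate_annotations,
    generate_citations,
    generate_drug_databases,
    generate_genome,
    generate_gwas,
)


class TestGenome:
    def test_counts_and_chromosomes(self):
        genes = generate_genome(n_chrom=2, n_genes=100, mean_gene_len=10_000,
                                mean_gap=50_000, seed=7)
        assert len(genes) == 100
        assert {g.chrom for g in genes} == {"chr1", "chr2"}

    def test_deterministic_under_seed(self):
        a = generate_genome(seed=7)
        b = generate_genome(seed=7)
        assert a == b

    def test_zero_genes(self):
        assert generate_genome(n_genes=0, seed=1) == []

    def test_genes_do_not_overlap_within_chromosome(self):
        genes = generate_genome(n_chrom=3, n_genes=300, seed=2)
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for gs in by_chrom.values():
            gs.sort(key=lambda g: g.start)
            assert all(a.end <= b.start for a, b in zip(gs, gs[1:]))

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError):
            generate_genome(n_chrom=1, n_genes=100, mean_gene_len=10_000,
                            mean_gap=10_000, seed=1, max_chrom_len=50_000)


class TestGwas:
    def test_one_locus_per_stratum_recovers_nested_sizes(self):
        genome = generate_genome(n_genes=50, seed=3)
        sim = generate_gwas(genome, n_disease_loci=4,
                            strata_mix={"HS": 1, "MHS": 1, "MWS": 1, "WS": 1},
                            n_null_snps=10, seed=3)
        strata = stratify_snps(sim.snps)
        assert [len(s) for s in strata] == [1, 2, 3, 4]

    def test_planted_pvalues_obey_stratum_bounds(self):
        genome = generate_genome(n_genes=100, seed=4)
        sim = generate_gwas(genome, seed=4)
        by_id = {s.snp_id: s for s in sim.snps}
        for snp_id, label in sim.planted_snps.items():
            lo, hi = STRATUM_P_RANGES[label]
            assert lo < by_id[snp_id].p_value <= hi

    def test_no_disease_loci_means_empty_ws(self):
        genome = generate_genome(n_genes=50, seed=5)
        sim = generate_gwas(genome, n_disease_loci=0, strata_mix={}, n_null_snps=30, seed=5)
        strata = stratify_snps(sim.snps)
        assert all(len(s) == 0 for s in strata)

    def test_planted_snp_sits_inside_its_gene(self):
        genome = generate_genome(n_genes=100, seed=6)
        sim = generate_gwas(genome, seed=6)
        genes = {g.symbol: g for g in genome}
        for snp, gene_sym in zip(sim.snps[: len(sim.planted_genes)], sim.planted_genes):
            g = genes[gene_sym]
            assert g.start < snp.pos <= g.end and snp.chrom == g.chrom

    def test_more_loci_than_genes_rejected(self):
        genome = generate_genome(n_genes=5, seed=1)
        with pytest.raises(ValueError):
            generate_gwas(genome, n_disease_loci=10, strata_mix={"WS": 10}, seed=1)


class TestAnnotations:
    def _setup(self, decoy_density, seed=8):
        genome = generate_genome(n_genes=200, seed=seed)
        gwas = generate_gwas(genome, n_disease_loci=10,
                             strata_mix={"HS": 2, "MHS": 2, "MWS": 3, "WS": 3},
                             n_null_snps=50, seed=seed)
        ann = generate_annotations(genome, gwas.planted_genes,
                                   decoy_density=decoy_density, seed=seed)
        strata = stratify_snps(gwas.snps)
        spaces = build_all_search_spaces(strata, genome)
        ws = [s for s in spaces if s.stratum_label == "WS"]
        return ann, ws

    def test_zero_decoys_recover_exactly_the_designated_subsets(self):
        ann, ws = self._setup(decoy_density=0.0)
        groups = {}
        for g, m in ann.module_assignment.items():
            groups.setdefault(m, set()).add(g)
        predicted = {m: set() for m in ("CPS", "PPI", "CMP", "CRT", "MIR")}
        for s in ws:
            predicted["CPS"] |= {p.gene for p in predict_cps(s, ann.tables["pathway"])}
            predicted["PPI"] |= {p.gene for p in predict_ppi(s, ann.tables["interaction"])}
            predicted["CMP"] |= {
                p.gene for p in predict_cmp(s, ann.tables["domain"], ann.seed_genes)
            }
            predicted["CRT"] |= {p.gene for p in predict_crt(s, ann.tables["tf_target"])}
            predicted["MIR"] |= {p.gene for p in predict_mir(s, ann.tables["mirna_target"])}
        for m, genes in predicted.items():
            # seed genes are annotation-only symbols, not search-space members
            assert genes == groups.get(m, set()), m

    def test_decoys_never_remove_planted_predictions(self):
        ann0, ws = self._setup(decoy_density=0.0)
        ann2, _ = self._setup(decoy_density=2.0)
        base = set()
        dense = set()
        for s in ws:
            base |= {p.gene for p in predict_cps(s, ann0.tables["pathway"])}
            dense |= {p.gene for p in predict_cps(s, ann2.tables["pathway"])}
        assert base <= dense

    def test_no_planted_genes_gives_empty_planted_predictions(self):
        genome = generate_genome(n_genes=50, seed=9)
        ann = generate_annotations(genome, [], decoy_density=1.0, seed=9)
        assert ann.module_assignment == {} and ann.seed_genes == ()


class TestDrugDatabases:
    def test_exact_overlap_profile_reproduced(self):
        genome = generate_genome(n_genes=400, seed=10)
        profile = {"only_a": 12, "only_b": 5, "only_c": 3, "ab_only": 4,
                   "ac_only": 2, "bc_only": 1, "abc": 7}
        sim = generate_drug_databases(genome, db_overlap_profile=profile,
                                      target_fraction=34 / 400, seed=10)
        by_db = {db: set() for db in ("DrugBank", "TTD", "PharmGKB")}
        for gene, region in sim.target_regions.items():
            for db in by_db:
                short = {"DrugBank": "a", "TTD": "b", "PharmGKB": "c"}[db]
                if short in region.replace("only_", "").replace("_only", "") or region == "abc":
                    by_db[db].add(gene)
        v = venn_regions(by_db["DrugBank"], by_db["TTD"], by_db["PharmGKB"])
        assert v.as_dict() == profile

    def test_inconsistent_count_profile_rejected(self):
        genome = generate_genome(n_genes=100, seed=1)
        bad = {"only_a": 3, "only_b": 0, "only_c": 0, "ab_only": 0,
               "ac_only": 0, "bc_only": 0, "abc": 2}  # sums to 5, not 8
        with pytest.raises(ValueError):
            generate_drug_databases(genome, db_overlap_profile=bad,
                                    target_fraction=0.08, seed=1)

    def test_target_fraction_sizes_target_set(self):
        genome = generate_genome(n_genes=1000, seed=12)
        sim = generate_drug_databases(genome, target_fraction=0.08, seed=12)
        assert len(sim.target_regions) == 80

    def test_zero_known_drug_fraction_leaves_all_novel(self):
        genome = generate_genome(n_genes=200, seed=13)
        gwas = generate_gwas(genome, seed=13)
        sim = generate_drug_databases(genome, gwas.planted_genes,
                                      known_drug_fraction=0.0, seed=13)
        assert sim.known_drugs == ()

    def test_exports_parse_under_their_dialects(self, tmp_path):
        genome = generate_genome(n_genes=200, seed=14)
        gwas = generate_gwas(genome, seed=14)
        sim = generate_drug_databases(genome, gwas.planted_genes, seed=14)
        paths = {
            "DrugBank": (tmp_path / "db.csv", "drugbank", ","),
            "TTD": (tmp_path / "ttd.tsv", "ttd", "\t"),
            "PharmGKB": (tmp_path / "pg.tsv", "pharmgkb", "\t"),
        }
        for db, (path, dialect, sep) in paths.items():
            sim.exports[db].to_csv(path, sep=sep, index=False)
            records, _ = parse_drug_export(path, dialect, db)
            assert records, db
            assert all(r.source_db == db for r in records)


class TestCitations:
    def test_separated_rates_give_high_auc(self):
        genes = [f"g{i}" for i in range(300)]
        cited = set(genes[:20])
        counts = generate_citations(genes, cited, high_rate=20, low_rate=0.1, seed=15)
        res = citation_benchmark(cited, set(genes), counts)
        assert res.roc.auc >= 0.9

    def test_equal_rates_near_chance(self):
        genes = [f"g{i}" for i in range(400)]
        cited = set(genes[:200])
        counts = generate_citations(genes, cited, high_rate=2.0, low_rate=2.0, seed=16)
        auc = mann_whitney_auc(
            [counts[g] for g in genes[:200]], [counts[g] for g in genes[200:]]
        )
        assert abs(auc - 0.5) < 0.08

    def test_deterministic_under_seed(self):
        genes = ["a", "b", "c"]
        assert generate_citations(genes, {"a"}, seed=17) == generate_citations(genes, {"a"}, seed=17)
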