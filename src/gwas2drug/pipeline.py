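"""Pipeline orchestration: configuration, staged execution, and reporting.

Stages run in a fixed order -- stratify, spaces, predict, integrate,
reposition, benchmark, compare -- each writing its intermediate artifact to
the output directory, so every number in the final report can be re-derived
from the written files.  A stage failure aborts the run with the stage name
and cause; artifacts already written are retained.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import benchmarks as bm
from . import comparison as cmp_mod
from . import drug_db, gene_prediction, gwas_loci, repositioning

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run.

    Paths are resolved relative to ``base_dir`` (the config file's directory
    when loaded from YAML).  Unknown keys are rejected at load time.
    """

    association_file: str = "assoc.tsv"
    gene_bed: str = "genome.bed"
    annotation_files: dict = field(default_factory=dict)  # kind -> path
    drug_exports: list = field(default_factory=list)  # [{path, dialect, source_db}]
    id_map: str | None = None
    citations: str | None = None
    seed_gene_file: str | None = None
    external_gene_list: str | None = None
    previous_targets: str | None = None
    thresholds: Sequence[float] = gwas_loci.DEFAULT_THRESHOLDS
    fixed_widths: dict = field(default_factory=dict)
    nearest_ks: dict = field(default_factory=dict)
    association_dialect: dict = field(default_factory=dict)
    tau: float = gene_prediction.DEFAULT_TAU
    hub_k: int = gene_prediction.DEFAULT_HUB_K
    phenotype_terms: Sequence[str] = ("coronary artery disease", "coronary heart disease")
    citation_thresholds: Sequence[int] = bm.DEFAULT_CITATION_THRESHOLDS
    n_permutations: int = 1000
    seed: int = 0
    outdir: str = "results"
    base_dir: str = "."

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise gwas_loci.ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        raw.setdefault("base_dir", str(path.parent))
        return cls(**raw)

    def resolve(self, p: str | None) -> Path | None:
        return None if p is None else Path(self.base_dir) / p


@dataclass
class PipelineResult:
    """Everything one run produced, plus where its artifacts were written."""

    summary: repositioning.RepositioningSummary
    candidates: frozenset[str]
    targets: list
    drugs: list
    venn: drug_db.VennCounts3
    space_benchmark: bm.SpaceBenchmark | None
    citation_benchmark: bm.CitationBenchmark | None
    comparisons: dict
    outdir: Path


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages; see the module docstring for the stage order."""
    outdir = Path(config.base_dir) / config.outdir
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("stage: %s", name)
        return name

    # -- stratify -------------------------------------------------------
    try:
        stage("stratify")
        snps, n_rejected = gwas_loci.parse_association_file(
            config.resolve(config.association_file), dialect=config.association_dialect or None
        )
        strata = gwas_loci.stratify_snps(snps, config.thresholds)
        logger.info(
            "parsed %d SNPs (%d rejected); strata sizes %s",
            len(snps), n_rejected, {s.label: len(s) for s in strata},
        )
    except Exception as e:  # noqa: BLE001 - rewrap with stage name
        raise StageError("stratify", e) from e

    # -- spaces ---------------------------------------------------------
    try:
        stage("spaces")
        genes = gwas_loci.read_bed(config.resolve(config.gene_bed))
        spaces = gwas_loci.build_all_search_spaces(
            strata, genes, config.fixed_widths or None, config.nearest_ks or None
        )
        gwas_loci.write_search_spaces(spaces, outdir / "search_spaces.tsv")
        logger.info("built %d search spaces over %d genes", len(spaces), len(genes))
    except Exception as e:
        raise StageError("spaces", e) from e

    # -- predict --------------------------------------------------------
    try:
        stage("predict")
        annotations = {
            kind: gene_prediction.AnnotationTable.from_tsv(config.resolve(p), kind)
            for kind, p in sorted(config.annotation_files.items())
        }
        seed_genes: frozenset[str] = frozenset()
        if config.seed_gene_file:
            seed_genes = cmp_mod.read_gene_list(config.resolve(config.seed_gene_file))
        per_space = [
            gene_prediction.predict_all(
                s, annotations, seed_genes, tau=config.tau, hub_k=config.hub_k
            )
            for s in spaces
        ]
        predictions = gene_prediction.combine_predictions(per_space)
        gene_prediction.write_predictions(predictions, outdir / "predictions.tsv")
        candidates = frozenset(p.gene for p in predictions)
        logger.info("predicted %d candidate genes", len(candidates))
    except Exception as e:
        raise StageError("predict", e) from e

    # -- integrate ------------------------------------------------------
    try:
        stage("integrate")
        if not config.drug_exports:
            raise gwas_loci.ConfigurationError("no drug databases configured")
        id_map = drug_db.read_id_map(config.resolve(config.id_map)) if config.id_map else {}
        collections = []
        for spec in config.drug_exports:
            records, n_unknown = drug_db.parse_drug_export(
                config.resolve(spec["path"]), spec.get("dialect", "drugbank"),
                spec["source_db"],
            )
            mapped, n_dropped, n_ambig = drug_db.map_to_hugo(records, id_map)
            logger.info(
                "%s: %d records, %d unknown-status, %d dropped, %d ambiguous",
                spec["source_db"], len(records), n_unknown, n_dropped, n_ambig,
            )
            collections.append(mapped)
        pooled = drug_db.pool_databases(*collections)
        pooled.to_frame().to_csv(outdir / "pooled.tsv", sep="\t", index=False)
        logger.info(
            "pooled %d pairs, %d unique targets, %d unique drugs",
            len(pooled.records), len(pooled.unique_targets), len(pooled.unique_drugs),
        )
    except Exception as e:
        raise StageError("integrate", e) from e

    # -- reposition -----------------------------------------------------
    try:
        stage("reposition")
        targets = repositioning.map_targets(candidates, pooled)
        targets = repositioning.classify_target_novelty(targets, config.phenotype_terms)
        drugs = repositioning.aggregate_drugs(targets, config.phenotype_terms)
        target_genes = {t.gene for t in targets}
        venn = drug_db.venn_regions(
            target_genes & pooled.targets_of("DrugBank"),
            target_genes & pooled.targets_of("TTD"),
            target_genes & pooled.targets_of("PharmGKB"),
        )
        summary = repositioning.summarize(candidates, targets, drugs, venn)
        repositioning.targets_to_frame(targets).to_csv(outdir / "targets.tsv", sep="\t", index=False)
        repositioning.drugs_to_frame(drugs).to_csv(outdir / "drugs.tsv", sep="\t", index=False)
        logger.info(
            "%d targets (%d known, %d novel), %d drugs",
            summary.n_targets, summary.n_known_targets, summary.n_novel_targets,
            summary.n_drugs,
        )
    except Exception as e:
        raise StageError("reposition", e) from e

    # -- benchmark ------------------------------------------------------
    try:
        stage("benchmark")
        known_in_db = frozenset(
            g for g, pairs in pooled.by_target.items()
            if any(
                p.indications and repositioning.indication_matches(
                    p.indications, config.phenotype_terms
                )
                for p in pairs
            )
        )
        ws_label = gwas_loci.STRATUM_LABELS[-1]
        ws_spaces = [s for s in spaces if s.stratum_label == ws_label]
        space_bench = bm.benchmark_search_spaces(
            ws_spaces, target_genes, known_in_db,
            n_perm=config.n_permutations, seed=config.seed,
        )
        bm.tables_to_frame(
            space_bench.tables, [f"space_{i}" for i in range(1, len(space_bench.tables) + 1)]
        ).to_csv(outdir / "benchmark_spaces.tsv", sep="\t", index=False)
        citation_bench = None
        if config.citations:
            counts = bm.read_citations(config.resolve(config.citations))
            universe = gwas_loci.search_space_gene_universe(ws_spaces)
            citation_bench = bm.citation_benchmark(
                target_genes & universe, universe, counts, config.citation_thresholds
            )
            bm.tables_to_frame(
                citation_bench.tables, list(config.citation_thresholds)
            ).to_csv(outdir / "benchmark_citations.tsv", sep="\t", index=False)
    except Exception as e:
        raise StageError("benchmark", e) from e

    # -- compare --------------------------------------------------------
    try:
        stage("compare")
        comparisons = {}
        if config.previous_targets:
            prev = cmp_mod.read_gene_list(config.resolve(config.previous_targets))
            comparisons["previous_study"] = cmp_mod.compare_sets(target_genes, prev)
        if config.external_gene_list:
            ext = cmp_mod.read_gene_list(config.resolve(config.external_gene_list))
            mapped, comp = cmp_mod.external_list_overlap(ext, pooled, target_genes)
            comparisons["external_list"] = comp
            comparisons["external_mapped"] = mapped
        for name in ("previous_study", "external_list"):
            if name in comparisons:
                comparisons[name].to_frame().to_csv(
                    outdir / f"comparison_{name}.tsv", sep="\t", index=False
                )
    except Exception as e:
        raise StageError("compare", e) from e

    result = PipelineResult(
        summary=summary, candidates=candidates, targets=targets, drugs=drugs,
        venn=venn, space_benchmark=space_bench, citation_benchmark=citation_bench,
        comparisons=comparisons, outdir=outdir,
    )
    report_txt, report_json = render_report(result)
    (outdir / "report.txt").write_text(report_txt)
    (outdir / "report.json").write_text(report_json)
    return result


def render_report(result: PipelineResult) -> tuple[str, str]:
    """Render the consolidated report as ``key: value`` text and as JSON.

    Both forms are fully derivable from the written intermediate files and
    deterministic: keys are emitted in sorted order and floats at fixed
    precision.
    """
    d: dict[str, object] = dict(result.summary.to_dict())
    if result.space_benchmark is not None:
        sb = result.space_benchmark
        d["benchmark1_auc"] = round(sb.roc.auc, 6)
        d["benchmark1_auc_rank"] = round(sb.auc_rank, 6)
        d["benchmark1_p"] = round(sb.p_value, 6)
        d["benchmark1_universe_size"] = len(sb.universe)
        d["benchmark1_tables"] = [dataclasses.asdict(t) for t in sb.tables]
    else:
        d["benchmark1"] = "not-run"
    if result.citation_benchmark is not None:
        cb = result.citation_benchmark
        d["benchmark2_auc"] = round(cb.roc.auc, 6)
        d["benchmark2_missing_citations"] = cb.n_missing
        d["benchmark2_tables"] = [dataclasses.asdict(t) for t in cb.tables]
    else:
        d["benchmark2"] = "not-run"
    for name in ("previous_study", "external_list"):
        comp = result.comparisons.get(name)
        if comp is None:
            d[f"comparison_{name}"] = "not-run"
        else:
            d[f"comparison_{name}_common"] = comp.n_common
            d[f"comparison_{name}_only_ours"] = comp.n_only_b if name == "external_list" else comp.n_only_a
            d[f"comparison_{name}_only_theirs"] = comp.n_only_a if name == "external_list" else comp.n_only_b
    if "external_mapped" in result.comparisons:
        mapped = result.comparisons["external_mapped"]
        d["external_mapped_targets"] = len(mapped)
        comp = result.comparisons["external_list"]
        if mapped:
            d["external_retrieval_fraction"] = round(comp.n_common / len(mapped), 6)

    lines = []
    for k in sorted(d):
        v = d[k]
        if isinstance(v, (dict, list)):
            v = json.dumps(v, sort_keys=True)
        lines.append(f"{k}: {v}")
    text = "\n".join(lines) + "\n"
    return text, json.dumps(d, sort_keys=True, indent=2, default=str) + "\n"
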