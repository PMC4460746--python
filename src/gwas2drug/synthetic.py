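"""Seeded generator of all pipeline inputs with a planted-truth manifest.

The generator emulates, at roughly 1/30 scale, the statistical structure the
analysis assumes: a gene annotation over a few chromosomes; an association
table whose planted SNPs sit inside planted disease genes with p-values
drawn inside their stratum's interval while null SNPs stay above the weakest
threshold; annotation tables wired so that each prediction rule recovers a
designated subset of the planted genes (cross-locus shared pathways, edges,
transcription factors and miRNAs; domain profiles matching seed genes; miRNA
in-degree at the hub threshold); three partially overlapping drug-database
exports in their native dialects whose target sets realize a configured
seven-region Venn profile over roughly 8% of the genome; and a citation
table separating planted genes from the background.

Decoy annotations attach background genes to private (degree-one or
external-partner) structures, so they can never create cross-locus sharing
among non-planted genes: at decoy density 0 or above, module predictions on
the planted check equal the designated planted subsets exactly.  Every
generator draws from one ``numpy.random.Generator`` passed explicitly; the
same seed reproduces every file byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .gene_prediction import MODULES, AnnotationTable, DEFAULT_HUB_K
from .gwas_loci import GeneRecord, SnpAssociation, STRATUM_LABELS, write_association_file, write_bed

DEFAULT_PHENOTYPE_TERMS = ("coronary artery disease", "coronary heart disease")

#: Stratum p-value intervals (lo, hi]: planted SNPs are drawn uniformly inside.
STRATUM_P_RANGES = {
    "HS": (1e-12, 5e-7),
    "MHS": (5e-7, 1e-5),
    "MWS": (1e-5, 1e-4),
    "WS": (1e-4, 1e-3),
}

DEFAULT_STRATA_MIX = {"HS": 4, "MHS": 4, "MWS": 6, "WS": 6}

#: Region keys of the three-database target overlap profile
#: (A = DrugBank, B = TTD, C = PharmGKB).
VENN_REGION_KEYS = ("only_a", "only_b", "only_c", "ab_only", "ac_only", "bc_only", "abc")
DEFAULT_OVERLAP_PROFILE = {
    "only_a": 0.55, "only_b": 0.08, "only_c": 0.05,
    "ab_only": 0.17, "ac_only": 0.08, "bc_only": 0.02, "abc": 0.05,
}
_REGION_DBS = {
    "only_a": ("DrugBank",), "only_b": ("TTD",), "only_c": ("PharmGKB",),
    "ab_only": ("DrugBank", "TTD"), "ac_only": ("DrugBank", "PharmGKB"),
    "bc_only": ("TTD", "PharmGKB"), "abc": ("DrugBank", "TTD", "PharmGKB"),
}

#: Indication vocabulary for background drugs; none of these strings contains
#: a phenotype term, so substring matching cannot mislabel them as known.
DECOY_INDICATIONS = (
    "epilepsy", "depressive disorder", "advanced renal cell carcinoma",
    "chronic obstructive pulmonary deficit", "metastatic breast cancer",
    "skin ulcers", "rheumatoid arthritis", "type 2 diabetes mellitus",
    "asthma", "migraine", "glaucoma", "psoriasis",
)

_DRUG_STATUS_MIX = {
    "approved": 0.35, "clinical": 0.45, "both": 0.06,
    "experimental": 0.09, "unknown": 0.05,
}


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class TruthManifest:
    """Planted ground truth of one synthetic bundle."""

    seed: int
    params: dict = field(default_factory=dict)
    planted_disease_genes: tuple[str, ...] = ()
    planted_snps: dict = field(default_factory=dict)  # snp_id -> stratum
    module_assignment: dict = field(default_factory=dict)  # gene -> module
    seed_genes: tuple[str, ...] = ()
    planted_known_targets: tuple[str, ...] = ()
    planted_novel_targets: tuple[str, ...] = ()
    planted_known_drugs: tuple[str, ...] = ()
    planted_novel_drugs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        overlap = set(self.planted_known_targets) & set(self.planted_novel_targets)
        if overlap:
            raise ValueError(f"known/novel target sets overlap: {sorted(overlap)}")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = sorted(v)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        d = json.loads(text)
        for k in (
            "planted_disease_genes", "seed_genes", "planted_known_targets",
            "planted_novel_targets", "planted_known_drugs", "planted_novel_drugs",
        ):
            d[k] = tuple(d.get(k, ()))
        return cls(**d)


def generate_genome(
    n_chrom: int = 3,
    n_genes: int = 600,
    mean_gene_len: int = 10_000,
    mean_gap: int = 40_000,
    seed=None,
    max_chrom_len: int | None = None,
) -> list[GeneRecord]:
    """Non-overlapping genes laid out left to right on ``n_chrom`` chromosomes."""
    if n_chrom < 1 or mean_gene_len < 1 or mean_gap < 1 or n_genes < 0:
        raise ValueError("all genome parameters must be positive")
    rng = _rng(seed)
    per_chrom = [n_genes // n_chrom + (1 if i < n_genes % n_chrom else 0) for i in range(n_chrom)]
    genes: list[GeneRecord] = []
    idx = 0
    for ci, count in enumerate(per_chrom, start=1):
        cursor = 0
        for _ in range(count):
            gap = 1 + int(rng.exponential(mean_gap))
            length = 200 + int(rng.exponential(max(1, mean_gene_len - 200)))
            start = cursor + gap
            end = start + length
            if max_chrom_len is not None and end > max_chrom_len:
                raise ValueError(
                    f"cannot pack {count} genes into chr{ci} of length {max_chrom_len}"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneRecord(f"G{idx:04d}", f"chr{ci}", start, end, strand))
            cursor = end
            idx += 1
    return genes


def _proportional_mix(n_disease_loci: int) -> dict[str, int]:
    """Default stratum shares (0.2/0.2/0.3/0.3 for HS/MHS/MWS/WS) rounded by
    largest remainder so the counts sum to ``n_disease_loci``."""
    shares = {"HS": 0.2, "MHS": 0.2, "MWS": 0.3, "WS": 0.3}
    raw = {k: n_disease_loci * v for k, v in shares.items()}
    mix = {k: int(np.floor(v)) for k, v in raw.items()}
    rest = n_disease_loci - sum(mix.values())
    for k in sorted(shares, key=lambda k: raw[k] - mix[k], reverse=True)[:rest]:
        mix[k] += 1
    return mix


@dataclass
class GwasSim:
    snps: list[SnpAssociation]
    planted_snps: dict  # snp_id -> stratum label
    planted_genes: tuple[str, ...]  # aligned with planted SNP order


def generate_gwas(
    genome: Sequence[GeneRecord],
    n_disease_loci: int = 20,
    strata_mix: Mapping[str, int] | None = None,
    n_null_snps: int = 300,
    seed=None,
) -> GwasSim:
    """Planted SNPs inside distinct disease genes, one stratum each, plus
    null SNPs with p above the weakest threshold."""
    rng = _rng(seed)
    if strata_mix is None:
        mix = _proportional_mix(n_disease_loci)
    else:
        mix = dict(strata_mix)
    if set(mix) - set(STRATUM_LABELS):
        raise ValueError(f"unknown strata in mix: {sorted(set(mix) - set(STRATUM_LABELS))}")
    if sum(mix.values()) != n_disease_loci:
        raise ValueError("strata_mix must assign every planted locus a stratum")
    if n_disease_loci > len(genome):
        raise ValueError("more planted loci than genes")

    order = rng.permutation(len(genome))
    planted = [genome[i] for i in order[:n_disease_loci]]
    labels = [lab for lab in STRATUM_LABELS for _ in range(mix.get(lab, 0))]

    snps: list[SnpAssociation] = []
    planted_snps: dict[str, str] = {}
    sid = 0
    for gene, lab in zip(planted, labels):
        lo, hi = STRATUM_P_RANGES[lab]
        p = float(lo + rng.random() * (hi - lo))
        pos = int(rng.integers(gene.start + 1, gene.end + 1))  # 1-based, inside gene
        snp_id = f"rs{sid:05d}"
        snps.append(SnpAssociation(snp_id, gene.chrom, pos, p))
        planted_snps[snp_id] = lab
        sid += 1

    chrom_len = {}
    for g in genome:
        chrom_len[g.chrom] = max(chrom_len.get(g.chrom, 0), g.end)
    chroms = sorted(chrom_len)
    for _ in range(n_null_snps):
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(1, chrom_len[chrom] + 1))
        p = float(1.1e-3 + rng.random() * (1.0 - 1.1e-3))
        snps.append(SnpAssociation(f"rs{sid:05d}", chrom, pos, p))
        sid += 1
    return GwasSim(snps, planted_snps, tuple(g.symbol for g in planted))


def assign_modules(planted_genes: Sequence[str]) -> dict[str, str]:
    """Round-robin designation of which rule should recover each planted gene.

    Cross-locus rules need at least two members to fire, so a singleton group
    for CPS/PPI/CRT/MIR is reassigned to CMP (which matches genes one by one
    against seed-gene domain profiles).
    """
    groups: dict[str, list[str]] = {m: [] for m in MODULES}
    for i, g in enumerate(planted_genes):
        groups[MODULES[i % len(MODULES)]].append(g)
    for m in ("CPS", "PPI", "CRT", "MIR"):
        if len(groups[m]) == 1:
            groups["CMP"].append(groups[m].pop())
    return {g: m for m, gs in groups.items() for g in gs}


@dataclass
class AnnotationSim:
    tables: dict  # kind -> AnnotationTable
    module_assignment: dict
    seed_genes: tuple[str, ...]


def generate_annotations(
    genome: Sequence[GeneRecord],
    planted_genes: Sequence[str],
    decoy_density: float = 1.0,
    hub_k: int = DEFAULT_HUB_K,
    module_assignment: Mapping[str, str] | None = None,
    seed=None,
) -> AnnotationSim:
    """Wire planted genes so their designated rule recovers them; add decoys.

    Decoy structures touch a single real gene each (pathway/TF/domain ids are
    private; interaction partners are external symbols absent from the
    genome), so raising ``decoy_density`` can never remove a planted
    prediction nor create a cross-locus false positive.
    """
    if decoy_density < 0:
        raise ValueError("decoy_density must be >= 0")
    rng = _rng(seed)
    symbols = {g.symbol for g in genome}
    missing = set(planted_genes) - symbols
    if missing:
        raise ValueError(f"planted genes absent from genome: {sorted(missing)[:5]}")
    assignment = dict(module_assignment) if module_assignment else assign_modules(planted_genes)
    groups: dict[str, list[str]] = {m: [] for m in MODULES}
    for g in planted_genes:
        groups[assignment[g]].append(g)

    pathway_pairs: list[tuple[str, str]] = [("PATH_PLANT", g) for g in groups["CPS"]]
    ppi_pairs: list[tuple[str, str]] = [
        (a, b) for a, b in zip(groups["PPI"], groups["PPI"][1:])
    ]
    tf_pairs: list[tuple[str, str]] = [("TF_PLANT", g) for g in groups["CRT"]]
    mir_pairs: list[tuple[str, str]] = [("MIR_PLANT", g) for g in groups["MIR"]]
    for g in groups["MIR"]:
        for j in range(hub_k - 1):
            mir_pairs.append((f"MIR_{g}_{j}", g))
    domain_pairs: list[tuple[str, str]] = []
    seed_genes = []
    for g in groups["CMP"]:
        sg = f"SEED_{g}"
        seed_genes.append(sg)
        for d in (f"DOM_{g}_A", f"DOM_{g}_B"):
            domain_pairs.append((g, d))
            domain_pairs.append((sg, d))

    # decoys on non-planted genes only
    planted_set = set(planted_genes)
    decoy_id = 0
    for g in sorted(symbols - planted_set):
        for kind in ("pathway", "interaction", "domain", "tf", "mirna"):
            for _ in range(int(rng.poisson(decoy_density))):
                tag = f"{decoy_id:05d}"
                decoy_id += 1
                if kind == "pathway":
                    pathway_pairs.append((f"DPATH_{tag}", g))
                elif kind == "interaction":
                    ppi_pairs.append((g, f"EXT_{tag}"))
                elif kind == "domain":
                    domain_pairs.append((g, f"DDOM_{tag}"))
                elif kind == "tf":
                    tf_pairs.append((f"DTF_{tag}", g))
                else:
                    mir_pairs.append((f"DMIR_{tag}", g))

    tables = {
        "pathway": AnnotationTable.from_pairs("pathway", pathway_pairs),
        "interaction": AnnotationTable.from_pairs("interaction", ppi_pairs),
        # domain pairs are (gene, domain): gene on the subject side so the
        # Jaccard grouping in the CMP rule sees gene -> domain set
        "domain": AnnotationTable.from_pairs("domain", domain_pairs),
        "tf_target": AnnotationTable.from_pairs("tf_target", tf_pairs),
        "mirna_target": AnnotationTable.from_pairs("mirna_target", mir_pairs),
    }
    return AnnotationSim(tables, assignment, tuple(seed_genes))


@dataclass
class DrugSim:
    exports: dict  # source_db -> pandas DataFrame in the db's dialect
    id_map: dict  # accession -> symbol
    target_regions: dict  # gene -> region key
    known_targets: tuple[str, ...]
    novel_targets: tuple[str, ...]
    known_drugs: tuple[str, ...]
    novel_drugs: tuple[str, ...]


def _profile_to_counts(profile: Mapping[str, float | int], n: int) -> dict[str, int]:
    vals = [profile.get(k, 0) for k in VENN_REGION_KEYS]
    if all(float(v).is_integer() for v in vals) and sum(vals) > 1.5:
        counts = {k: int(profile.get(k, 0)) for k in VENN_REGION_KEYS}
        if sum(counts.values()) != n:
            raise ValueError(
                f"overlap profile counts sum to {sum(counts.values())}, expected {n}"
            )
        return counts
    total = float(sum(vals))
    raw = {k: n * float(profile.get(k, 0)) / total for k in VENN_REGION_KEYS}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    remainder = n - sum(counts.values())
    for k in sorted(VENN_REGION_KEYS, key=lambda k: raw[k] - counts[k], reverse=True)[:remainder]:
        counts[k] += 1
    return counts


def generate_drug_databases(
    genome: Sequence[GeneRecord],
    planted_genes: Sequence[str] = (),
    n_known_targets: int = 5,
    target_fraction: float = 0.08,
    db_overlap_profile: Mapping[str, float | int] | None = None,
    known_drug_fraction: float = 0.5,
    phenotype_terms: Sequence[str] = DEFAULT_PHENOTYPE_TERMS,
    accession_share: float = 0.3,
    untranslatable_share: float = 0.05,
    n_unpredicted_known: int = 0,
    seed=None,
) -> DrugSim:
    """Three partially overlapping drug-database exports plus an id map.

    Roughly ``target_fraction`` of the genome is druggable; every planted
    gene is a target, and ``n_known_targets`` of them carry at least one
    drug indicated for the phenotype.  ``n_unpredicted_known`` additional
    background targets also get phenotype-indicated drugs (known targets the
    prediction stage will miss, as real drug databases contain).  Target
    sets of the three databases realize ``db_overlap_profile`` -- exact
    region counts if integers are given, largest-remainder-rounded fractions
    otherwise.  A share of TTD rows carries UniProt-style accessions that
    the id map translates back, plus ``untranslatable_share`` noise rows
    whose accessions the map omits.
    """
    for frac in (target_fraction, known_drug_fraction, accession_share, untranslatable_share):
        if not 0.0 <= frac <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
    rng = _rng(seed)
    symbols = [g.symbol for g in genome]
    planted = list(planted_genes)
    # known-for-phenotype designations only make sense among planted targets
    n_known_targets = min(n_known_targets, len(planted))
    n_targets = max(len(planted), int(round(target_fraction * len(symbols))))
    background = [s for s in symbols if s not in set(planted)]
    extra = [str(s) for s in rng.choice(background, size=n_targets - len(planted), replace=False)]
    targets = planted + extra

    counts = _profile_to_counts(db_overlap_profile or DEFAULT_OVERLAP_PROFILE, n_targets)
    shuffled = list(rng.permutation(targets))
    target_regions: dict[str, str] = {}
    i = 0
    for key in VENN_REGION_KEYS:
        for g in shuffled[i:i + counts[key]]:
            target_regions[g] = key
        i += counts[key]

    known_candidates = (
        [str(s) for s in rng.choice(planted, size=n_known_targets, replace=False)]
        if n_known_targets else []
    )
    unpred_known = (
        [str(s) for s in rng.choice(extra, size=n_unpredicted_known, replace=False)]
        if n_unpredicted_known else []
    )

    status_names = list(_DRUG_STATUS_MIX)
    status_probs = np.array([_DRUG_STATUS_MIX[s] for s in status_names])
    status_probs = status_probs / status_probs.sum()

    drug_rows: list[dict] = []  # neutral rows; rendered per-dialect below
    known_drugs: set[str] = set()
    novel_drugs: set[str] = set()
    did = 0
    for gene in targets:
        n_drugs = int(rng.integers(1, 4))
        make_known = gene in known_candidates or gene in unpred_known
        for j in range(n_drugs):
            name = f"drug{did:04d}"
            did += 1
            status = status_names[int(rng.choice(len(status_names), p=status_probs))]
            inds = {str(s) for s in rng.choice(DECOY_INDICATIONS, size=int(rng.integers(1, 3)), replace=False)}
            is_known_drug = make_known and (
                j == 0 or rng.random() < known_drug_fraction
            ) and known_drug_fraction > 0
            if is_known_drug:
                inds.add(phenotype_terms[0])
                known_drugs.add(name)
            elif gene in set(planted):
                novel_drugs.add(name)
            drug_rows.append(
                {"drug": name, "gene": gene, "status": status, "indications": sorted(inds)}
            )

    id_map = {}
    for k, gene in enumerate(sorted(targets)):
        id_map[f"P{10000 + k:05d}"] = gene
    acc_of = {gene: acc for acc, gene in id_map.items()}

    def _status_strings(status: str, db: str) -> list[str]:
        vocab = {
            "DrugBank": {"approved": "Approved", "clinical": "Investigational",
                         "experimental": "Experimental", "unknown": "Unknown"},
            "TTD": {"approved": "Launched", "clinical": "Phase III",
                    "experimental": "Experimental", "unknown": "Unknown"},
            "PharmGKB": {"approved": "Approved", "clinical": "Clinical trial",
                         "experimental": "Experimental", "unknown": "Unknown"},
        }[db]
        if status == "both":
            return [vocab["approved"], vocab["clinical"]]
        return [vocab[status]]

    per_db_rows: dict[str, list] = {"DrugBank": [], "TTD": [], "PharmGKB": []}
    for row in drug_rows:
        dbs = _REGION_DBS[target_regions[row["gene"]]]
        for db in dbs:
            target_field = row["gene"]
            if db == "TTD" and rng.random() < accession_share:
                target_field = acc_of[row["gene"]]
            for status_str in _status_strings(row["status"], db):
                per_db_rows[db].append((row["drug"], target_field, status_str,
                                        ";".join(row["indications"])))
    # untranslatable TTD noise rows
    n_noise = int(round(untranslatable_share * len(per_db_rows["TTD"])))
    for k in range(n_noise):
        per_db_rows["TTD"].append(
            (f"noise{k:03d}", f"Q{99000 + k:05d}", "Experimental", "unclassified")
        )

    exports = {
        "DrugBank": pd.DataFrame(
            [(f"DB{i:05d}", d, t, s, ind, "") for i, (d, t, s, ind) in enumerate(per_db_rows["DrugBank"])],
            columns=["drugbank_id", "name", "gene_name", "groups", "indication", "actions"],
        ),
        "TTD": pd.DataFrame(
            [(f"TTD{i:05d}", d, t, s, ind, "") for i, (d, t, s, ind) in enumerate(per_db_rows["TTD"])],
            columns=["ttd_id", "drug_name", "target", "highest_status", "indication", "moa"],
        ),
        "PharmGKB": pd.DataFrame(
            [(f"PA{i:05d}", d, t, s, ind, "") for i, (d, t, s, ind) in enumerate(per_db_rows["PharmGKB"])],
            columns=["pharmgkb_id", "chemical", "gene", "type", "diseases", "association"],
        ),
    }
    novel_targets = tuple(sorted(set(planted) - set(known_candidates)))
    return DrugSim(
        exports=exports,
        id_map=id_map,
        target_regions=target_regions,
        known_targets=tuple(sorted(set(known_candidates) | set(unpred_known))),
        novel_targets=novel_targets,
        known_drugs=tuple(sorted(known_drugs)),
        novel_drugs=tuple(sorted(novel_drugs)),
    )


def generate_citations(
    genes: Iterable[str],
    cited_genes: Iterable[str],
    high_rate: float = 20.0,
    low_rate: float = 0.1,
    seed=None,
) -> dict[str, int]:
    """Poisson citation counts: ``high_rate`` mean for ``cited_genes``,
    ``low_rate`` for the rest."""
    if high_rate < 0 or low_rate < 0:
        raise ValueError("rates must be >= 0")
    rng = _rng(seed)
    cited = set(cited_genes)
    return {
        g: int(rng.poisson(high_rate if g in cited else low_rate))
        for g in sorted(set(genes))
    }


@dataclass
class SyntheticBundle:
    """File paths and ground truth of one generated input bundle."""

    root: Path
    config_path: Path
    manifest: TruthManifest


def write_bundle(
    outdir,
    seed: int = 0,
    n_chrom: int = 3,
    n_genes: int = 600,
    n_disease_loci: int = 20,
    strata_mix: Mapping[str, int] | None = None,
    n_null_snps: int = 300,
    decoy_density: float = 1.0,
    hub_k: int = DEFAULT_HUB_K,
    tau: float = 0.5,
    n_known_targets: int = 5,
    target_fraction: float = 0.08,
    db_overlap_profile: Mapping[str, float | int] | None = None,
    known_drug_fraction: float = 0.5,
    n_unpredicted_known: int = 0,
    high_citation_rate: float = 20.0,
    low_citation_rate: float = 0.1,
    phenotype_terms: Sequence[str] = DEFAULT_PHENOTYPE_TERMS,
) -> SyntheticBundle:
    """Generate and write every pipeline input plus manifest and run config.

    A single seeded generator drives all sub-generators in a fixed order, so
    identical parameters and seed give byte-identical files.
    """
    root = Path(outdir)
    root.mkdir(parents=True, exist_ok=True)
    (root / "annotations").mkdir(exist_ok=True)
    (root / "drugs").mkdir(exist_ok=True)
    rng = np.random.default_rng(seed)

    genome = generate_genome(n_chrom=n_chrom, n_genes=n_genes, seed=rng)
    gwas = generate_gwas(
        genome, n_disease_loci=n_disease_loci, strata_mix=strata_mix,
        n_null_snps=n_null_snps, seed=rng,
    )
    ann = generate_annotations(
        genome, gwas.planted_genes, decoy_density=decoy_density, hub_k=hub_k, seed=rng,
    )
    drugs = generate_drug_databases(
        genome, gwas.planted_genes,
        n_known_targets=min(n_known_targets, n_disease_loci),
        target_fraction=target_fraction, db_overlap_profile=db_overlap_profile,
        known_drug_fraction=known_drug_fraction, phenotype_terms=phenotype_terms,
        n_unpredicted_known=n_unpredicted_known, seed=rng,
    )
    citations = generate_citations(
        [g.symbol for g in genome], gwas.planted_genes,
        high_rate=high_citation_rate, low_rate=low_citation_rate, seed=rng,
    )

    write_bed(genome, root / "genome.bed")
    write_association_file(gwas.snps, root / "assoc.tsv")
    for kind, table in ann.tables.items():
        table.to_frame().to_csv(root / "annotations" / f"{kind}.tsv", sep="\t", index=False)
    drugs.exports["DrugBank"].to_csv(root / "drugs" / "drugbank.csv", index=False)
    drugs.exports["TTD"].to_csv(root / "drugs" / "ttd.tsv", sep="\t", index=False)
    drugs.exports["PharmGKB"].to_csv(root / "drugs" / "pharmgkb.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(drugs.id_map.items()), columns=["accession", "symbol"]
    ).to_csv(root / "id_map.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(citations.items()), columns=["gene", "n_citations"]
    ).to_csv(root / "citations.tsv", sep="\t", index=False)
    (root / "seed_genes.txt").write_text("".join(f"{s}\n" for s in sorted(ann.seed_genes)))

    manifest = TruthManifest(
        seed=seed,
        params={
            "n_chrom": n_chrom, "n_genes": n_genes, "n_disease_loci": n_disease_loci,
            "n_null_snps": n_null_snps, "decoy_density": decoy_density,
            "hub_k": hub_k, "tau": tau, "n_known_targets": n_known_targets,
            "target_fraction": target_fraction,
            "known_drug_fraction": known_drug_fraction,
            "n_unpredicted_known": n_unpredicted_known,
            "high_citation_rate": high_citation_rate,
            "low_citation_rate": low_citation_rate,
        },
        planted_disease_genes=gwas.planted_genes,
        planted_snps=gwas.planted_snps,
        module_assignment=ann.module_assignment,
        seed_genes=ann.seed_genes,
        planted_known_targets=tuple(t for t in drugs.known_targets if t in set(gwas.planted_genes)),
        planted_novel_targets=drugs.novel_targets,
        planted_known_drugs=drugs.known_drugs,
        planted_novel_drugs=drugs.novel_drugs,
    )
    (root / "manifest.json").write_text(manifest.to_json() + "\n")

    config = {
        "association_file": "assoc.tsv",
        "gene_bed": "genome.bed",
        "annotation_files": {k: f"annotations/{k}.tsv" for k in ann.tables},
        "drug_exports": [
            {"path": "drugs/drugbank.csv", "dialect": "drugbank", "source_db": "DrugBank"},
            {"path": "drugs/ttd.tsv", "dialect": "ttd", "source_db": "TTD"},
            {"path": "drugs/pharmgkb.tsv", "dialect": "pharmgkb", "source_db": "PharmGKB"},
        ],
        "id_map": "id_map.tsv",
        "citations": "citations.tsv",
        "seed_gene_file": "seed_genes.txt",
        "tau": tau,
        "hub_k": hub_k,
        "phenotype_terms": list(phenotype_terms),
        "seed": seed,
        "outdir": "results",
    }
    import yaml

    config_path = root / "config.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=True))
    return SyntheticBundle(root, config_path, manifest)
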