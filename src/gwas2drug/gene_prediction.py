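"""Candidate-gene prediction inside search spaces.

Five principle-level prediction rules, one per knowledge source:

* CPS -- common pathway scanning: a gene is nominated when it shares a
  pathway with a gene at a *different* locus of the same search space.
* PPI -- protein-protein interaction: direct interaction with a gene at a
  different locus.
* CMP -- common module profiling: domain-profile similarity (Jaccard index
  over domain sets >= tau) to a known disease gene of the phenotype.
* CRT -- common regulatory targets: a shared transcription factor targets
  both the gene and a gene at a different locus.
* MIR -- miRNA regulation: a shared miRNA targets the gene and a gene at a
  different locus, and the gene sits in a regulatory hub (targeted by at
  least ``hub_k`` distinct miRNAs).

All rules are binary set-membership rules; no ranking scores are produced.
Intra-locus sharing never nominates a gene, and genes lacking annotation are
silently non-candidates for that rule.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .gwas_loci import SearchSpace

MODULES = ("CPS", "PPI", "CMP", "CRT", "MIR")
ANNOTATION_KINDS = ("pathway", "interaction", "domain", "tf_target", "mirna_target")

DEFAULT_TAU = 0.5
DEFAULT_HUB_K = 5


@dataclass(frozen=True)
class AnnotationTable:
    """A flat two-column annotation source: (subject, object) symbol pairs.

    ``pathway``: (pathway id, gene); ``interaction``: (gene, gene), stored
    order-independent; ``domain``: (gene, domain id); ``tf_target``:
    (transcription factor, gene); ``mirna_target``: (miRNA, gene).
    """

    kind: str
    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.kind not in ANNOTATION_KINDS:
            raise ValueError(f"unknown annotation kind {self.kind!r}")
        for a, b in self.pairs:
            if not a or not b:
                raise ValueError(f"empty symbol in pair ({a!r}, {b!r})")
        if self.kind == "interaction":
            normed = frozenset(tuple(sorted(p)) for p in self.pairs)
            object.__setattr__(self, "pairs", normed)

    @classmethod
    def from_pairs(cls, kind: str, pairs: Iterable[tuple[str, str]]) -> "AnnotationTable":
        return cls(kind, frozenset((str(a), str(b)) for a, b in pairs))

    @classmethod
    def from_tsv(cls, path, kind: str) -> "AnnotationTable":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if df.shape[1] < 2:
            raise ValueError(f"annotation table {path} needs two columns")
        return cls.from_pairs(kind, zip(df.iloc[:, 0], df.iloc[:, 1]))

    def groups(self) -> dict[str, set[str]]:
        """subject -> set of objects (e.g. pathway -> genes, TF -> targets)."""
        out: dict[str, set[str]] = defaultdict(set)
        for a, b in self.pairs:
            out[a].add(b)
        return dict(out)

    def object_sets(self) -> dict[str, set[str]]:
        """object-side grouping: gene -> set of subjects (domains per gene,
        miRNAs per gene)."""
        out: dict[str, set[str]] = defaultdict(set)
        for a, b in self.pairs:
            out[b].add(a)
        return dict(out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.pairs), columns=["subject", "object"])


@dataclass(frozen=True)
class CandidatePrediction:
    """A nominated gene with full provenance: which rules, loci and spaces."""

    gene: str
    modules: frozenset[str]
    loci: frozenset[str]
    spaces: frozenset[tuple[str, str]]  # (stratum, method)

    def __post_init__(self) -> None:
        if not self.modules:
            raise ValueError(f"{self.gene}: prediction without supporting modules")
        bad = self.modules - set(MODULES)
        if bad:
            raise ValueError(f"{self.gene}: unknown modules {sorted(bad)}")


def _cross_locus_hits(
    space: SearchSpace, groups: Mapping[str, Iterable[str]]
) -> dict[str, set[str]]:
    """For grouped annotations (pathway/TF/miRNA -> member genes): the loci at
    which each gene has a distinct group partner residing at a different locus."""
    memb = space.locus_membership()
    hits: dict[str, set[str]] = defaultdict(set)
    for members in groups.values():
        present = [g for g in set(members) if g in memb]
        if len(present) < 2:
            continue
        for g in present:
            partner_loci: set[str] = set()
            for h in present:
                if h != g:
                    partner_loci |= memb[h]
            if not partner_loci:
                continue
            for locus in memb[g]:
                if partner_loci - {locus}:
                    hits[g].add(locus)
    return dict(hits)


def _as_predictions(
    space: SearchSpace, module: str, hits: Mapping[str, set[str]]
) -> set[CandidatePrediction]:
    tag = frozenset({(space.stratum_label, space.method)})
    return {
        CandidatePrediction(g, frozenset({module}), frozenset(loci), tag)
        for g, loci in hits.items()
        if loci
    }


def predict_cps(space: SearchSpace, pathways: AnnotationTable) -> set[CandidatePrediction]:
    """Genes sharing a pathway with a gene at a different locus."""
    return _as_predictions(space, "CPS", _cross_locus_hits(space, pathways.groups()))


def predict_ppi(space: SearchSpace, interactions: AnnotationTable) -> set[CandidatePrediction]:
    """Genes directly interacting with a gene at a different locus.

    Interactions are symmetric; self-edges are ignored.
    """
    edge_groups = {
        f"{a}--{b}": (a, b) for a, b in interactions.pairs if a != b
    }
    return _as_predictions(space, "PPI", _cross_locus_hits(space, edge_groups))


def _jaccard(a: set[str], b: set[str]) -> float:
    if not a or not b:
        return 0.0
    return len(a & b) / len(a | b)


def predict_cmp(
    space: SearchSpace,
    domains: AnnotationTable,
    seed_genes: Iterable[str],
    tau: float = DEFAULT_TAU,
) -> set[CandidatePrediction]:
    """Genes whose domain profile resembles a known disease gene.

    A gene is nominated when the Jaccard index between its domain set and the
    domain set of any seed gene reaches ``tau``; empty domain sets never match.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau must be in [0, 1], got {tau}")
    dom = {g: set(d) for g, d in domains.groups().items()}
    seed_profiles = [dom[s] for s in set(seed_genes) if dom.get(s)]
    memb = space.locus_membership()
    hits: dict[str, set[str]] = {}
    for g, loci in memb.items():
        gd = dom.get(g)
        if not gd:
            continue
        if any(_jaccard(gd, sd) >= tau for sd in seed_profiles):
            hits[g] = set(loci)
    return _as_predictions(space, "CMP", hits)


def predict_crt(space: SearchSpace, tf_targets: AnnotationTable) -> set[CandidatePrediction]:
    """Genes sharing a transcription factor with a gene at a different locus."""
    return _as_predictions(space, "CRT", _cross_locus_hits(space, tf_targets.groups()))


def predict_mir(
    space: SearchSpace, mirna_targets: AnnotationTable, hub_k: int = DEFAULT_HUB_K
) -> set[CandidatePrediction]:
    """Genes with a cross-locus shared miRNA that also sit in a regulatory hub
    (>= hub_k distinct targeting miRNAs)."""
    if hub_k < 1:
        raise ValueError(f"hub_k must be >= 1, got {hub_k}")
    indegree = {g: len(ms) for g, ms in mirna_targets.object_sets().items()}
    shared = _cross_locus_hits(space, mirna_targets.groups())
    hits = {g: loci for g, loci in shared.items() if indegree.get(g, 0) >= hub_k}
    return _as_predictions(space, "MIR", hits)


def predict_all(
    space: SearchSpace,
    annotations: Mapping[str, AnnotationTable],
    seed_genes: Iterable[str] = (),
    tau: float = DEFAULT_TAU,
    hub_k: int = DEFAULT_HUB_K,
) -> set[CandidatePrediction]:
    """Run every rule whose annotation table is present on one search space."""
    out: list[set[CandidatePrediction]] = []
    if "pathway" in annotations:
        out.append(predict_cps(space, annotations["pathway"]))
    if "interaction" in annotations:
        out.append(predict_ppi(space, annotations["interaction"]))
    if "domain" in annotations:
        out.append(predict_cmp(space, annotations["domain"], seed_genes, tau))
    if "tf_target" in annotations:
        out.append(predict_crt(space, annotations["tf_target"]))
    if "mirna_target" in annotations:
        out.append(predict_mir(space, annotations["mirna_target"], hub_k))
    return combine_predictions(out)


def combine_predictions(
    prediction_sets: Iterable[Iterable[CandidatePrediction]],
) -> set[CandidatePrediction]:
    """Union per-module, per-space results into one record per gene, merging
    module, locus and space provenance."""
    merged: dict[str, CandidatePrediction] = {}
    for preds in prediction_sets:
        for p in preds:
            if p.gene in merged:
                q = merged[p.gene]
                merged[p.gene] = CandidatePrediction(
                    p.gene, q.modules | p.modules, q.loci | p.loci, q.spaces | p.spaces
                )
            else:
                merged[p.gene] = p
    return set(merged.values())


def predictions_to_frame(predictions: Iterable[CandidatePrediction]) -> pd.DataFrame:
    rows = [
        (
            p.gene,
            ";".join(sorted(p.modules)),
            len(p.loci),
            ";".join(sorted({s for s, _ in p.spaces})),
            ";".join(sorted(f"{s}:{m}" for s, m in p.spaces)),
        )
        for p in sorted(predictions, key=lambda p: p.gene)
    ]
    return pd.DataFrame(rows, columns=["gene", "modules", "n_loci", "strata", "spaces"])


def write_predictions(predictions: Iterable[CandidatePrediction], path) -> None:
    predictions_to_frame(predictions).to_csv(path, sep="\t", index=False)
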