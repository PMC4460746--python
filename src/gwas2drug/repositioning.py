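"""Candidate-gene / drug-target intersection and repositioning statistics.

A predicted candidate gene that is also a target in the pooled drug-target
dataset is a *therapeutic target*.  A target is *known* for the phenotype
when at least one of its drugs carries an indication matching a phenotype
term (normalized substring match); otherwise it is *novel* and its drugs
are repositioning candidates.  Summary statistics follow the field's usage:

* targetability index (TI) = therapeutic targets / candidate genes,
  reported as a percentage rounded to the nearest integer;
* novelty ratio = novel targets / all targets, reported truncated to two
  decimals.

Development-status classes partition targets (and drugs) into approved_only
/ clinical_only / both; items carrying only experimental or unknown
statuses are binned with clinical_only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .drug_db import PooledDrugTargets, PooledPair, VennCounts3

STATUS_CLASSES = ("approved_only", "clinical_only", "both")


class IntegrityError(ValueError):
    """A summary identity (partition or ratio bound) failed to hold."""


class UndefinedRatioError(ZeroDivisionError):
    """Requested ratio has a zero denominator."""


@dataclass(frozen=True)
class TherapeuticTarget:
    """A candidate gene with at least one drug in the pooled dataset."""

    gene: str
    pairs: tuple[PooledPair, ...]
    is_known: bool | None = None

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError(f"{self.gene}: therapeutic target without drugs")

    @property
    def drugs(self) -> frozenset[str]:
        return frozenset(p.drug_key for p in self.pairs)

    @property
    def source_dbs(self) -> frozenset[str]:
        return frozenset(db for p in self.pairs for db in p.source_dbs)

    @property
    def statuses(self) -> frozenset[str]:
        return frozenset(s for p in self.pairs for s in p.statuses)

    @property
    def status_class(self) -> str:
        return status_class(self.statuses)


@dataclass(frozen=True)
class DrugSummary:
    """One pooled drug aggregated over its targets."""

    drug_key: str
    drug_name: str
    targets: frozenset[str]
    statuses: frozenset[str]
    indications: frozenset[str]
    is_known: bool | None = None

    @property
    def status_class(self) -> str:
        return status_class(self.statuses)


def normalize_text(s: str) -> str:
    return " ".join(str(s).strip().casefold().split())


def indication_matches(indications: Iterable[str], phenotype_terms: Iterable[str]) -> bool:
    """Normalized substring match of any phenotype term in any indication."""
    terms = [normalize_text(t) for t in phenotype_terms if str(t).strip()]
    if not terms:
        raise ValueError("phenotype_terms must be non-empty")
    for ind in indications:
        ind_n = normalize_text(ind)
        if any(t in ind_n for t in terms):
            return True
    return False


def map_targets(
    candidates: Iterable[str], pooled: PooledDrugTargets
) -> list[TherapeuticTarget]:
    """Intersect candidate genes with pooled drug targets."""
    by_target = pooled.by_target
    out = [
        TherapeuticTarget(g, tuple(sorted(by_target[g])))
        for g in sorted(set(candidates))
        if g in by_target
    ]
    return out


def classify_target_novelty(
    targets: Iterable[TherapeuticTarget], phenotype_terms: Iterable[str]
) -> list[TherapeuticTarget]:
    """Set is_known: true iff any associated drug is indicated for the phenotype."""
    terms = list(phenotype_terms)
    out = []
    for t in targets:
        known = any(indication_matches(p.indications, terms) for p in t.pairs if p.indications)
        out.append(replace(t, is_known=known))
    return out


def status_class(statuses: Iterable[str]) -> str:
    """approved_only / clinical_only / both from a set of member statuses.

    experimental and unknown count toward the clinical bin; an item with both
    an approved and a clinical-bin status is 'both'.
    """
    statuses = set(statuses)
    has_approved = "approved" in statuses
    has_clinical = bool(statuses - {"approved"})
    if has_approved and has_clinical:
        return "both"
    if has_approved:
        return "approved_only"
    return "clinical_only"


@dataclass(frozen=True)
class StatusBreakdown:
    approved_only: int
    clinical_only: int
    both: int

    @property
    def total(self) -> int:
        return self.approved_only + self.clinical_only + self.both


def classify_status(items: Iterable[TherapeuticTarget | DrugSummary]) -> StatusBreakdown:
    counts = {c: 0 for c in STATUS_CLASSES}
    for item in items:
        counts[item.status_class] += 1
    return StatusBreakdown(**{k.replace("_only", "_only"): v for k, v in counts.items()})


def aggregate_drugs(
    targets: Iterable[TherapeuticTarget], phenotype_terms: Iterable[str] | None = None
) -> list[DrugSummary]:
    """Aggregate the pooled pairs of the given targets into per-drug records."""
    slots: dict[str, dict] = {}
    for t in targets:
        for p in t.pairs:
            s = slots.setdefault(
                p.drug_key,
                {"name": p.drug_name, "targets": set(), "statuses": set(), "inds": set()},
            )
            s["targets"].add(t.gene)
            s["statuses"] |= set(p.statuses)
            s["inds"] |= set(p.indications)
    out = []
    for key in sorted(slots):
        s = slots[key]
        known = None
        if phenotype_terms is not None:
            known = bool(s["inds"]) and indication_matches(s["inds"], phenotype_terms)
        out.append(
            DrugSummary(
                drug_key=key, drug_name=s["name"], targets=frozenset(s["targets"]),
                statuses=frozenset(s["statuses"]), indications=frozenset(s["inds"]),
                is_known=known,
            )
        )
    return out


def targetability_index(n_targets: int, n_candidates: int) -> float:
    """Therapeutic targets as a fraction of predicted candidate genes."""
    if n_candidates <= 0:
        raise UndefinedRatioError("targetability index undefined for zero candidates")
    if n_targets > n_candidates:
        raise IntegrityError(f"n_targets {n_targets} > n_candidates {n_candidates}")
    return n_targets / n_candidates


def novelty_ratio(n_novel: int, n_targets: int) -> float:
    """Novel therapeutic targets as a fraction of all therapeutic targets."""
    if n_targets <= 0:
        raise UndefinedRatioError("novelty ratio undefined for zero targets")
    if n_novel > n_targets:
        raise IntegrityError(f"n_novel {n_novel} > n_targets {n_targets}")
    return n_novel / n_targets


def render_percent(fraction: float) -> str:
    """Report a fraction as a whole-number percentage (nearest integer)."""
    return f"{int(math.floor(fraction * 100 + 0.5))}%"


def render_ratio(ratio: float) -> str:
    """Report a ratio truncated (not rounded) to two decimals."""
    return f"{math.floor(ratio * 100) / 100:.2f}"


@dataclass(frozen=True)
class RepositioningSummary:
    """All headline counts of one pipeline run, with their identities."""

    n_candidates: int
    n_targets: int
    n_known_targets: int
    n_novel_targets: int
    targetability_index: float | None
    novelty_ratio: float | None
    n_drugs: int
    n_known_drugs: int
    n_novel_drugs: int
    novel_target_status: StatusBreakdown
    novel_drug_status: StatusBreakdown
    per_db_targets: Mapping[str, int]
    target_venn: VennCounts3 | None

    def validate(self) -> None:
        if self.n_targets != self.n_known_targets + self.n_novel_targets:
            raise IntegrityError("n_targets != n_known_targets + n_novel_targets")
        if self.n_drugs != self.n_known_drugs + self.n_novel_drugs:
            raise IntegrityError("n_drugs != n_known_drugs + n_novel_drugs")
        if self.targetability_index is not None and not 0 <= self.targetability_index <= 1:
            raise IntegrityError("targetability_index outside [0, 1]")
        if self.novelty_ratio is not None and not 0 <= self.novelty_ratio <= 1:
            raise IntegrityError("novelty_ratio outside [0, 1]")
        if self.novel_target_status.total != self.n_novel_targets:
            raise IntegrityError("novel-target status breakdown does not sum to n_novel_targets")
        if self.novel_drug_status.total != self.n_novel_drugs:
            raise IntegrityError("novel-drug status breakdown does not sum to n_novel_drugs")

    def to_dict(self) -> dict:
        return {
            "n_candidates": self.n_candidates,
            "n_targets": self.n_targets,
            "n_known_targets": self.n_known_targets,
            "n_novel_targets": self.n_novel_targets,
            "targetability_index": self.targetability_index,
            "targetability_index_rendered": (
                render_percent(self.targetability_index)
                if self.targetability_index is not None else "undefined"
            ),
            "novelty_ratio": self.novelty_ratio,
            "novelty_ratio_rendered": (
                render_ratio(self.novelty_ratio)
                if self.novelty_ratio is not None else "undefined"
            ),
            "n_drugs": self.n_drugs,
            "n_known_drugs": self.n_known_drugs,
            "n_novel_drugs": self.n_novel_drugs,
            "novel_targets_approved_only": self.novel_target_status.approved_only,
            "novel_targets_clinical_only": self.novel_target_status.clinical_only,
            "novel_targets_both": self.novel_target_status.both,
            "novel_drugs_approved_only": self.novel_drug_status.approved_only,
            "novel_drugs_clinical_only": self.novel_drug_status.clinical_only,
            "novel_drugs_both": self.novel_drug_status.both,
            "per_db_targets": dict(sorted(self.per_db_targets.items())),
            "target_venn": self.target_venn.as_dict() if self.target_venn else None,
        }


def summarize(
    candidates: Iterable[str],
    targets: Sequence[TherapeuticTarget],
    drugs: Sequence[DrugSummary],
    venn: VennCounts3 | None = None,
) -> RepositioningSummary:
    """Aggregate one run; all partition identities are checked on construction."""
    candidates = set(candidates)
    if any(t.is_known is None for t in targets):
        raise IntegrityError("targets must be novelty-classified before summarize()")
    if any(d.is_known is None for d in drugs):
        raise IntegrityError("drugs must be novelty-classified before summarize()")
    not_candidates = [t.gene for t in targets if t.gene not in candidates]
    if not_candidates:
        raise IntegrityError(f"targets outside candidate set: {not_candidates[:5]}")
    known_t = [t for t in targets if t.is_known]
    novel_t = [t for t in targets if not t.is_known]
    known_d = [d for d in drugs if d.is_known]
    novel_d = [d for d in drugs if not d.is_known]
    per_db = {}
    for db in sorted({db for t in targets for db in t.source_dbs}):
        per_db[db] = sum(1 for t in targets if db in t.source_dbs)
    summary = RepositioningSummary(
        n_candidates=len(candidates),
        n_targets=len(targets),
        n_known_targets=len(known_t),
        n_novel_targets=len(novel_t),
        targetability_index=(
            targetability_index(len(targets), len(candidates)) if candidates else None
        ),
        novelty_ratio=novelty_ratio(len(novel_t), len(targets)) if targets else None,
        n_drugs=len(drugs),
        n_known_drugs=len(known_d),
        n_novel_drugs=len(novel_d),
        novel_target_status=classify_status(novel_t),
        novel_drug_status=classify_status(novel_d),
        per_db_targets=per_db,
        target_venn=venn,
    )
    summary.validate()
    return summary


def targets_to_frame(targets: Iterable[TherapeuticTarget]) -> pd.DataFrame:
    rows = [
        (t.gene, t.is_known, t.status_class, len(t.drugs), ";".join(sorted(t.source_dbs)))
        for t in sorted(targets, key=lambda t: t.gene)
    ]
    return pd.DataFrame(rows, columns=["gene", "is_known", "status_class", "n_drugs", "dbs"])


def drugs_to_frame(drugs: Iterable[DrugSummary]) -> pd.DataFrame:
    rows = [
        (d.drug_key, "known" if d.is_known else "novel", d.status_class,
         ";".join(sorted(d.targets)))
        for d in sorted(drugs, key=lambda d: d.drug_key)
    ]
    return pd.DataFrame(rows, columns=["drug", "novelty", "status_class", "targets"])
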