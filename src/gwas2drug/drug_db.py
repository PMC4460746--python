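"""Drug-target database parsing, harmonization, pooling and Venn statistics.

Three export dialects (DrugBank-like CSV, TTD-like TSV, PharmGKB-like TSV)
are mapped onto a common record: (drug, target, development status,
indications, action, source database).  Statuses are normalized to a closed
vocabulary -- approved / clinical / experimental / unknown -- where
"Launched" counts as approved and any phase/trial string counts as clinical.
Targets are harmonized to HUGO symbols via an accession-to-symbol map;
records whose target cannot be mapped to a human symbol are dropped and
counted.  Pooled (drug, target) pairs are deduplicated by case-folded drug
name with merged source-database provenance.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

SOURCE_DBS = ("DrugBank", "TTD", "PharmGKB")
STATUS_VOCAB = ("approved", "clinical", "experimental", "unknown")

_APPROVED_PAT = re.compile(r"launch|approv", re.I)
_CLINICAL_PAT = re.compile(r"phase|clinical|trial|investigation", re.I)
_EXPERIMENTAL_PAT = re.compile(r"experimental|preclinical", re.I)

#: UniProt accession shapes (6- and 10-character forms).
UNIPROT_RE = re.compile(
    r"^(?:[OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9](?:[A-Z][A-Z0-9]{2}[0-9]){1,2})$"
)


def normalize_status(raw: str) -> str:
    """Map a free-text development-status string to the closed vocabulary."""
    raw = (raw or "").strip()
    if _APPROVED_PAT.search(raw):
        return "approved"
    if _CLINICAL_PAT.search(raw):
        return "clinical"
    if _EXPERIMENTAL_PAT.search(raw):
        return "experimental"
    return "unknown"


def normalize_drug_name(name: str) -> str:
    """Drug identity across databases: case-folded, whitespace-normalized name."""
    return " ".join(str(name).strip().casefold().split())


@dataclass(frozen=True)
class DrugExportDialect:
    """Column mapping and normalizers for one database export format."""

    sep: str
    drug_name: str
    target: str
    status: str
    indication: str
    drug_id: str | None = None
    action: str | None = None
    indication_sep: str = ";"
    status_overrides: Mapping[str, str] = field(default_factory=dict)


DEFAULT_DIALECTS: dict[str, DrugExportDialect] = {
    "drugbank": DrugExportDialect(
        sep=",", drug_id="drugbank_id", drug_name="name", target="gene_name",
        status="groups", indication="indication", action="actions",
    ),
    "ttd": DrugExportDialect(
        sep="\t", drug_id="ttd_id", drug_name="drug_name", target="target",
        status="highest_status", indication="indication", action="moa",
    ),
    "pharmgkb": DrugExportDialect(
        sep="\t", drug_id="pharmgkb_id", drug_name="chemical", target="gene",
        status="type", indication="diseases", action="association",
    ),
}


@dataclass(frozen=True, order=True)
class DrugTargetRecord:
    """One drug-target association from one source database."""

    drug_id: str
    drug_name: str
    target: str
    source_db: str
    status: str
    indications: frozenset[str]
    action: str = ""

    def __post_init__(self) -> None:
        if not self.target:
            raise ValueError("target symbol must be non-empty")
        if self.source_db not in SOURCE_DBS:
            raise ValueError(f"unknown source_db {self.source_db!r}")
        if self.status not in STATUS_VOCAB:
            raise ValueError(f"status {self.status!r} outside closed vocabulary")

    @property
    def drug_key(self) -> str:
        return normalize_drug_name(self.drug_name)


class DrugParse(NamedTuple):
    records: list[DrugTargetRecord]
    n_unknown_status: int


def parse_drug_export(
    path, dialect: DrugExportDialect | str, source_db: str
) -> DrugParse:
    """Parse one database export into normalized drug-target records."""
    if isinstance(dialect, str):
        dialect = DEFAULT_DIALECTS[dialect]
    df = pd.read_csv(path, sep=dialect.sep, dtype=str, keep_default_na=False)
    if df.empty:
        return DrugParse([], 0)
    required = [dialect.drug_name, dialect.target, dialect.status, dialect.indication]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"drug export {path} lacks declared columns {missing}")

    records: list[DrugTargetRecord] = []
    n_unknown = 0
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        raw_status = str(d[dialect.status])
        status = dialect.status_overrides.get(raw_status, normalize_status(raw_status))
        if status == "unknown" and raw_status.strip().lower() not in {"", "unknown"}:
            n_unknown += 1
        target = str(d[dialect.target]).strip()
        if not target:
            continue
        indications = frozenset(
            tok.strip().lower()
            for tok in str(d[dialect.indication]).split(dialect.indication_sep)
            if tok.strip()
        )
        records.append(
            DrugTargetRecord(
                drug_id=str(d.get(dialect.drug_id, "")) if dialect.drug_id else "",
                drug_name=str(d[dialect.drug_name]),
                target=target,
                source_db=source_db,
                status=status,
                indications=indications,
                action=str(d.get(dialect.action, "")) if dialect.action else "",
            )
        )
    if n_unknown:
        logger.warning("%s: %d unrecognized status tokens mapped to 'unknown'", path, n_unknown)
    return DrugParse(records, n_unknown)


class HugoMapping(NamedTuple):
    records: list[DrugTargetRecord]
    n_dropped: int
    n_ambiguous: int


def map_to_hugo(
    records: Iterable[DrugTargetRecord],
    id_map: Mapping[str, str | Sequence[str]],
) -> HugoMapping:
    """Harmonize targets to HUGO symbols.

    Targets present in ``id_map`` are translated; accession-shaped targets
    absent from the map are dropped (non-human or untranslatable); anything
    else is taken to already be a symbol and passes through.  An accession
    mapping to several symbols duplicates the record, once per symbol.
    """
    out: list[DrugTargetRecord] = []
    n_dropped = 0
    n_ambiguous = 0
    for rec in records:
        t = rec.target
        if t in id_map:
            symbols = id_map[t]
            if isinstance(symbols, str):
                symbols = [symbols]
            if len(symbols) > 1:
                n_ambiguous += 1
            for sym in symbols:
                out.append(replace(rec, target=sym))
        elif UNIPROT_RE.match(t):
            n_dropped += 1
        else:
            out.append(rec)
    if n_dropped:
        logger.warning("dropped %d records with untranslatable accessions", n_dropped)
    return HugoMapping(out, n_dropped, n_ambiguous)


def read_id_map(path) -> dict[str, list[str]]:
    """Accession -> symbol(s) table (TSV: accession, symbol)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict[str, list[str]] = {}
    for acc, sym in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(str(acc), []).append(str(sym))
    return out


@dataclass(frozen=True, order=True)
class PooledPair:
    """One deduplicated (drug, target) pair with merged provenance."""

    drug_key: str
    target: str
    drug_name: str
    source_dbs: frozenset[str]
    statuses: frozenset[str]
    indications: frozenset[str]
    actions: frozenset[str]


@dataclass(frozen=True)
class PooledDrugTargets:
    """The pooled drug-target dataset across source databases."""

    records: tuple[PooledPair, ...]

    @property
    def by_target(self) -> dict[str, list[PooledPair]]:
        out: dict[str, list[PooledPair]] = {}
        for r in self.records:
            out.setdefault(r.target, []).append(r)
        return out

    @property
    def by_drug(self) -> dict[str, list[PooledPair]]:
        out: dict[str, list[PooledPair]] = {}
        for r in self.records:
            out.setdefault(r.drug_key, []).append(r)
        return out

    @property
    def unique_targets(self) -> frozenset[str]:
        return frozenset(r.target for r in self.records)

    @property
    def unique_drugs(self) -> frozenset[str]:
        return frozenset(r.drug_key for r in self.records)

    def targets_of(self, source_db: str) -> frozenset[str]:
        return frozenset(r.target for r in self.records if source_db in r.source_dbs)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (r.drug_key, r.drug_name, r.target, ";".join(sorted(r.source_dbs)),
             ";".join(sorted(r.statuses)), ";".join(sorted(r.indications)),
             ";".join(sorted(a for a in r.actions if a)))
            for r in sorted(self.records)
        ]
        return pd.DataFrame(
            rows,
            columns=["drug_key", "drug_name", "target", "source_dbs", "statuses",
                     "indications", "actions"],
        )


def pool_databases(
    *collections: Iterable[DrugTargetRecord | PooledPair],
) -> PooledDrugTargets:
    """Pool record collections, deduplicating (drug name, target) pairs.

    Accepts raw records or already-pooled pairs, so pooling is idempotent.
    """
    merged: dict[tuple[str, str], dict] = {}
    for coll in collections:
        for rec in coll:
            if isinstance(rec, PooledPair):
                key = (rec.drug_key, rec.target)
                dbs, statuses = rec.source_dbs, rec.statuses
                indications, actions = rec.indications, rec.actions
                name = rec.drug_name
            else:
                key = (rec.drug_key, rec.target)
                dbs, statuses = {rec.source_db}, {rec.status}
                indications = rec.indications
                actions = {rec.action} if rec.action else set()
                name = rec.drug_name
            slot = merged.setdefault(
                key,
                {"name": name, "dbs": set(), "statuses": set(),
                 "indications": set(), "actions": set()},
            )
            slot["dbs"] |= set(dbs)
            slot["statuses"] |= set(statuses)
            slot["indications"] |= set(indications)
            slot["actions"] |= set(actions)
    pairs = tuple(
        sorted(
            PooledPair(
                drug_key=k[0], target=k[1], drug_name=v["name"],
                source_dbs=frozenset(v["dbs"]), statuses=frozenset(v["statuses"]),
                indications=frozenset(v["indications"]), actions=frozenset(v["actions"]),
            )
            for k, v in merged.items()
        )
    )
    return PooledDrugTargets(pairs)


@dataclass(frozen=True)
class VennCounts3:
    """The seven exclusive regions of a three-set Venn diagram."""

    only_a: int
    only_b: int
    only_c: int
    ab_only: int
    ac_only: int
    bc_only: int
    abc: int

    def __post_init__(self) -> None:
        for name, v in self.as_dict().items():
            if v < 0:
                raise ValueError(f"negative Venn region {name}={v}")

    def as_dict(self) -> dict[str, int]:
        return {
            "only_a": self.only_a, "only_b": self.only_b, "only_c": self.only_c,
            "ab_only": self.ab_only, "ac_only": self.ac_only, "bc_only": self.bc_only,
            "abc": self.abc,
        }

    @property
    def total_a(self) -> int:
        return self.only_a + self.ab_only + self.ac_only + self.abc

    @property
    def total_b(self) -> int:
        return self.only_b + self.ab_only + self.bc_only + self.abc

    @property
    def total_c(self) -> int:
        return self.only_c + self.ac_only + self.bc_only + self.abc

    @property
    def union(self) -> int:
        return sum(self.as_dict().values())


def venn_regions(a: Iterable, b: Iterable, c: Iterable) -> VennCounts3:
    """Exclusive three-set region counts by direct membership enumeration."""
    a, b, c = set(a), set(b), set(c)
    return VennCounts3(
        only_a=len(a - b - c),
        only_b=len(b - a - c),
        only_c=len(c - a - b),
        ab_only=len((a & b) - c),
        ac_only=len((a & c) - b),
        bc_only=len((b & c) - a),
        abc=len(a & b & c),
    )


def venn_from_totals(
    total_a: int, total_b: int, total_c: int,
    ab_only: int, ac_only: int, bc_only: int, abc: int,
) -> VennCounts3:
    """Reconstruct exclusive singles from per-set totals plus printed
    pairwise-exclusive overlaps and the triple region."""
    return VennCounts3(
        only_a=total_a - ab_only - ac_only - abc,
        only_b=total_b - ab_only - bc_only - abc,
        only_c=total_c - ac_only - bc_only - abc,
        ab_only=ab_only, ac_only=ac_only, bc_only=bc_only, abc=abc,
    )
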