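"""SNP association results, significance strata, and gene search spaces.

A GWAS association table is stratified into four nested significance sets of
decreasing stringency -- highly significant (HS, p <= 5e-7), medium-highly
significant (MHS, p <= 1e-5), medium-weakly significant (MWS, p <= 1e-4) and
weakly significant (WS, p <= 1e-3).  Around each SNP of a stratum a genetic
locus is built by one of six construction methods: three fixed-width windows
(default half-widths 100 kb, 500 kb and 1 Mb) and three proximity rules
(1, 3 or 5 nearest genes).  4 strata x 6 methods = 24 gene search spaces.

Coordinate conventions: SNP positions are 1-based (association-file
convention), gene intervals are 0-based half-open (BED convention).  The
1-based SNP position is converted exactly once, when a locus is built, and
strand is ignored by all distance computations (distance is measured to the
gene interval, not to the transcription start site).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STRATUM_LABELS = ("HS", "MHS", "MWS", "WS")
DEFAULT_THRESHOLDS = (5e-7, 1e-5, 1e-4, 1e-3)

#: Default association-file column mapping (PLINK ``.assoc`` header).
DEFAULT_DIALECT = {"snp": "SNP", "chrom": "CHR", "pos": "BP", "p": "P"}

#: Six search-space construction methods and their default parameters.
FIXED_WIDTH_METHODS = {
    "fixed_100kb": 100_000,
    "fixed_500kb": 500_000,
    "fixed_1Mb": 1_000_000,
}
NEAREST_METHODS = {"nearest_1": 1, "nearest_3": 3, "nearest_5": 5}
METHOD_NAMES = tuple(FIXED_WIDTH_METHODS) + tuple(NEAREST_METHODS)


class ConfigurationError(ValueError):
    """Raised when user-supplied configuration is invalid."""


@dataclass(frozen=True, order=True)
class SnpAssociation:
    """One SNP with genomic position and association p-value."""

    snp_id: str
    chrom: str
    pos: int  # 1-based base pairs
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value!r}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos!r}")


@dataclass(frozen=True)
class SignificanceStratum:
    """A nested SNP significance set (HS, MHS, MWS or WS)."""

    label: str
    threshold: float
    snps: frozenset[SnpAssociation]

    def __post_init__(self) -> None:
        bad = [s.snp_id for s in self.snps if s.p_value > self.threshold]
        if bad:
            raise ValueError(
                f"stratum {self.label}: members above threshold {self.threshold}: {bad[:5]}"
            )

    def __len__(self) -> int:
        return len(self.snps)


@dataclass(frozen=True, order=True)
class GeneRecord:
    """A gene interval in 0-based half-open (BED) coordinates."""

    symbol: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.symbol}: start must be < end ({self.start}, {self.end})")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"{self.symbol}: bad strand {self.strand!r}")


class Locus(NamedTuple):
    """One SNP-anchored genetic locus and its assigned genes."""

    snp_ids: tuple[str, ...]
    chrom: str
    start: int
    end: int
    genes: frozenset[str]


@dataclass(frozen=True)
class SearchSpace:
    """Genes assigned to SNP loci under one (stratum x method) combination."""

    stratum_label: str
    method: str
    loci: Mapping[str, Locus]

    @property
    def gene_universe(self) -> frozenset[str]:
        out: set[str] = set()
        for locus in self.loci.values():
            out.update(locus.genes)
        return frozenset(out)

    def locus_membership(self) -> dict[str, set[str]]:
        """Map gene symbol -> ids of the loci that contain it."""
        memb: dict[str, set[str]] = {}
        for lid, locus in self.loci.items():
            for g in locus.genes:
                memb.setdefault(g, set()).add(lid)
        return memb


class AssociationParse(NamedTuple):
    records: list[SnpAssociation]
    n_rejected: int


def parse_association_file(
    path,
    dialect: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> AssociationParse:
    """Parse a PLINK-style association table.

    Rows whose p-value is non-numeric or outside (0, 1], or whose position is
    not a positive integer, are dropped and counted in ``n_rejected``.
    """
    dialect = dict(DEFAULT_DIALECT, **(dialect or {}))
    df = pd.read_csv(path, sep=sep or r"\s+", dtype=str, keep_default_na=False)
    if df.empty and df.columns.size == 0:
        logger.warning("association file %s is empty", path)
        return AssociationParse([], 0)
    missing = [c for c in dialect.values() if c not in df.columns]
    if missing:
        raise ConfigurationError(f"association file {path} lacks mapped columns {missing}")

    records: list[SnpAssociation] = []
    n_rejected = 0
    for row in df.itertuples(index=False):
        d = row._asdict()
        try:
            p = float(d[dialect["p"]])
            pos = int(d[dialect["pos"]])
            rec = SnpAssociation(
                snp_id=str(d[dialect["snp"]]),
                chrom=str(d[dialect["chrom"]]),
                pos=pos,
                p_value=p,
            )
        except (ValueError, TypeError):
            n_rejected += 1
            continue
        records.append(rec)
    if n_rejected:
        logger.warning("%s: rejected %d malformed rows", path, n_rejected)
    seen = [r.snp_id for r in records]
    if len(set(seen)) != len(seen):
        raise ConfigurationError(f"duplicate SNP ids in {path}")
    return AssociationParse(records, n_rejected)


def write_association_file(records: Iterable[SnpAssociation], path) -> None:
    df = pd.DataFrame(
        [(r.chrom, r.snp_id, r.pos, r.p_value) for r in records],
        columns=["CHR", "SNP", "BP", "P"],
    )
    df.to_csv(path, sep="\t", index=False)


def stratify_snps(
    snps: Iterable[SnpAssociation],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    labels: Sequence[str] = STRATUM_LABELS,
) -> list[SignificanceStratum]:
    """Build the nested significance strata (inclusive bounds, p <= t)."""
    thresholds = tuple(thresholds)
    if len(thresholds) != len(labels):
        raise ConfigurationError("one threshold per stratum label required")
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ConfigurationError(f"thresholds must be strictly increasing: {thresholds}")
    snps = list(snps)
    return [
        SignificanceStratum(lab, t, frozenset(s for s in snps if s.p_value <= t))
        for lab, t in zip(labels, thresholds)
    ]


def read_bed(path) -> list[GeneRecord]:
    """Read gene annotation from BED (chrom, start, end, name[, score, strand])."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, keep_default_na=False)
    if df.shape[1] < 4:
        raise ConfigurationError(f"BED file {path} needs >= 4 columns (chrom start end name)")
    genes = []
    for row in df.itertuples(index=False):
        strand = str(row[5]) if df.shape[1] >= 6 else "."
        genes.append(
            GeneRecord(
                symbol=str(row[3]),
                chrom=str(row[0]),
                start=int(row[1]),
                end=int(row[2]),
                strand=strand if strand in {"+", "-"} else ".",
            )
        )
    symbols = [g.symbol for g in genes]
    if len(set(symbols)) != len(symbols):
        raise ConfigurationError(f"duplicate gene symbols in {path}")
    return genes


def write_bed(genes: Iterable[GeneRecord], path) -> None:
    df = pd.DataFrame(
        [(g.chrom, g.start, g.end, g.symbol, 0, g.strand) for g in sorted(genes)],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )
    df.to_csv(path, sep="\t", header=False, index=False)


class _GeneIndex:
    """Per-chromosome arrays for vectorised window and proximity queries."""

    def __init__(self, genes: Sequence[GeneRecord]):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[GeneRecord]] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, gs in by_chrom.items():
            gs.sort(key=lambda g: (g.start, g.symbol))
            self._by_chrom[chrom] = (
                np.array([g.start for g in gs], dtype=np.int64),
                np.array([g.end for g in gs], dtype=np.int64),
                np.array([g.symbol for g in gs], dtype=object),
            )

    def overlapping(self, chrom: str, lo: int, hi: int) -> frozenset[str]:
        """Genes whose [start, end) intersects [lo, hi)."""
        if chrom not in self._by_chrom or hi <= lo:
            return frozenset()
        starts, ends, symbols = self._by_chrom[chrom]
        mask = (starts < hi) & (ends > lo)
        return frozenset(symbols[mask].tolist())

    def nearest(self, chrom: str, pos0: int, k: int) -> frozenset[str]:
        """The k genes with minimal base-pair distance to pos0 (0 if inside);
        ties broken by lexicographic symbol."""
        if chrom not in self._by_chrom:
            return frozenset()
        starts, ends, symbols = self._by_chrom[chrom]
        dist = np.maximum(starts - pos0, 0) + np.maximum(pos0 - (ends - 1), 0)
        order = np.lexsort((symbols, dist))
        return frozenset(symbols[order[:k]].tolist())


def build_search_space(
    stratum: SignificanceStratum,
    genes: Sequence[GeneRecord],
    method: str,
    param: int | None = None,
    _index: "_GeneIndex | None" = None,
) -> SearchSpace:
    """Construct one search space: a locus per stratum SNP with its gene set.

    ``param`` overrides the method default (half-width in bp for fixed-width
    methods, k for proximity methods).  Loci on chromosomes with no annotated
    genes are kept, with empty gene sets.
    """
    if method in FIXED_WIDTH_METHODS:
        kind, p = "fixed", param if param is not None else FIXED_WIDTH_METHODS[method]
    elif method in NEAREST_METHODS:
        kind, p = "nearest", param if param is not None else NEAREST_METHODS[method]
    else:
        raise ConfigurationError(f"unknown search-space method {method!r}")
    index = _index if _index is not None else _GeneIndex(genes)

    loci: dict[str, Locus] = {}
    for snp in sorted(stratum.snps):
        pos0 = snp.pos - 1  # 1-based -> 0-based, done once per locus
        if kind == "fixed":
            lo, hi = max(0, pos0 - p), pos0 + p
            gset = index.overlapping(snp.chrom, lo, hi)
        else:
            lo, hi = pos0, pos0 + 1
            gset = index.nearest(snp.chrom, pos0, p)
        loci[snp.snp_id] = Locus((snp.snp_id,), snp.chrom, lo, hi, gset)
    return SearchSpace(stratum.label, method, loci)


def build_all_search_spaces(
    strata: Sequence[SignificanceStratum],
    genes: Sequence[GeneRecord],
    fixed_widths: Mapping[str, int] | None = None,
    nearest_ks: Mapping[str, int] | None = None,
) -> list[SearchSpace]:
    """All (stratum x method) search spaces -- 24 under the default four strata."""
    fixed = dict(FIXED_WIDTH_METHODS, **(fixed_widths or {}))
    near = dict(NEAREST_METHODS, **(nearest_ks or {}))
    index = _GeneIndex(genes)
    spaces = []
    for stratum in strata:
        for method, w in fixed.items():
            spaces.append(build_search_space(stratum, genes, method, w, _index=index))
        for method, k in near.items():
            spaces.append(build_search_space(stratum, genes, method, k, _index=index))
    return spaces


def search_space_gene_universe(spaces: Sequence[SearchSpace]) -> frozenset[str]:
    """Union of gene symbols across the six search spaces of one stratum."""
    labels = {s.stratum_label for s in spaces}
    if len(labels) > 1:
        raise ValueError(f"search spaces from mixed strata: {sorted(labels)}")
    out: set[str] = set()
    for s in spaces:
        out.update(s.gene_universe)
    return frozenset(out)


def spaces_to_frame(spaces: Sequence[SearchSpace]) -> pd.DataFrame:
    """Serialize search spaces, one row per (locus, gene); empty loci keep a
    row with an empty gene field so deserialization is lossless."""
    rows = []
    for s in spaces:
        for lid in sorted(s.loci):
            locus = s.loci[lid]
            genes = sorted(locus.genes) or [""]
            for g in genes:
                rows.append(
                    (s.stratum_label, s.method, lid, ";".join(locus.snp_ids),
                     locus.chrom, locus.start, locus.end, g)
                )
    df = pd.DataFrame(
        rows,
        columns=["stratum", "method", "locus_id", "snp_ids", "chrom", "start", "end", "gene"],
    )
    return df.sort_values(list(df.columns), kind="mergesort").reset_index(drop=True)


def spaces_from_frame(df: pd.DataFrame) -> list[SearchSpace]:
    spaces = []
    for (stratum, method), grp in df.groupby(["stratum", "method"], sort=True):
        loci: dict[str, Locus] = {}
        for lid, lgrp in grp.groupby("locus_id", sort=True):
            first = lgrp.iloc[0]
            genes = frozenset(g for g in lgrp["gene"].astype(str) if g)
            loci[str(lid)] = Locus(
                tuple(str(first["snp_ids"]).split(";")),
                str(first["chrom"]), int(first["start"]), int(first["end"]), genes,
            )
        spaces.append(SearchSpace(str(stratum), str(method), loci))
    return spaces


def write_search_spaces(spaces: Sequence[SearchSpace], path) -> None:
    spaces_to_frame(spaces).to_csv(path, sep="\t", index=False)


def read_search_spaces(path) -> list[SearchSpace]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return spaces_from_frame(df)
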