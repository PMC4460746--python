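"""Validation benchmarks: contingency classification and ROC analysis.

Two benchmarks validate predicted therapeutic targets against independent
evidence:

1. **Known-target benchmark.**  Over a benchmark universe (by default the
   union of the six search spaces of the weakly-significant stratum), genes
   already targeted by drugs registered for the phenotype are the positive
   class.  Predicted targets present in each of the six search spaces give
   six nested prediction sets, hence six (FPR, TPR) points -- one
   contingency table per space -- assembled into a ROC curve.

2. **Literature-citation benchmark.**  Genes are scored by the number of
   publications citing both the gene and the phenotype.  Four citation
   thresholds (1, 5, 10 and 15 by default) define four positive classes and
   four contingency tables, again assembled into a ROC curve.

AUC is the trapezoidal area under the threshold points anchored at (0,0)
and (1,1).  Significance against the chance level of 0.5 is assessed with a
rank-sum (Mann-Whitney) AUC on per-gene scores plus a seeded label
permutation test; the trapezoid and rank-sum formulations agree exactly on
score-threshold ROC curves, which the test suite exploits as a
cross-check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_CITATION_THRESHOLDS = (1, 5, 10, 15)


@dataclass(frozen=True)
class ContingencyTable:
    """TP/FP/FN/TN counts underlying one ROC point."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative count {name}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def tpr(self) -> float | None:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) > 0 else None

    @property
    def fpr(self) -> float | None:
        return self.fp / (self.fp + self.tn) if (self.fp + self.tn) > 0 else None


@dataclass(frozen=True)
class CitationRecord:
    gene: str
    n_phenotype_citations: int

    def __post_init__(self) -> None:
        if self.n_phenotype_citations < 0:
            raise ValueError("citation count must be >= 0")


@dataclass(frozen=True)
class RocCurve:
    """Ordered (fpr, tpr) points anchored at (0,0) and (1,1), with
    trapezoidal AUC."""

    points: tuple[tuple[float, float], ...]
    auc: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0 + 1e-12:
            raise ValueError(f"auc outside [0, 1]: {self.auc}")


def contingency_table(
    universe: Iterable[str], predicted: Iterable[str], known: Iterable[str]
) -> ContingencyTable:
    """Classify the universe into TP/FP/FN/TN.

    ``predicted`` must lie inside the universe; known positives outside the
    universe are excluded (and logged), mirroring benchmark construction
    where only search-space genes are classifiable.
    """
    universe, predicted, known = set(universe), set(predicted), set(known)
    if not universe:
        raise ValueError("benchmark universe is empty")
    if predicted - universe:
        raise ValueError(
            f"predicted genes outside universe: {sorted(predicted - universe)[:5]}"
        )
    outside = known - universe
    if outside:
        logger.warning("%d known positives outside the universe excluded", len(outside))
    known &= universe
    tp = len(predicted & known)
    fn = len(known - predicted)
    fp = len(predicted - known)
    tn = len(universe - predicted - known)
    return ContingencyTable(tp, fp, fn, tn)


def roc_from_thresholds(tables: Sequence[ContingencyTable]) -> RocCurve:
    """Assemble a ROC curve from per-threshold contingency tables.

    Tables with an undefined rate are skipped with a warning.  Points are
    sorted by FPR (ties by TPR) between the (0,0) and (1,1) anchors, and the
    AUC is the trapezoidal area.
    """
    if not tables:
        raise ValueError("at least one contingency table required")
    pts = []
    for t in tables:
        if t.tpr is None or t.fpr is None:
            logger.warning("skipping table with undefined rate: %s", t)
            continue
        pts.append((t.fpr, t.tpr))
    pts = sorted(set(pts) | {(0.0, 0.0), (1.0, 1.0)})
    fpr = np.array([p[0] for p in pts])
    tpr = np.array([p[1] for p in pts])
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(tuple(pts), auc)


def mann_whitney_auc(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> float:
    """AUC as the rank-sum pairwise probability P(pos > neg) + 0.5 P(tie)."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score classes must be non-empty")
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u) / (pos.size * neg.size)


def auc_significance(
    pos_scores: Sequence[float],
    neg_scores: Sequence[float],
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Rank-sum AUC with a one-sided permutation p-value for H0: AUC = 0.5.

    The p-value is the fraction of label permutations whose AUC reaches the
    observed one, with the +1 correction; reproducible under a fixed seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    auc = mann_whitney_auc(pos_scores, neg_scores)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    combined = np.concatenate([np.asarray(pos_scores, float), np.asarray(neg_scores, float)])
    n_pos = len(pos_scores)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(combined)
        if mann_whitney_auc(perm[:n_pos], perm[n_pos:]) >= auc - 1e-12:
            hits += 1
    p_value = (hits + 1) / (n_perm + 1)
    return auc, p_value


class CitationBenchmark(NamedTuple):
    tables: list[ContingencyTable]
    roc: RocCurve
    n_missing: int


def citation_benchmark(
    targets: Iterable[str],
    universe: Iterable[str],
    citations: Iterable[CitationRecord] | Mapping[str, int],
    thresholds: Sequence[int] = DEFAULT_CITATION_THRESHOLDS,
) -> CitationBenchmark:
    """Literature benchmark: one contingency table per citation threshold.

    At threshold t the positive class is {gene : citations >= t}; universe
    genes without a citation record count as 0 citations (reported in
    ``n_missing``).
    """
    thresholds = tuple(thresholds)
    if not thresholds or any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be non-empty and strictly increasing")
    universe = set(universe)
    targets = set(targets)
    if isinstance(citations, Mapping):
        counts = {str(g): int(n) for g, n in citations.items()}
    else:
        counts = {c.gene: c.n_phenotype_citations for c in citations}
    n_missing = len([g for g in universe if g not in counts])
    if n_missing:
        logger.warning("%d universe genes lack citation records (treated as 0)", n_missing)
    tables = []
    for t in thresholds:
        positive = {g for g in universe if counts.get(g, 0) >= t}
        tables.append(contingency_table(universe, targets, positive))
    return CitationBenchmark(tables, roc_from_thresholds(tables), n_missing)


class SpaceBenchmark(NamedTuple):
    tables: list[ContingencyTable]
    roc: RocCurve
    universe: frozenset[str]
    auc_rank: float
    p_value: float


def benchmark_search_spaces(
    spaces,
    predicted_targets: Iterable[str],
    known_targets: Iterable[str],
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> SpaceBenchmark:
    """Known-target benchmark over the six search spaces of one stratum.

    Each space restricts the predicted-target set to its own genes, yielding
    six nested thresholds ordered by the number of targets present.  The
    per-gene score for the rank-sum significance test is the number of
    spaces in which the gene is a predicted target (0-6).
    """
    from .gwas_loci import search_space_gene_universe

    predicted_targets = set(predicted_targets)
    known = set(known_targets)
    universe = search_space_gene_universe(spaces)
    spaces = sorted(
        spaces, key=lambda s: (len(predicted_targets & s.gene_universe), s.method)
    )
    tables = [
        contingency_table(universe, predicted_targets & s.gene_universe, known)
        for s in spaces
    ]
    roc = roc_from_thresholds(tables)
    score = {
        g: sum(1 for s in spaces if g in s.gene_universe and g in predicted_targets)
        for g in universe
    }
    known_in = sorted(known & universe)
    rest = sorted(universe - known)
    if known_in and rest:
        auc_rank, p_value = auc_significance(
            [score[g] for g in known_in], [score[g] for g in rest],
            n_perm=n_perm, seed=seed,
        )
    else:
        auc_rank, p_value = float("nan"), float("nan")
    return SpaceBenchmark(tables, roc, universe, auc_rank, p_value)


def read_citations(path) -> dict[str, int]:
    """Citations TSV: gene, n_citations."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return {str(g): int(n) for g, n in zip(df.iloc[:, 0], df.iloc[:, 1])}


def citations_from_links(gene_pmids: Iterable[tuple[str, str]], phenotype_pmids: Iterable[str]) -> dict[str, int]:
    """Two-file form: gene<->publication pairs joined against a phenotype
    publication-id list; a gene's count is the size of the intersection."""
    pheno = set(map(str, phenotype_pmids))
    seen: dict[str, set[str]] = {}
    for gene, pmid in gene_pmids:
        seen.setdefault(str(gene), set()).add(str(pmid))
    return {g: len(pmids & pheno) for g, pmids in seen.items()}


def tables_to_frame(tables: Sequence[ContingencyTable], labels: Sequence | None = None) -> pd.DataFrame:
    labels = list(labels) if labels is not None else list(range(1, len(tables) + 1))
    rows = [
        (lab, t.tp, t.fp, t.fn, t.tn, t.total, t.tpr, t.fpr)
        for lab, t in zip(labels, tables)
    ]
    return pd.DataFrame(rows, columns=["threshold", "tp", "fp", "fn", "tn", "total", "tpr", "fpr"])
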