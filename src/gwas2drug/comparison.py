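"""Set-level comparisons between prediction runs and external gene lists."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .drug_db import PooledDrugTargets


@dataclass(frozen=True)
class SetComparison:
    """Partition of two symbol sets into shared and exclusive members."""

    common: frozenset[str]
    only_a: frozenset[str]
    only_b: frozenset[str]

    @property
    def n_common(self) -> int:
        return len(self.common)

    @property
    def n_only_a(self) -> int:
        return len(self.only_a)

    @property
    def n_only_b(self) -> int:
        return len(self.only_b)

    @property
    def n_a(self) -> int:
        return self.n_common + self.n_only_a

    @property
    def n_b(self) -> int:
        return self.n_common + self.n_only_b

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [(g, "common") for g in sorted(self.common)]
            + [(g, "only_a") for g in sorted(self.only_a)]
            + [(g, "only_b") for g in sorted(self.only_b)]
        )
        return pd.DataFrame(rows, columns=["gene", "partition"])


def compare_sets(a: Iterable[str], b: Iterable[str]) -> SetComparison:
    a, b = set(a), set(b)
    return SetComparison(frozenset(a & b), frozenset(a - b), frozenset(b - a))


def external_list_overlap(
    gene_list: Iterable[str],
    pooled: PooledDrugTargets,
    predicted_targets: Iterable[str],
) -> tuple[frozenset[str], SetComparison]:
    """Map an external gene list (e.g. a consortium meta-analysis hit list)
    onto the pooled drug-target dataset, then compare its druggable subset
    with our predicted targets.

    Returns the mapped (druggable) genes and the comparison of that set
    (side A) against the predicted targets (side B); the retrieval fraction
    is ``n_common / len(mapped)``.
    """
    mapped = frozenset(set(gene_list) & pooled.unique_targets)
    return mapped, compare_sets(mapped, predicted_targets)


def retrieval_fraction(mapped: Iterable[str], predicted_targets: Iterable[str]) -> float:
    mapped = set(mapped)
    if not mapped:
        raise ZeroDivisionError("no mapped external targets")
    return len(mapped & set(predicted_targets)) / len(mapped)


def read_gene_list(path) -> frozenset[str]:
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())
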