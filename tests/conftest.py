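import numpy as np
import pytest

from gwas2drug import PipelineConfig, run_pipeline, synthetic
from gwas2drug.gwas_loci import GeneRecord, Locus, SearchSpace, SignificanceStratum, SnpAssociation


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default synthetic input bundle, shared across the session."""
    return synthetic.write_bundle(tmp_path_factory.mktemp("bundle"), seed=11)


@pytest.fixture(scope="session")
def pipeline_result(bundle):
    """One full pipeline run on the default bundle."""
    return run_pipeline(PipelineConfig.from_yaml(bundle.config_path))


@pytest.fixture
def rng():
    return np.random.default_rng(123)


def make_space(locus_genes: dict[str, list[str]], stratum="WS", method="fixed_100kb") -> SearchSpace:
    """Build a search space directly from locus -> gene-list mappings."""
    loci = {
        lid: Locus((lid,), "chr1", i * 1000, i * 1000 + 100, frozenset(genes))
        for i, (lid, genes) in enumerate(sorted(locus_genes.items()))
    }
    return SearchSpace(stratum, method, loci)


def make_stratum(positions_pvalues, label="WS", threshold=1e-3, chrom="chr1"):
    snps = frozenset(
        SnpAssociation(f"rs{i}", chrom, pos, p) for i, (pos, p) in enumerate(positions_pvalues)
    )
    return SignificanceStratum(label, threshold, snps)


def make_genes(intervals, chrom="chr1"):
    return [GeneRecord(sym, chrom, start, end) for sym, start, end in intervals]
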