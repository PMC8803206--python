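"""Shared fixtures: hand-written toy annotations and a small simulated study."""

import numpy as np
import pandas as pd
import pytest

from apmeth.gene_models import build_promoters, flag_internal_promoters, \
    parse_gene_models
from apmeth.simulate import SimulationDesign, simulate_dataset


def gtf_line(chrom, feature, start, end, strand, gene, tx):
    attrs = f'gene_id "{gene}"; transcript_id "{tx}";'
    return "\t".join(map(str, (chrom, "toy", feature, start, end, ".",
                               strand, ".", attrs)))


@pytest.fixture
def toy_gtf():
    """3 genes: two-promoter gene A (one shared first exon pair + one distinct),
    minus-strand gene B, single-exon gene C."""
    lines = [
        # gene A, promoter 1: t1 and t2 share overlapping first exons
        gtf_line("chr1", "exon", 101, 200, "+", "A", "A.t1"),
        gtf_line("chr1", "exon", 401, 500, "+", "A", "A.t1"),
        gtf_line("chr1", "exon", 121, 220, "+", "A", "A.t2"),
        gtf_line("chr1", "exon", 401, 500, "+", "A", "A.t2"),
        # gene A, promoter 2: disjoint downstream first exon
        gtf_line("chr1", "exon", 1001, 1100, "+", "A", "A.t3"),
        gtf_line("chr1", "exon", 1401, 1500, "+", "A", "A.t3"),
        # gene B on minus strand: first exon is the genomically last one
        gtf_line("chr1", "exon", 2101, 2200, "-", "B", "B.t1"),
        gtf_line("chr1", "exon", 2401, 2500, "-", "B", "B.t1"),
        # gene C: single-exon transcript
        gtf_line("chr2", "exon", 501, 700, "+", "C", "C.t1"),
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture
def toy_catalog(toy_gtf):
    return flag_internal_promoters(build_promoters(parse_gene_models(toy_gtf)))


@pytest.fixture(scope="session")
def small_dataset():
    """60-gene simulated study shared by the slower integration tests."""
    return simulate_dataset(SimulationDesign(n_genes=60, seed=11))


@pytest.fixture(scope="session")
def small_catalog(small_dataset):
    return flag_internal_promoters(
        build_promoters(parse_gene_models(small_dataset.gtf_text)))


@pytest.fixture
def paired_design():
    def make(n_pairs, prefix="S"):
        rows = []
        for i in range(1, n_pairs + 1):
            rows.append((f"{prefix}{i:02d}T", "tumor", f"P{i:02d}"))
            rows.append((f"{prefix}{i:02d}N", "normal", f"P{i:02d}"))
        return pd.DataFrame(rows, columns=["sample_id", "condition",
                                           "pair_id"])
    return make


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
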