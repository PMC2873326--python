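import numpy as np
import pandas as pd
import pytest

from domsil.models import GeneModel, GenomicInterval, L1Domain, ProbeMatrix, RepeatElement
from domsil.simulate import SimConfig, simulate_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """A small but complete synthetic bundle shared across tests."""
    cfg = SimConfig(seed=7, chrom_len=30_000_000)
    return simulate_bundle(cfg)


@pytest.fixture
def toy_domains():
    return [
        L1Domain("HL1", GenomicInterval("chr1", 0, 2_000_000)),
        L1Domain("LL1", GenomicInterval("chr1", 2_000_000, 6_000_000)),
        L1Domain("HL1", GenomicInterval("chr1", 6_000_000, 7_000_000)),
    ]


@pytest.fixture
def toy_matrix():
    values = pd.DataFrame(
        {
            "c1": [8.0, 5.0, 9.1],
            "c2": [8.2, 5.2, 9.0],
            "c3": [7.8, 4.9, 9.2],
            "t1": [7.0, 5.1, 9.1],
            "t2": [7.2, 4.8, 9.2],
            "t3": [6.8, 5.0, 9.0],
        },
        index=["pA", "pB", "pC"],
    )
    design = pd.Series(
        ["control"] * 3 + ["treated"] * 3, index=["c1", "c2", "c3", "t1", "t2", "t3"]
    )
    return ProbeMatrix(values, design)


def make_gene(gene_id, start, end, strand="+", chrom="chr1", exons=None, probes=()):
    iv = GenomicInterval(chrom, start, end, strand)
    return GeneModel(gene_id, iv, exons or [], list(probes))


def make_repeat(start, end, cls="L1", sub="L1Md_A", fl=False, chrom="chr1", strand="+"):
    return RepeatElement(GenomicInterval(chrom, start, end, strand), cls, sub, fl)
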