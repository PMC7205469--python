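import numpy as np
import pytest

from apa.annotation import GeneModel, PASite


@pytest.fixture
def plus_gene():
    """+ strand gene: last CDS exon [1000,1200), 3'UTR [1200,1500)."""
    return GeneModel(
        gene_id="gA",
        tx_id="gA.t1",
        chrom="chr1",
        strand="+",
        exons=((500, 700), (1000, 1500)),
        cds=(550, 1200),
        utr3=((1200, 1500),),
    )


@pytest.fixture
def minus_gene():
    """Reflection of plus_gene about pivot M=2000 (interval [a,b) -> [M-b,M-a))."""
    M = 2000
    return GeneModel(
        gene_id="gA",
        tx_id="gA.t1",
        chrom="chr1",
        strand="-",
        exons=((M - 1500, M - 1000), (M - 700, M - 500)),
        cds=(M - 1200, M - 550),
        utr3=((M - 1500, M - 1200),),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
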