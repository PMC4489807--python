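import numpy as np
import pytest

from dellaseq.io import Gene, GenomeAnnotation, Summit
from dellaseq.merging import BindingSite


def make_gene(gid, chrom, strand, start, *, length=1000, utr=100,
              exon1=(0, 450), intron=(450, 650)):
    """Fixed-architecture gene model (2 exons, 1 intron, UTRs at both ends)."""
    return Gene(
        id=gid, chrom=chrom, strand=strand,
        tx_start=start, tx_end=start + length,
        exons=[(start + exon1[0], start + exon1[1]),
               (start + intron[1], start + length)],
        cds_start=start + utr, cds_end=start + length - utr,
    )


def make_site(site_id, chrom, anchor, width=200):
    return BindingSite(
        chrom=chrom, mean_summit=anchor,
        start=anchor - width // 2, end=anchor + width // 2, site_id=site_id,
    )


@pytest.fixture
def single_plus_gene():
    """One + strand gene with TSS at 10000 on a 100 kb chromosome."""
    ann = GenomeAnnotation(chrom_lengths={"chr1": 100_000})
    ann.add(make_gene("GENE1", "chr1", "+", 10_000))
    return ann


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)


def summit(pos, rep, chrom="chr1"):
    return Summit(chrom, pos, rep)
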