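import numpy as np
import pysam
import pytest

from tescreen import GenomeContext
from tescreen.sim import make_header


@pytest.fixture
def ctx():
    """Small genome: one 1 Mb target chromosome, two TE consensus contigs."""
    return GenomeContext(
        {"chrX": 1_000_000, "mdg4": 7_000, "Doc": 4_500},
        te_contigs={"mdg4", "Doc"},
        target_contigs={"chrX"},
    )


@pytest.fixture
def header(ctx):
    return make_header(ctx)


def make_pair(
    header,
    name,
    chrom_a,
    pos_a,
    chrom_b,
    pos_b,
    read_len=50,
    proper=False,
    mapq=60,
    flag_extra_a=0,
    flag_extra_b=0,
    paired=True,
):
    """Fabricate one FR read pair as two alignment records."""
    tid = {sq: i for i, sq in enumerate(header.references)}
    base = (0x1 if paired else 0) | (0x2 if proper else 0)
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.flag = base | 0x20 | 0x40 | flag_extra_a if paired else flag_extra_a
    a.reference_id, a.reference_start = tid[chrom_a], pos_a
    a.mapping_quality = mapq
    a.cigartuples = [(0, read_len)]
    if paired:
        a.next_reference_id, a.next_reference_start = tid[chrom_b], pos_b
    b = pysam.AlignedSegment(header)
    b.query_name = name
    b.flag = base | 0x10 | 0x80 | flag_extra_b if paired else flag_extra_b
    b.reference_id, b.reference_start = tid[chrom_b], pos_b
    b.mapping_quality = mapq
    b.cigartuples = [(0, read_len)]
    if paired:
        b.next_reference_id, b.next_reference_start = tid[chrom_a], pos_a
    return [a, b]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
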