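import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

from redoxmir.config import PipelineConfig
from redoxmir.preprocess import AlignmentRecord, UniqueRead


@pytest.fixture
def config():
    return PipelineConfig()


def make_alignment(seq="A" * 21, chrom="chr1", start=100, strand="+",
                   counts=(1,), n_placements=1):
    """Convenience constructor for a single alignment record."""
    ur = UniqueRead(seq=seq, counts=list(counts))
    return AlignmentRecord(read=ur, chrom=chrom, start=start,
                           end=start + len(seq), strand=strand,
                           n_placements=n_placements)


def random_alignments(rng, n, genome_len=2000, chroms=("chr1",)):
    """Random alignment instances for clustering comparisons."""
    out = []
    for i in range(n):
        length = int(rng.integers(18, 27))
        start = int(rng.integers(0, genome_len - length))
        strand = "+" if rng.random() < 0.5 else "-"
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        seq = "".join(rng.choice(list("ACGT"), size=length))
        count = int(rng.integers(1, 200))
        out.append(make_alignment(seq=seq, chrom=chrom, start=start,
                                  strand=strand, counts=(count,)))
    return out
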