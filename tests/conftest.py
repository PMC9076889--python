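import numpy as np
import pytest

import forkhist as fh


@pytest.fixture(scope="session")
def toy_genome():
    """Two 1 Mb chromosomes, 8 origins, 40 genes — shared read-only fixture."""
    return fh.make_genome(2, 1_000_000, 8, 40, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_reads(genome, rng, n, assay="espan", read_length=100):
    """Uniform random stranded reads over the genome."""
    chroms = [c for c, _ in genome.chromosomes]
    lengths = genome.chrom_lengths
    reads = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, lengths[chrom] - read_length))
        strand = "W" if rng.random() < 0.5 else "C"
        reads.append(fh.StrandedRead(chrom, start, start + read_length, strand, assay))
    return reads
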