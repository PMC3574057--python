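import numpy as np
import pytest

from peakspec.intervals import GenomicInterval, Peak
from peakspec.simulate import SimConfig, generate


def random_peaks(rng, n, tf="TFX", cell="cellA", chroms=("chr1", "chr2"),
                 span=50_000, max_len=300):
    peaks = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        height = int(rng.integers(1, 100))
        peaks.append(
            Peak(GenomicInterval(chrom, start, start + length), height, tf, cell, f"p{i}")
        )
    return peaks


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study shared by integration-style tests."""
    return generate(SimConfig(seed=11, peaks_per_tf=250, chrom_length=1_500_000,
                              n_genes=80))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
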