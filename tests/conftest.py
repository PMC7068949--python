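import numpy as np
import pandas as pd
import pytest

from hicsig.core_data import GenomicBin, canonicalize
from hicsig.io_formats import FeatureTable
from hicsig import synth


def bin_at(chrom, start, size=1000):
    return GenomicBin(chrom, start, start + size)


@pytest.fixture
def small_bins():
    """10 bins of 1 kb on one chromosome."""
    return synth.make_bins({"chr1": 10_000}, 1000)


@pytest.fixture
def two_chrom_bins():
    return synth.make_bins({"chr1": 5000, "chr2": 3000}, 1000)


@pytest.fixture
def simple_map():
    """Three cis pairs plus one trans pair and one self pair."""
    b = bin_at
    return canonicalize(
        [
            (b("chr1", 0), b("chr1", 2000), 4),
            (b("chr1", 0), b("chr1", 5000), 2),
            (b("chr1", 2000), b("chr1", 5000), 1),
            (b("chr1", 0), b("chr2", 0), 3),
            (b("chr1", 3000), b("chr1", 3000), 5),
        ],
        resolution=1000,
    )


@pytest.fixture
def uniform_features(small_bins):
    df = small_bins.table
    return FeatureTable(
        pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["start"],
                "end": df["end"],
                "effective_length": 1.0,
                "gc": 0.5,
                "mappability": 1.0,
            }
        )
    )


def random_map(seed, n_chroms=2, n_bins=12, binsize=1000, n_reads=400):
    """A small random fixed-resolution map for round-trip style tests."""
    rng = np.random.default_rng(seed)
    lengths = {f"chr{i + 1}": n_bins * binsize for i in range(n_chroms)}
    bins = synth.make_bins(lengths, binsize)
    weights = rng.uniform(0.2, 1.5, len(bins))
    return synth.simulate_gothic_null(bins, weights, n_reads, seed + 1)
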