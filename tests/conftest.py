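import numpy as np
import pytest

from g4meth.core_tracks import GenomeInterval, PeakSet, SignalTrack


@pytest.fixture
def step_track() -> SignalTrack:
    """chr1: [0,100)=2, [100,150)=5, [200,300)=1; chr2: [10,20)=4."""
    return SignalTrack(
        {
            "chr1": (
                np.array([0, 100, 200]),
                np.array([100, 150, 300]),
                np.array([2.0, 5.0, 1.0]),
            ),
            "chr2": (np.array([10]), np.array([20]), np.array([4.0])),
        }
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_track(rng, chrom_len=1000, n_runs=30) -> SignalTrack:
    """Sorted disjoint runs with random gaps and values on one chromosome."""
    bounds = np.sort(rng.choice(chrom_len, size=2 * n_runs, replace=False))
    starts, ends = bounds[0::2], bounds[1::2]
    values = rng.gamma(2.0, 2.0, size=n_runs)
    return SignalTrack({"chr1": (starts, ends, values)})


def random_peaks(rng, n, chrom_len=500, chroms=("chr1", "chr2")) -> PeakSet:
    out = []
    for _ in range(n):
        chrom = str(rng.choice(chroms))
        start = int(rng.integers(0, chrom_len - 2))
        end = int(rng.integers(start + 1, min(start + 60, chrom_len)))
        out.append(GenomeInterval(chrom, start, end))
    return PeakSet(out)
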