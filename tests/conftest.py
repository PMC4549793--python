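import numpy as np
import pytest

from msikit import CohortSpec, generate_cohort
from msikit.repeats import GenomicInterval


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured synthetic cohort shared across tests."""
    spec = CohortSpec(
        n_msih=8, n_non=20, n_pole=2, capture_mb=2.0, seed=20260930
    )
    return generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_intervals(rng, n, chroms=("1", "2"), span=10_000, max_len=50):
    """Random valid half-open intervals for oracle-based tests."""
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(span))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def coverage_bitmap(intervals, chroms=("1", "2"), span=11_000):
    """Per-base boolean coverage, the oracle for merge/union semantics."""
    maps = {c: np.zeros(span, dtype=bool) for c in chroms}
    for iv in intervals:
        maps[iv.chrom][iv.start : iv.end] = True
    return maps
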