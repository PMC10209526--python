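from __future__ import annotations

import numpy as np
import pytest

from peakcompare.core import ChromSizes, GenomicInterval, PeakSet
from peakcompare.simulate import FixtureSpec, SamplePlan, simulate_peaksets


def make_set(label, triples, build="hg38", fmt="bed3", **kwargs) -> PeakSet:
    """Shorthand: PeakSet from (chrom, start, end) or interval tuples."""
    ivs = [t if isinstance(t, GenomicInterval) else GenomicInterval(*t)
           for t in triples]
    return PeakSet(label, ivs, genome_build=build, source_format=fmt, **kwargs)


def random_intervals(rng: np.random.Generator, n: int,
                     chroms=("chr1", "chr2"), length=100_000,
                     max_width=500) -> list[GenomicInterval]:
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, length - max_width))
        width = int(rng.integers(1, max_width))
        out.append(GenomicInterval(chrom, start, start + width))
    return out


@pytest.fixture(scope="session")
def chrom_sizes() -> ChromSizes:
    return ChromSizes({"chr1": 1_000_000, "chr2": 1_000_000})


@pytest.fixture(scope="session")
def small_spec() -> FixtureSpec:
    """Scaled-down corpus plan used where full defaults would be slow."""
    return FixtureSpec(
        seed=7,
        chroms={"chr1": 200_000, "chr2": 200_000},
        n_truth=60, truth_width=400,
        samples=[SamplePlan("rep1", n_peaks=120, shared_fraction=0.8),
                 SamplePlan("rep2", n_peaks=120, shared_fraction=0.8),
                 SamplePlan("other", n_peaks=120, shared_fraction=0.2)],
        blacklist_n=8, seg_tile=4000, n_genes=50,
    )


@pytest.fixture(scope="session")
def corpus(small_spec):
    samples, truth = simulate_peaksets(small_spec)
    return {"samples": samples, "truth": truth, "spec": small_spec}
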