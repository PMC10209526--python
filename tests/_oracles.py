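"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (all-pairs loops, per-base sets,
exhaustive enumeration) and shares no code with the library's engines.
"""

from __future__ import annotations

from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np

from peakcompare.core import GenomicInterval


def brute_overlap_flags(query: Sequence[GenomicInterval],
                        subject: Sequence[GenomicInterval],
                        min_bp: int = 1) -> list[bool]:
    """All-pairs overlap check, vectorised per query interval."""
    if not subject:
        return [False] * len(query)
    s_chrom = np.array([iv.chrom for iv in subject])
    s_start = np.array([iv.start for iv in subject])
    s_end = np.array([iv.end for iv in subject])
    flags = []
    for iv in query:
        shared = (np.minimum(s_end, iv.end)
                  - np.maximum(s_start, iv.start))
        flags.append(bool(np.any((s_chrom == iv.chrom) & (shared >= min_bp))))
    return flags


def covered_bases(intervals: Sequence[GenomicInterval]) -> set[tuple[str, int]]:
    """The exact set of (chrom, bp) positions covered."""
    bases: set[tuple[str, int]] = set()
    for iv in intervals:
        bases.update((iv.chrom, p) for p in range(iv.start, iv.end))
    return bases


def hypergeom_tail_enumeration(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by exhaustive enumeration of all C(N, n) draws.

    The universe is {0..N-1} with the "special" genes being {0..K-1}.
    Only feasible for N <= ~25.
    """
    hits = sum(1 for draw in combinations(range(N), n)
               if sum(1 for g in draw if g < K) >= k)
    return hits / comb(N, n)


def tss_profile_total_bruteforce(peaks, genes, window: int, bin_width: int) -> int:
    """Total binned count via a per-base (peak x TSS) double loop."""
    total = 0
    for g in genes.genes:
        t = g.tss
        for iv in peaks:
            if iv.chrom != g.chrom:
                continue
            touched_bins = set()
            for pos in range(iv.start, iv.end):
                rel = pos - t if g.strand == "+" else t - pos - 1
                # the implementation maps the body [s,e) to [s-T,e-T) on +
                # and to the mirrored interval [T-e, T-s) on -; per base,
                # position p on - contributes base T-p-1 of that interval
                if -window <= rel < window:
                    touched_bins.add((rel + window) // bin_width)
            total += len(touched_bins)
    return total
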