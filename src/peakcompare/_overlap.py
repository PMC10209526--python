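"""Shared interval-overlap engine (interval-tree backed).

Overlap means >= ``min_bp`` shared bases under half-open coordinates, so
bookended intervals ([100,200) vs [200,300)) do not overlap. Strand is
ignored: peak files are typically unstranded.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .core import GenomicInterval


def build_trees(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    """One IntervalTree per chromosome."""
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def overlap_flags(
    query: Sequence[GenomicInterval],
    trees: dict[str, IntervalTree],
    min_bp: int = 1,
) -> list[bool]:
    """Per-query flag: does it share >= min_bp bases with any tree interval."""
    flags = []
    for iv in query:
        tree = trees.get(iv.chrom)
        if tree is None:
            flags.append(False)
            continue
        hit = False
        for node in tree.overlap(iv.start, iv.end):
            if min(iv.end, node.end) - max(iv.start, node.begin) >= min_bp:
                hit = True
                break
        flags.append(hit)
    return flags
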