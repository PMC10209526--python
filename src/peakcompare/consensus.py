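"""Consensus peak calling across groups of peak files.

The strategy is deliberately simple and fast: merge the union of all
member peaks into disjoint intervals, count how many distinct members
intersect each merged interval (its *support*), and keep intervals whose
support reaches ``min_samples``. With the default ``min_samples=2`` the
result resembles ENCODE-style "replicated peaks". Support is counted per
merged interval, not per base: a sample contributing several overlapping
fragments to one region still counts once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from ._overlap import build_trees, overlap_flags
from .core import GenomicInterval, PeakSet, require_shared_build


def merge_intervals(
    intervals: Iterable[GenomicInterval],
    min_gap: int = 0,
) -> list[GenomicInterval]:
    """Unite intervals that overlap or lie within ``min_gap`` bp.

    With ``min_gap=0`` bookended intervals ([a,b) and [b,c)) merge but the
    union of covered bases is preserved. Output is disjoint and sorted.
    """
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
        if (merged and merged[-1].chrom == iv.chrom
                and iv.start - merged[-1].end <= min_gap):
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


@dataclass
class ConsensusInterval:
    interval: GenomicInterval
    support: int
    members: tuple[str, ...]


@dataclass
class ConsensusSet:
    """Merged consensus intervals, each with its supporting members."""

    label: str
    intervals: list[ConsensusInterval]
    min_samples: int
    group_size: int

    def __len__(self) -> int:
        return len(self.intervals)

    def to_peakset(self, genome_build=None) -> PeakSet:
        """BED6-shaped PeakSet: support in the score column, membership in
        the name."""
        return PeakSet(
            label=self.label,
            intervals=[
                GenomicInterval(ci.interval.chrom, ci.interval.start,
                                ci.interval.end, name=";".join(ci.members),
                                score=float(ci.support))
                for ci in self.intervals],
            genome_build=genome_build, source_format="bed6",
        )


def compute_consensus_peaks(
    group: Sequence[PeakSet],
    min_samples: int = 2,
    min_gap: int = 0,
    label: str = "consensus",
) -> ConsensusSet:
    """Call consensus peaks from a group of peak files.

    Merges the union of all member intervals (gap <= ``min_gap`` merges),
    annotates each merged interval with the distinct members intersecting
    it, and retains those supported by >= ``min_samples`` members.
    """
    if not group:
        raise ValueError("consensus requires a non-empty group")
    if not 1 <= min_samples <= len(group):
        raise ValueError(
            f"min_samples must be in [1, {len(group)}], got {min_samples}")
    require_shared_build(group)
    merged = merge_intervals((iv for ps in group for iv in ps), min_gap=min_gap)
    trees = {ps.label: build_trees(ps) for ps in group}
    kept: list[ConsensusInterval] = []
    for region in merged:
        members = tuple(
            ps.label for ps in group
            if overlap_flags([region], trees[ps.label])[0])
        if len(members) >= min_samples:
            kept.append(ConsensusInterval(region, len(members), members))
    return ConsensusSet(label, kept, min_samples, len(group))
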