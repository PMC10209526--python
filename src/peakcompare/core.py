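"""Core in-memory containers for genomic peak data.

Coordinates are BED-convention throughout: 0-based, half-open ``[start, end)``.
A peak is a :class:`GenomicInterval`; a named, genome-build-tagged, sorted
collection of peaks is a :class:`PeakSet`; chromosome lengths live in a
:class:`ChromSizes` mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pandas as pd

#: Genome builds the pipeline knows about. "GRCh38" is normalised to "hg38".
KNOWN_BUILDS = ("hg19", "hg38", "mm9", "mm10")

#: BED-family dialects the readers understand.
KNOWN_FORMATS = ("bed3", "bed6", "narrowPeak", "broadPeak", "seacr", "homer")

STRANDS = ("+", "-", ".")


def normalize_build(build: Optional[str]) -> Optional[str]:
    """Map synonymous build names onto the canonical spelling."""
    if build is None:
        return None
    if build == "GRCh38":
        return "hg38"
    if build == "GRCh37":
        return "hg19"
    return build


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """One peak or region: chrom, 0-based half-open [start, end) plus
    optional BED6 / ENCODE narrowPeak metadata.

    ``p_value`` and ``q_value`` are on the -log10 scale as in narrowPeak
    columns 8-9; ``summit_offset`` is narrowPeak column 10 (-1 when absent).
    The MACS convention of "-1" meaning "not computed" in the p/q columns is
    handled at parse time (stored as None), not here.
    """

    chrom: str
    start: int
    end: int
    name: Optional[str] = field(default=None, compare=False)
    score: Optional[float] = field(default=None, compare=False)
    strand: str = field(default=".", compare=False)
    signal_value: Optional[float] = field(default=None, compare=False)
    p_value: Optional[float] = field(default=None, compare=False)
    q_value: Optional[float] = field(default=None, compare=False)
    summit_offset: Optional[int] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.summit_offset is not None and self.summit_offset != -1:
            if not (0 <= self.summit_offset < self.end - self.start):
                raise ValueError(
                    f"summit offset {self.summit_offset} outside peak body "
                    f"of width {self.end - self.start}"
                )

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", min_bp: int = 1) -> bool:
        """True iff the two intervals share >= ``min_bp`` bases."""
        if self.chrom != other.chrom:
            return False
        return min(self.end, other.end) - max(self.start, other.start) >= min_bp

    def shifted(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)


class PeakSet:
    """A labelled, sorted collection of :class:`GenomicInterval`.

    Parameters
    ----------
    label
        Sample name used in every downstream table and figure.
    intervals
        Any iterable of intervals; stored sorted by (chrom, start, end).
    genome_build
        One of hg19/hg38/mm9/mm10 (GRCh38 accepted as synonym) or None
        when not yet declared. Cross-file comparisons require it to be set
        and equal on both sides.
    source_format
        The BED dialect the set was read from (or will be written as).
    strength_column
        Field name used for strength thresholding, or None. Usually filled
        by :func:`peakcompare.io.infer_strength_column`.
    """

    __slots__ = ("label", "intervals", "genome_build", "source_format",
                 "strength_column")

    def __init__(
        self,
        label: str,
        intervals: Iterable[GenomicInterval] = (),
        genome_build: Optional[str] = None,
        source_format: str = "bed3",
        strength_column: Optional[str] = None,
    ) -> None:
        build = normalize_build(genome_build)
        if build is not None and build not in KNOWN_BUILDS:
            raise ValueError(f"unknown genome build {genome_build!r}")
        if source_format not in KNOWN_FORMATS:
            raise ValueError(f"unknown source format {source_format!r}")
        self.label = label
        self.intervals: tuple[GenomicInterval, ...] = tuple(
            sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        )
        self.genome_build = build
        self.source_format = source_format
        self.strength_column = strength_column

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __repr__(self) -> str:
        return (f"PeakSet({self.label!r}, n={len(self)}, "
                f"build={self.genome_build}, format={self.source_format})")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return (self.label == other.label
                and self.intervals == other.intervals
                and self.genome_build == other.genome_build
                and self.source_format == other.source_format)

    def with_intervals(self, intervals: Iterable[GenomicInterval],
                       **overrides) -> "PeakSet":
        """Copy of this set with new intervals (metadata preserved)."""
        kw = dict(label=self.label, genome_build=self.genome_build,
                  source_format=self.source_format,
                  strength_column=self.strength_column)
        kw.update(overrides)
        return PeakSet(intervals=intervals, **kw)

    def chroms(self) -> tuple[str, ...]:
        return tuple(sorted({iv.chrom for iv in self.intervals}))

    def strengths(self) -> list[Optional[float]]:
        """Values of the declared strength column, aligned with intervals."""
        col = self.strength_column
        if col is None:
            return [None] * len(self)
        return [getattr(iv, col) for iv in self.intervals]

    def to_dataframe(self) -> pd.DataFrame:
        """Ten-column DataFrame mirroring narrowPeak field order."""
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "name": [iv.name for iv in self.intervals],
                "score": [iv.score for iv in self.intervals],
                "strand": [iv.strand for iv in self.intervals],
                "signal_value": [iv.signal_value for iv in self.intervals],
                "p_value": [iv.p_value for iv in self.intervals],
                "q_value": [iv.q_value for iv in self.intervals],
                "summit_offset": [iv.summit_offset for iv in self.intervals],
            }
        )


class ChromSizes(dict):
    """Mapping chromosome name -> length in bp. Lengths must be positive."""

    def __init__(self, sizes: Mapping[str, int] | Iterable[tuple[str, int]] = ()):
        super().__init__()
        items = sizes.items() if isinstance(sizes, Mapping) else sizes
        for name, length in items:
            self[name] = length

    def __setitem__(self, name: str, length: int) -> None:
        length = int(length)
        if length <= 0:
            raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        super().__setitem__(name, length)


def require_same_build(a: PeakSet, b: PeakSet) -> None:
    """Raise if two sets are not declared on the same genome build."""
    if a.genome_build != b.genome_build:
        raise ValueError(
            f"genome build mismatch: {a.label!r} is {a.genome_build}, "
            f"{b.label!r} is {b.genome_build}"
        )


def require_shared_build(peaksets: Sequence[PeakSet]) -> None:
    builds = {ps.genome_build for ps in peaksets}
    if len(builds) > 1:
        raise ValueError(f"peak sets span multiple genome builds: {sorted(map(str, builds))}")
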