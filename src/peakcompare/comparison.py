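"""Peak-overlap analytics between samples and against a reference.

All overlap is strand-blind and means >= 1 shared bp under half-open
coordinates (configurable via ``min_overlap_bp`` where exposed). The
percent-overlap matrix is intentionally asymmetric: entry (i, j) uses
sample i's peaks as the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._overlap import build_trees, overlap_flags
from .core import GenomicInterval, PeakSet, require_same_build, require_shared_build
from .io import infer_strength_column


def overlap_any(query: PeakSet, subject: PeakSet, min_overlap_bp: int = 1) -> list[bool]:
    """Per-query-peak flag: does it intersect any subject peak by
    >= ``min_overlap_bp`` bases. Both sets must share a genome build."""
    require_same_build(query, subject)
    trees = build_trees(subject)
    return overlap_flags(query.intervals, trees, min_bp=min_overlap_bp)


@dataclass
class OverlapMatrix:
    """Percent of row-sample peaks overlapping >= 1 column-sample peak."""

    labels: list[str]
    values: pd.DataFrame  # square, rows/cols = labels, NaN for empty rows

    def to_frame(self) -> pd.DataFrame:
        return self.values.copy()


def overlap_matrix(peaksets: Sequence[PeakSet], min_overlap_bp: int = 1) -> OverlapMatrix:
    """Pairwise percent-overlap matrix across >= 2 peak sets.

    Entry (i, j) = 100 * (#peaks of i overlapping j) / |i|; recorded as
    NaN when sample i is empty.
    """
    if len(peaksets) < 2:
        raise ValueError("overlap_matrix needs at least two peak sets")
    require_shared_build(peaksets)
    labels = [ps.label for ps in peaksets]
    trees = {ps.label: build_trees(ps) for ps in peaksets}
    mat = np.full((len(peaksets), len(peaksets)), np.nan)
    for i, qi in enumerate(peaksets):
        if len(qi) == 0:
            continue
        for j, sj in enumerate(peaksets):
            flags = overlap_flags(qi.intervals, trees[sj.label], min_bp=min_overlap_bp)
            mat[i, j] = 100.0 * sum(flags) / len(qi)
    return OverlapMatrix(labels, pd.DataFrame(mat, index=labels, columns=labels))


@dataclass
class UpsetCounts:
    """Counts of merged union regions per exact sample-membership subset."""

    counts: dict[frozenset, int]
    n_regions: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"membership": "&".join(sorted(subset)), "count": n}
            for subset, n in sorted(self.counts.items(),
                                    key=lambda kv: (-kv[1], sorted(kv[0])))
        ]
        return pd.DataFrame(rows, columns=["membership", "count"])


def _merged_union(peaksets: Sequence[PeakSet]) -> list[GenomicInterval]:
    """Disjoint regions from merging all intervals that overlap by >= 1 bp
    (bookended intervals stay separate)."""
    everything = sorted(
        (iv for ps in peaksets for iv in ps),
        key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in everything:
        if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def upset_counts(peaksets: Sequence[PeakSet], min_overlap_bp: int = 1) -> UpsetCounts:
    """Upset-style combination counts over merged union regions.

    The union of all peaks is merged into disjoint regions; each region's
    membership is the set of samples with >= 1 peak intersecting it, so a
    region counts once no matter how many fragments a sample contributes.
    """
    if len(peaksets) < 2:
        raise ValueError("upset_counts needs at least two peak sets")
    require_shared_build(peaksets)
    regions = _merged_union(peaksets)
    trees = {ps.label: build_trees(ps) for ps in peaksets}
    counts: dict[frozenset, int] = {}
    for region in regions:
        members = frozenset(
            ps.label for ps in peaksets
            if overlap_flags([region], trees[ps.label], min_bp=min_overlap_bp)[0])
        counts[members] = counts.get(members, 0) + 1
    return UpsetCounts(counts, n_regions=len(regions))


@dataclass
class StatSplit:
    """-log10 q-values of sample peaks split by overlap with the reference."""

    overlapping_q: list[float]
    nonoverlapping_q: list[float]
    summaries: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        rows = []
        for group, values in (("overlapping", self.overlapping_q),
                              ("non-overlapping", self.nonoverlapping_q)):
            arr = np.asarray(values, dtype=float)
            if arr.size:
                q1, med, q3 = np.percentile(arr, [25, 50, 75])
            else:
                q1 = med = q3 = np.nan
            rows.append({"group": group, "n": arr.size, "median": med,
                         "q1": q1, "q3": q3, "iqr": q3 - q1})
        self.summaries = pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        return self.summaries.copy()


def stat_split(sample: PeakSet, reference: PeakSet) -> StatSplit:
    """Partition the q-values of sample peaks by reference overlap.

    Peaks without a q-value are excluded. Raises if no peak carries one
    (the significance comparison should then be skipped).
    """
    flags = overlap_any(sample, reference)
    over, nonover = [], []
    n_with_q = 0
    for iv, hit in zip(sample.intervals, flags):
        if iv.q_value is None:
            continue
        n_with_q += 1
        (over if hit else nonover).append(iv.q_value)
    if n_with_q == 0:
        raise ValueError(
            f"{sample.label!r} has no q-values; skip the significance plot")
    return StatSplit(over, nonover)


@dataclass
class PRCurve:
    """Precision/recall/F1 at each strength threshold, thresholds ascending."""

    thresholds: list[float]
    precision: list[float]  # NaN where no peaks retained
    recall: list[float]
    f1: list[float]
    strength_column: Optional[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds, "precision": self.precision,
            "recall": self.recall, "f1": self.f1})


def precision_recall(
    sample: PeakSet,
    reference: PeakSet,
    n_thresholds: int = 11,
    min_overlap_bp: int = 1,
) -> PRCurve:
    """Precision-recall curve across peak-strength thresholds.

    Thresholds are the ``n_thresholds`` equally spaced quantiles of the
    sample's own strength values (making curves comparable across score
    scales). At cutoff t, sample peaks with strength >= t are retained
    (peaks lacking a strength value are always retained);
    precision(t) = fraction of retained peaks overlapping the reference,
    recall(t) = fraction of reference peaks overlapped by a retained peak.
    Without a usable strength column the curve degrades to a single
    keep-all threshold.
    """
    if len(reference) == 0:
        raise ValueError("reference peak set is empty")
    require_same_build(sample, reference)
    column = sample.strength_column or infer_strength_column(sample)
    strengths = ([getattr(iv, column) for iv in sample] if column
                 else [None] * len(sample))
    observed = np.array([s for s in strengths if s is not None], dtype=float)
    if column is None or observed.size == 0:
        thresholds = [0.0]
        column = None
    else:
        qs = np.linspace(0.0, 1.0, n_thresholds)
        thresholds = sorted(set(float(t) for t in np.quantile(observed, qs)))

    ref_trees = build_trees(reference)
    sample_hit = overlap_flags(sample.intervals, ref_trees, min_bp=min_overlap_bp)

    precisions, recalls, f1s = [], [], []
    for t in thresholds:
        retained_idx = [i for i, s in enumerate(strengths)
                        if s is None or s >= t]
        if retained_idx:
            retained = [sample.intervals[i] for i in retained_idx]
            prec = sum(sample_hit[i] for i in retained_idx) / len(retained_idx)
            ret_trees = build_trees(retained)
            ref_hit = overlap_flags(reference.intervals, ret_trees,
                                    min_bp=min_overlap_bp)
            rec = sum(ref_hit) / len(reference)
        else:
            prec = float("nan")
            rec = 0.0
        if np.isnan(prec):
            f1 = float("nan")
        elif prec + rec == 0:
            f1 = 0.0
        else:
            f1 = 2 * prec * rec / (prec + rec)
        precisions.append(prec)
        recalls.append(rec)
        f1s.append(f1)
    return PRCurve(list(thresholds), precisions, recalls, f1s, column)
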