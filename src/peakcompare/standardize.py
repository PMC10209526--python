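"""Quality control and standardization of peak files.

Three checks are applied to every input before any comparison:

1. **Genome-build harmonization** — files declared on a different build
   than the target are lifted over through a UCSC chain (see
   :mod:`peakcompare.chain`).
2. **Blacklist removal** — peaks sharing >= 1 bp with a blacklisted region
   (artifact-prone, anomalous-signal loci) are dropped.
3. **Chromosome tidying** — peaks on non-standard contigs (anything other
   than autosomes + X/Y) and, by default, the mitochondrial chromosome are
   dropped.

The pipeline order is liftover -> blacklist -> tidy: the blacklist is
declared in its own build and must be on the target build before
cross-build filtering makes sense. Per-file QC metrics (peak counts,
percent blacklisted / non-standard, width distribution, optional Picard
duplication rate) are collected along the way.
"""

from __future__ import annotations

import dataclasses
import os
import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._overlap import build_trees, overlap_flags
from .chain import ChainMap
from .core import ChromSizes, GenomicInterval, PeakSet, normalize_build, require_same_build

_STANDARD_RE = re.compile(r"^(chr)?(\d+|X|Y)$")
_MITO_RE = re.compile(r"^(chr)?(M|MT)$")


@dataclass
class QCMetrics:
    """Per-file General Metrics summary."""

    label: str
    n_peaks_raw: int
    n_peaks_final: int
    pct_blacklisted: float
    pct_nonstandard_chrom: float
    width_summary: dict[str, float]
    duplication_rate: Optional[float] = None
    n_unmapped: int = 0

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def remove_blacklist(peaks: PeakSet, blacklist: PeakSet) -> tuple[PeakSet, int]:
    """Drop every peak sharing >= 1 bp with a blacklisted region.

    Both sets must be declared on the same genome build. Returns the
    filtered set and the number of peaks removed.
    """
    require_same_build(peaks, blacklist)
    trees = build_trees(blacklist)
    flags = overlap_flags(peaks.intervals, trees)
    kept = [iv for iv, hit in zip(peaks.intervals, flags) if not hit]
    return peaks.with_intervals(kept), len(peaks) - len(kept)


def is_standard_chrom(name: str) -> bool:
    return _STANDARD_RE.match(name) is not None


def is_mito_chrom(name: str) -> bool:
    return _MITO_RE.match(name) is not None


def tidy_chromosomes(
    peaks: PeakSet,
    chrom_sizes: Optional[ChromSizes] = None,
    keep_mito: bool = False,
) -> tuple[PeakSet, int]:
    """Retain peaks on standard chromosomes only.

    Standard means chr1..chrN / chrX / chrY (with or without the "chr"
    prefix) and, when ``chrom_sizes`` is given, present among its keys.
    chrM/MT is removed unless ``keep_mito``; underscore-bearing contigs,
    chrUn, chrEBV etc. are always removed.
    """
    kept = []
    for iv in peaks:
        if is_mito_chrom(iv.chrom):
            if not keep_mito:
                continue
        elif not is_standard_chrom(iv.chrom):
            continue
        elif chrom_sizes is not None and iv.chrom not in chrom_sizes:
            continue
        kept.append(iv)
    return peaks.with_intervals(kept), len(peaks) - len(kept)


def liftover(
    peaks: PeakSet,
    chain: ChainMap,
    min_fraction: float = 0.95,
) -> tuple[PeakSet, int]:
    """Translate peak coordinates to another genome build.

    Each peak is routed through the highest-scoring chain overlapping it
    and mapped block by block; the lifted peak spans the mapped bases on
    the destination chromosome. Peaks with no covering chain, or whose
    mapped bases cover less than ``min_fraction`` of their width, are
    dropped and counted as unmapped. Auxiliary fields are preserved (the
    summit offset is invalidated if it falls outside the lifted body).
    """
    if chain.source_build is not None and peaks.genome_build is not None:
        if peaks.genome_build != chain.source_build:
            raise ValueError(
                f"cannot lift {peaks.label!r}: declared build "
                f"{peaks.genome_build} but chain maps from {chain.source_build}"
            )
    lifted: list[GenomicInterval] = []
    unmapped = 0
    for iv in peaks:
        best = chain.best_chain(iv.chrom, iv.start, iv.end)
        if best is None:
            unmapped += 1
            continue
        spans = best.map_span(iv.start, iv.end)
        mapped_bases = sum(e - s for s, e in spans)
        if not spans or mapped_bases / iv.width < min_fraction:
            unmapped += 1
            continue
        new_start = min(s for s, _ in spans)
        new_end = max(e for _, e in spans)
        summit = iv.summit_offset
        if summit is not None and not (summit == -1 or summit < new_end - new_start):
            summit = -1
        lifted.append(dataclasses.replace(
            iv, chrom=best.q_name, start=new_start, end=new_end,
            summit_offset=summit))
    out = PeakSet(
        label=peaks.label, intervals=lifted,
        genome_build=chain.target_build, source_format=peaks.source_format,
        strength_column=peaks.strength_column)
    return out, unmapped


def _width_summary(intervals: Sequence[GenomicInterval]) -> dict[str, float]:
    if not intervals:
        return {k: float("nan") for k in ("min", "q1", "median", "q3", "max")}
    widths = np.array([iv.width for iv in intervals], dtype=float)
    q = np.percentile(widths, [0, 25, 50, 75, 100])
    return dict(zip(("min", "q1", "median", "q3", "max"), map(float, q)))


def _resolve_build(builds, role: str, default: Optional[str]) -> Optional[str]:
    if builds is None:
        return default
    if isinstance(builds, str):
        return normalize_build(builds)
    return normalize_build(builds.get(role, builds.get("peakfiles", default)))


def _find_chain(chains: Sequence[ChainMap], source: str, target: str) -> ChainMap:
    for chain in chains or ():
        if chain.source_build == source and chain.target_build == target:
            return chain
    raise ValueError(f"no chain file available for liftover {source} -> {target}")


def standardize_all(
    peaksets: Sequence[PeakSet],
    blacklist: PeakSet,
    builds=None,
    target_build: Optional[str] = None,
    chains: Sequence[ChainMap] = (),
    chrom_sizes: Optional[ChromSizes] = None,
    keep_mito: bool = False,
    liftover_min_fraction: float = 0.95,
    duplication_rates: Optional[dict[str, float]] = None,
) -> tuple[list[PeakSet], list[QCMetrics]]:
    """Run the full QC/standardization pipeline over a list of peak files.

    ``builds`` is either a single build name for everything or a mapping
    of roles/labels to builds (keys: sample labels, plus ``"blacklist"``
    and the catch-all ``"peakfiles"``). Every file whose build differs
    from ``target_build`` is lifted first (the blacklist too), then
    blacklist-filtered, then chromosome-tidied. Percentages in the QC
    metrics are measured on the pre-filter (post-liftover) set.
    """
    target_build = normalize_build(target_build)
    if target_build is None:
        declared = _resolve_build(builds, "peakfiles", blacklist.genome_build)
        target_build = declared or blacklist.genome_build

    bl_build = _resolve_build(builds, "blacklist", blacklist.genome_build)
    bl = blacklist
    if bl.genome_build is None:
        bl = bl.with_intervals(bl.intervals, genome_build=bl_build or target_build)
    if target_build is not None and bl.genome_build != target_build:
        bl, _ = liftover(bl, _find_chain(chains, bl.genome_build, target_build),
                         liftover_min_fraction)

    out_sets: list[PeakSet] = []
    out_metrics: list[QCMetrics] = []
    for ps in peaksets:
        n_raw = len(ps)
        build = ps.genome_build or _resolve_build(builds, ps.label, target_build)
        work = ps if ps.genome_build is not None else ps.with_intervals(
            ps.intervals, genome_build=build)
        unmapped = 0
        if target_build is not None and work.genome_build != target_build:
            work, unmapped = liftover(
                work, _find_chain(chains, work.genome_build, target_build),
                liftover_min_fraction)
        n_pre = len(work)
        filtered, n_black = remove_blacklist(work, bl)
        tidied, _ = tidy_chromosomes(filtered, chrom_sizes, keep_mito=keep_mito)
        # percent non-standard is measured on the pre-filter set
        _, n_nonstd = tidy_chromosomes(work, chrom_sizes, keep_mito=keep_mito)
        out_sets.append(tidied)
        dup = (duplication_rates or {}).get(ps.label)
        out_metrics.append(QCMetrics(
            label=ps.label,
            n_peaks_raw=n_raw,
            n_peaks_final=len(tidied),
            pct_blacklisted=100.0 * n_black / n_pre if n_pre else 0.0,
            pct_nonstandard_chrom=100.0 * n_nonstd / n_pre if n_pre else 0.0,
            width_summary=_width_summary(tidied.intervals),
            duplication_rate=dup,
            n_unmapped=unmapped,
        ))
    return out_sets, out_metrics


def parse_picard_metrics(path: os.PathLike | str) -> float:
    """Extract PERCENT_DUPLICATION from a Picard MarkDuplicates metrics file.

    Returns the value of the first metrics row as a fraction in [0, 1].
    Raises :class:`ValueError` if the metrics table or the column is absent.
    """
    header: Optional[list[str]] = None
    with open(path) as handle:
        lines = iter(handle)
        for raw in lines:
            line = raw.rstrip("\n")
            if line.startswith("## METRICS CLASS"):
                header = next(lines).rstrip("\n").split("\t")
                break
        if header is None:
            raise ValueError(f"{path}: no '## METRICS CLASS' section found")
        if "PERCENT_DUPLICATION" not in header:
            raise ValueError(f"{path}: metrics header lacks PERCENT_DUPLICATION")
        col = header.index("PERCENT_DUPLICATION")
        for raw in lines:
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                break
            fields = line.split("\t")
            value = float(fields[col])
            if not 0.0 <= value <= 1.0:
                raise ValueError(
                    f"{path}: PERCENT_DUPLICATION {value} outside [0, 1]")
            return value
    raise ValueError(f"{path}: metrics section has no data row")
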