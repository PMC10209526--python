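"""Functional annotation of peaks.

Four analyses relate peaks to genomic context:

* **Chromatin-state annotation** against a ChromHMM-style segmentation
  BED (state label in the name column): the fraction of peak bases
  falling in each state, base-pair weighted so partial overlaps count
  proportionally.
* **Genomic-feature annotation** against a gene model, labelling each
  peak by a fixed precedence: Promoter > Exon > Intron > Downstream >
  Distal Intergenic.
* **TSS profile**: strand-oriented peak frequency in bins around
  transcription start sites (default +/- 3000 bp, 100 bp bins).
* **Gene-set enrichment** of the genes whose promoters the peaks hit,
  via the one-sided hypergeometric test with Benjamini-Hochberg
  correction, against user-supplied GMT files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .core import GenomicInterval, PeakSet


# ---------------------------------------------------------------------------
# chromatin-state segmentation

@dataclass
class StateSegmentation:
    """Non-overlapping labelled intervals partitioning (part of) a genome."""

    intervals: list[tuple[GenomicInterval, str]]  # (interval, state label)
    states: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        self.states = tuple(sorted({state for _, state in self.intervals}))
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv, _ in self.intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for ivs in by_chrom.values():
            ivs.sort(key=lambda x: (x.start, x.end))
            for a, b in zip(ivs, ivs[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"segmentation intervals overlap on {a.chrom}: "
                        f"{a.start}-{a.end} vs {b.start}-{b.end}")


def read_segmentation(path: os.PathLike | str) -> StateSegmentation:
    """Read a ChromHMM segmentation BED (chrom, start, end, state)."""
    records = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"segmentation line {lineno}: need 4 columns")
            records.append((GenomicInterval(fields[0], int(fields[1]),
                                            int(fields[2])), fields[3]))
    if not records:
        raise ValueError(f"{path}: empty segmentation")
    return StateSegmentation(records)


@dataclass
class StateAnnotation:
    """Base-pair-weighted state composition of one peak set."""

    fractions: pd.Series        # per state, over annotated bases; sums to 1
    annotated_bases: int
    unannotated_bases: int      # peak bases outside the segmentation
    unannotated_peaks: int      # peaks with zero segmentation overlap

    def to_frame(self) -> pd.DataFrame:
        out = self.fractions.rename("fraction").to_frame()
        out.index.name = "state"
        return out.reset_index()


def chromhmm_annotate(peaks: PeakSet, seg: StateSegmentation) -> StateAnnotation:
    """Fraction of peak bases in each chromatin state.

    Fractions are over the peak bases that overlap *any* state, so they
    sum to 1 whenever overlap exists; bases and whole peaks outside the
    segmentation are reported separately rather than silently dropped.
    """
    if not seg.intervals:
        raise ValueError("empty segmentation")
    trees: dict[str, IntervalTree] = {}
    for iv, state in seg.intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, state)

    bases_per_state = {state: 0 for state in seg.states}
    annotated = unannotated_bases = unannotated_peaks = 0
    for peak in peaks:
        tree = trees.get(peak.chrom)
        covered = 0
        if tree is not None:
            for node in tree.overlap(peak.start, peak.end):
                ov = min(peak.end, node.end) - max(peak.start, node.begin)
                if ov > 0:
                    bases_per_state[node.data] += ov
                    covered += ov
        annotated += covered
        unannotated_bases += peak.width - covered
        if covered == 0:
            unannotated_peaks += 1

    fractions = pd.Series(
        {state: (bases_per_state[state] / annotated if annotated else 0.0)
         for state in seg.states}, dtype=float)
    return StateAnnotation(fractions, annotated, unannotated_bases,
                           unannotated_peaks)


# ---------------------------------------------------------------------------
# gene model

@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = ()

    @property
    def tss(self) -> int:
        """Transcription start: span start on +, span end - 1 on -."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class GeneModel:
    genes: list[Gene]

    def __len__(self) -> int:
        return len(self.genes)

    def gene_ids(self) -> set[str]:
        return {g.gene_id for g in self.genes}


def read_gene_bed(path: os.PathLike | str) -> GeneModel:
    """Read a gene model from BED6 (one gene per line, no exon structure)
    or BED12 (exons reconstructed from the block columns)."""
    genes: list[Gene] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"gene BED line {lineno}: need >= 6 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name, strand = fields[3], fields[5]
            if strand not in ("+", "-"):
                raise ValueError(f"gene BED line {lineno}: strand must be + or -")
            exons: tuple[tuple[int, int], ...] = ()
            if len(fields) >= 12:
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
                exons = tuple((start + off, start + off + size)
                              for off, size in zip(starts, sizes))
            genes.append(Gene(name, chrom, strand, start, end, exons))
    return GeneModel(genes)


def promoter_window(gene: Gene, upstream: int = 2000,
                    downstream: int = 500) -> tuple[int, int]:
    """Genomic span of the promoter: upstream bp before the TSS through
    downstream bp after it, oriented by strand."""
    if gene.strand == "+":
        return max(0, gene.tss - upstream), gene.tss + downstream
    return max(0, gene.tss - downstream), gene.tss + upstream


# ---------------------------------------------------------------------------
# feature annotation

FEATURE_LABELS = ("Promoter", "Exon", "Intron", "Downstream", "Distal Intergenic")


@dataclass
class FeatureAnnotation:
    labels: list[str]           # one per peak, in peak order
    fractions: pd.Series        # per feature label

    def to_frame(self) -> pd.DataFrame:
        out = self.fractions.rename("fraction").to_frame()
        out.index.name = "feature"
        return out.reset_index()


def feature_annotate(
    peaks: PeakSet,
    genes: GeneModel,
    promoter: tuple[int, int] = (2000, 500),
    downstream_bp: int = 3000,
) -> FeatureAnnotation:
    """Label each peak by genomic feature with a fixed precedence.

    Promoter (peak intersects the strand-oriented promoter window) beats
    Exon beats Intron (inside a gene span but no exon) beats Downstream
    (within ``downstream_bp`` past the transcript end) beats Distal
    Intergenic. Every peak gets exactly one label.
    """
    up, down = promoter
    prom_tree: dict[str, IntervalTree] = {}
    exon_tree: dict[str, IntervalTree] = {}
    span_tree: dict[str, IntervalTree] = {}
    down_tree: dict[str, IntervalTree] = {}
    for g in genes.genes:
        ps, pe = promoter_window(g, up, down)
        if ps < pe:
            prom_tree.setdefault(g.chrom, IntervalTree()).addi(ps, pe)
        for es, ee in g.exons:
            exon_tree.setdefault(g.chrom, IntervalTree()).addi(es, ee)
        span_tree.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end)
        if g.strand == "+":
            ds, de = g.end, g.end + downstream_bp
        else:
            ds, de = max(0, g.start - downstream_bp), g.start
        if ds < de:
            down_tree.setdefault(g.chrom, IntervalTree()).addi(ds, de)

    def hits(trees: dict[str, IntervalTree], iv: GenomicInterval) -> bool:
        tree = trees.get(iv.chrom)
        return bool(tree is not None and tree.overlap(iv.start, iv.end))

    labels = []
    for iv in peaks:
        if hits(prom_tree, iv):
            labels.append("Promoter")
        elif hits(exon_tree, iv):
            labels.append("Exon")
        elif hits(span_tree, iv):
            labels.append("Intron")
        elif hits(down_tree, iv):
            labels.append("Downstream")
        else:
            labels.append("Distal Intergenic")
    n = len(labels)
    fractions = pd.Series(
        {lab: (labels.count(lab) / n if n else 0.0) for lab in FEATURE_LABELS},
        dtype=float)
    return FeatureAnnotation(labels, fractions)


# ---------------------------------------------------------------------------
# TSS profile

@dataclass
class TSSProfile:
    """Peak frequency in strand-oriented bins around all TSSs."""

    bin_starts: np.ndarray     # relative bp, ascending, length 2*window/bin
    counts: np.ndarray         # (peak, TSS) incidences per bin
    normalized: np.ndarray     # counts / number of TSSs
    window: int
    bin_width: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"rel_start": self.bin_starts,
                             "count": self.counts,
                             "per_tss": self.normalized})


def tss_profile(
    peaks: PeakSet,
    genes: GeneModel,
    window: int = 3000,
    bin_width: int = 100,
) -> TSSProfile:
    """Histogram of peak occupancy by distance from transcription starts.

    For each TSS, peak bodies are projected into TSS-relative coordinates
    (mirrored for minus-strand genes: a peak upstream of a minus-strand
    TSS lands at negative positions) and every bin the body covers within
    [-window, +window) is incremented, once per (peak, TSS) pair.
    """
    if (2 * window) % bin_width != 0:
        raise ValueError("bin width must divide the full window span")
    if len(genes) == 0:
        raise ValueError("gene model is empty")
    n_bins = 2 * window // bin_width
    counts = np.zeros(n_bins, dtype=np.int64)

    peak_tree: dict[str, IntervalTree] = {}
    for iv in peaks:
        peak_tree.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)

    for g in genes.genes:
        tree = peak_tree.get(g.chrom)
        if tree is None:
            continue
        t = g.tss
        for node in tree.overlap(t - window, t + window):
            if g.strand == "+":
                rel_lo, rel_hi = node.begin - t, node.end - t
            else:
                rel_lo, rel_hi = t - node.end, t - node.begin
            lo = max(rel_lo, -window)
            hi = min(rel_hi, window)
            if lo >= hi:
                continue
            first = (lo + window) // bin_width
            last = (hi - 1 + window) // bin_width
            counts[first:last + 1] += 1

    bin_starts = np.arange(-window, window, bin_width)
    return TSSProfile(bin_starts, counts, counts / len(genes), window, bin_width)


# ---------------------------------------------------------------------------
# peaks -> genes -> enrichment

def peaks_to_genes(
    peaks: PeakSet,
    genes: GeneModel,
    rule: str = "promoter_overlap",
    promoter: tuple[int, int] = (2000, 500),
) -> set[str]:
    """Bridge from peaks to a gene id set for enrichment testing.

    ``promoter_overlap``: genes whose promoter window intersects >= 1
    peak. ``nearest_tss``: for each peak, the closest TSS (ties keep all
    tied genes).
    """
    if rule == "promoter_overlap":
        up, down = promoter
        hit: set[str] = set()
        peak_tree: dict[str, IntervalTree] = {}
        for iv in peaks:
            peak_tree.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
        for g in genes.genes:
            tree = peak_tree.get(g.chrom)
            if tree is None:
                continue
            ps, pe = promoter_window(g, up, down)
            if ps < pe and tree.overlap(ps, pe):
                hit.add(g.gene_id)
        return hit
    if rule == "nearest_tss":
        out: set[str] = set()
        for iv in peaks:
            best = None
            best_genes: list[str] = []
            for g in genes.genes:
                if g.chrom != iv.chrom:
                    continue
                d = max(0, iv.start - g.tss, g.tss - (iv.end - 1))
                if best is None or d < best:
                    best, best_genes = d, [g.gene_id]
                elif d == best:
                    best_genes.append(g.gene_id)
            out.update(best_genes)
        return out
    raise ValueError(f"unknown peak-to-gene rule {rule!r}")


def read_gmt(path: os.PathLike | str) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name <TAB> description <TAB> genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: need name, description, genes")
            sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def enrichment_test(
    query_genes: set[str],
    gene_sets: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of a gene set collection.

    For each set, with universe size N, set size K (after intersecting
    with the universe), query size n and overlap k, the p-value is
    P(X >= k) for X ~ Hypergeom(N, K, n). Benjamini-Hochberg correction
    is applied across all tested sets; rows sorted by p.
    """
    if not universe:
        raise ValueError("empty gene universe")
    if not query_genes:
        raise ValueError("empty query gene set")
    if not query_genes <= universe:
        raise ValueError("query genes must be a subset of the universe")
    rows = []
    n = len(query_genes)
    N = len(universe)
    for name, members in gene_sets.items():
        in_universe = members & universe
        K = len(in_universe)
        k = len(in_universe & query_genes)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"set": name, "k": k, "K": K, "n": n, "N": N, "p_value": p})
    result = pd.DataFrame(rows)
    if len(result):
        result["q_value"] = multipletests(result["p_value"], method="fdr_bh")[1]
        result = result.sort_values("p_value", kind="stable").reset_index(drop=True)
    return result
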