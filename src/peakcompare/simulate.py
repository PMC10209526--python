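"""Deterministic synthetic-data generation for the whole pipeline.

The generator fabricates every input the comparison pipeline consumes —
peak files, a blacklist, chromosome sizes, a liftover chain, a chromatin
-state segmentation, a gene model, GMT gene sets and a Picard duplicate
-metrics file — on a toy genome (default: two 1 Mb chromosomes, large
enough for ~10^3 peaks without saturation yet small enough for
brute-force oracles).

Samples are built around a latent *truth* peak set: a fraction
(``shared_fraction``) of each sample's peaks are jittered copies of truth
intervals, the rest are background placed uniformly at random while
avoiding the truth set entirely. Jitter is bounded below half a peak
width, so every truth-derived peak still overlaps its truth interval and
a sample's keep-all precision against the truth is its shared fraction
(background contributes nothing by construction). Strengths are drawn so
truth-derived peaks stochastically exceed background, making
precision-recall curves informative.

All randomness flows from one seed; per-sample substreams are derived by
stable hashing of the sample label, so adding a sample never perturbs
the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .annotation import Gene, GeneModel, StateSegmentation, promoter_window
from .chain import ChainMap, shift_chain, write_chain
from .core import ChromSizes, GenomicInterval, PeakSet
from .io import write_peaks


@dataclass
class SamplePlan:
    """Recipe for one synthetic peak file."""

    label: str
    n_peaks: int = 500
    shared_fraction: float = 0.8    # fraction of peaks derived from truth
    width_mean: float = 300.0       # lognormal-ish peak widths, bp
    width_sd: float = 80.0
    jitter: int = 50                # max |start shift| of truth-derived peaks
    strength_mu_truth: float = 8.0  # -log10 q of truth-derived peaks
    strength_mu_bg: float = 3.0
    strength_sd: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must be in [0, 1]")
        if self.n_peaks < 0:
            raise ValueError("n_peaks must be >= 0")


def default_samples() -> list[SamplePlan]:
    return [
        SamplePlan("rep1", shared_fraction=0.8),
        SamplePlan("rep2", shared_fraction=0.8),
        SamplePlan("other", shared_fraction=0.2),
    ]


@dataclass
class FixtureSpec:
    """Full plan for one synthetic corpus."""

    seed: int = 0
    chroms: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000})
    genome_build: str = "hg38"
    n_truth: int = 300
    truth_width: int = 400
    samples: list[SamplePlan] = field(default_factory=default_samples)
    blacklist_n: int = 30
    blacklist_width: int = 2000
    seg_states: int = 6
    seg_tile: int = 5000
    n_genes: int = 200
    gene_span: int = 2000
    chain_shifts: dict[str, int] = field(
        default_factory=lambda: {"chr1": 100, "chr2": 100})
    chain_source_build: str = "hg19"
    gmt_n_random_sets: int = 5
    gmt_set_size: int = 25
    duplication_rate: float = 0.15


def _substream(seed: int, label: str) -> np.random.Generator:
    """Independent generator keyed by (seed, stable hash of label)."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed,
                               spawn_key=(zlib.crc32(label.encode()),)))


def _place_intervals(
    rng: np.random.Generator,
    chroms: dict[str, int],
    n: int,
    widths: np.ndarray,
    forbidden: Optional[Sequence[GenomicInterval]] = None,
    self_disjoint: bool = False,
    max_tries: int = 200,
) -> list[GenomicInterval]:
    """Uniform placement with rejection against forbidden intervals."""
    names = sorted(chroms)
    lengths = np.array([chroms[c] for c in names], dtype=float)
    probs = lengths / lengths.sum()
    by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in names}
    for iv in forbidden or ():
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    placed: list[GenomicInterval] = []
    for i in range(n):
        width = max(1, int(widths[i]))
        for attempt in range(max_tries):
            chrom = names[rng.choice(len(names), p=probs)]
            limit = chroms[chrom] - width
            if limit < 0:
                continue
            start = int(rng.integers(0, limit + 1))
            end = start + width
            if any(start < e and s < end for s, e in by_chrom[chrom]):
                continue
            placed.append(GenomicInterval(chrom, start, end))
            if self_disjoint:
                by_chrom[chrom].append((start, end))
            break
        else:
            raise ValueError(
                "could not place interval after "
                f"{max_tries} tries: genome too small for the plan")
    return placed


def simulate_truth(spec: FixtureSpec) -> PeakSet:
    """The latent truth set all samples are generated around."""
    rng = _substream(spec.seed, "__truth__")
    widths = np.full(spec.n_truth, spec.truth_width)
    intervals = _place_intervals(rng, spec.chroms, spec.n_truth, widths,
                                 self_disjoint=True)
    return PeakSet("truth", intervals, genome_build=spec.genome_build,
                   source_format="bed3")


def simulate_peaksets(spec: FixtureSpec) -> tuple[list[PeakSet], PeakSet]:
    """Generate every sample of the plan plus the latent truth set."""
    truth = simulate_truth(spec)
    truth_ivs = list(truth.intervals)
    samples: list[PeakSet] = []
    for plan in spec.samples:
        rng = _substream(spec.seed, plan.label)
        n_shared = int(round(plan.shared_fraction * plan.n_peaks))
        n_bg = plan.n_peaks - n_shared

        intervals: list[GenomicInterval] = []
        strengths: list[float] = []
        if n_shared:
            picks = rng.choice(len(truth_ivs), size=n_shared,
                               replace=n_shared > len(truth_ivs))
            for idx in picks:
                tv = truth_ivs[int(idx)]
                width = max(2 * plan.jitter + 1,
                            int(rng.normal(plan.width_mean, plan.width_sd)))
                jit = int(rng.integers(-plan.jitter, plan.jitter + 1))
                centre = (tv.start + tv.end) // 2 + jit
                start = max(0, centre - width // 2)
                end = min(spec.chroms[tv.chrom], start + width)
                intervals.append(GenomicInterval(tv.chrom, start, end))
                strengths.append(max(0.1, rng.normal(plan.strength_mu_truth,
                                                     plan.strength_sd)))
        if n_bg:
            widths = np.maximum(
                1, rng.normal(plan.width_mean, plan.width_sd, size=n_bg))
            bg = _place_intervals(rng, spec.chroms, n_bg, widths,
                                  forbidden=truth_ivs)
            intervals.extend(bg)
            strengths.extend(
                max(0.1, rng.normal(plan.strength_mu_bg, plan.strength_sd))
                for _ in range(n_bg))

        records = [
            GenomicInterval(
                iv.chrom, iv.start, iv.end,
                name=f"{plan.label}_peak{i}",
                score=float(min(1000, int(round(s * 100)))),
                strand=".",
                signal_value=round(float(s) * 1.7, 4),
                p_value=round(float(s) * 1.1, 4),
                q_value=round(float(s), 4),
                summit_offset=iv.width // 2)
            for i, (iv, s) in enumerate(zip(intervals, strengths))
        ]
        samples.append(PeakSet(plan.label, records,
                               genome_build=spec.genome_build,
                               source_format="narrowPeak",
                               strength_column="q_value"))
    return samples, truth


def simulate_blacklist(spec: FixtureSpec) -> PeakSet:
    rng = _substream(spec.seed, "__blacklist__")
    widths = np.full(spec.blacklist_n, spec.blacklist_width)
    intervals = _place_intervals(rng, spec.chroms, spec.blacklist_n, widths,
                                 self_disjoint=True)
    return PeakSet("blacklist", intervals, genome_build=spec.genome_build,
                   source_format="bed3")


def simulate_segmentation(spec: FixtureSpec) -> StateSegmentation:
    """Tile the genome exactly with cycling chromatin-state labels."""
    rng = _substream(spec.seed, "__segmentation__")
    records = []
    for chrom in sorted(spec.chroms):
        length = spec.chroms[chrom]
        pos = 0
        while pos < length:
            end = min(pos + spec.seg_tile, length)
            state = f"E{int(rng.integers(1, spec.seg_states + 1))}"
            records.append((GenomicInterval(chrom, pos, end), state))
            pos = end
    return StateSegmentation(records)


def simulate_genes(spec: FixtureSpec) -> GeneModel:
    """Evenly spaced genes with random strand and two exons each."""
    rng = _substream(spec.seed, "__genes__")
    total = sum(spec.chroms.values())
    genes: list[Gene] = []
    gid = 0
    for chrom in sorted(spec.chroms):
        length = spec.chroms[chrom]
        n = max(1, round(spec.n_genes * length / total))
        spacing = length // (n + 1)
        for i in range(n):
            start = spacing * (i + 1)
            end = min(start + spec.gene_span, length)
            if end - start < 2:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            exon_len = max(1, (end - start) // 4)
            exons = ((start, start + exon_len), (end - exon_len, end))
            genes.append(Gene(f"GENE{gid:04d}", chrom, strand, start, end, exons))
            gid += 1
    return GeneModel(genes)


def simulate_gmt(spec: FixtureSpec, genes: GeneModel,
                 truth: PeakSet) -> dict[str, set[str]]:
    """Gene sets with one known-enriched set: genes whose promoters sit
    near truth peaks."""
    rng = _substream(spec.seed, "__gmt__")
    from ._overlap import build_trees, overlap_flags
    trees = build_trees(truth)
    near_truth = []
    for g in genes.genes:
        ps, pe = promoter_window(g)
        probe = GenomicInterval(g.chrom, ps, max(pe, ps + 1))
        if overlap_flags([probe], trees)[0]:
            near_truth.append(g.gene_id)
    all_ids = sorted(genes.gene_ids())
    sets: dict[str, set[str]] = {}
    if near_truth:
        size = min(len(near_truth), spec.gmt_set_size)
        picked = rng.choice(len(near_truth), size=size, replace=False)
        sets["TRUTH_TARGETS"] = {near_truth[int(i)] for i in picked}
    for i in range(spec.gmt_n_random_sets):
        size = min(len(all_ids), spec.gmt_set_size)
        picked = rng.choice(len(all_ids), size=size, replace=False)
        sets[f"RANDOM_SET_{i + 1}"] = {all_ids[int(j)] for j in picked}
    return sets


def simulate_chain(spec: FixtureSpec) -> ChainMap:
    """Per-chromosome constant-shift chain (source build -> corpus build)."""
    target_sizes = {
        chrom: size + max(0, spec.chain_shifts.get(chrom, 0))
        for chrom, size in spec.chroms.items()}
    return shift_chain(spec.chain_shifts, dict(spec.chroms),
                       source_build=spec.chain_source_build,
                       target_build=spec.genome_build,
                       target_sizes=target_sizes)


def write_picard_metrics(path: Path, duplication_rate: float,
                         library: str = "synthetic_lib") -> Path:
    """Write a minimal, syntactically valid MarkDuplicates metrics file."""
    with open(path, "w") as handle:
        handle.write("## htsjdk.samtools.metrics.StringHeader\n")
        handle.write("# MarkDuplicates (synthetic metrics)\n")
        handle.write("## METRICS CLASS\tpicard.sam.DuplicationMetrics\n")
        handle.write("LIBRARY\tUNPAIRED_READS_EXAMINED\tREAD_PAIRS_EXAMINED\t"
                     "PERCENT_DUPLICATION\tESTIMATED_LIBRARY_SIZE\n")
        handle.write(f"{library}\t0\t1000000\t{duplication_rate}\t5000000\n")
    return path


def simulate_aux(spec: FixtureSpec, outdir: Path) -> dict[str, Path]:
    """Write every auxiliary input format to ``outdir``; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    blacklist = simulate_blacklist(spec)
    paths["blacklist"] = write_peaks(blacklist, outdir / "blacklist.bed")

    paths["chrom_sizes"] = outdir / "genome.chrom.sizes"
    with open(paths["chrom_sizes"], "w") as handle:
        for chrom in sorted(spec.chroms):
            handle.write(f"{chrom}\t{spec.chroms[chrom]}\n")

    chain = simulate_chain(spec)
    src, dst = spec.chain_source_build, spec.genome_build
    paths["chain"] = write_chain(
        chain, outdir / f"{src}To{dst[0].upper()}{dst[1:]}.over.chain")

    seg = simulate_segmentation(spec)
    paths["segmentation"] = outdir / "segmentation.bed"
    with open(paths["segmentation"], "w") as handle:
        for iv, state in seg.intervals:
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{state}\n")

    genes = simulate_genes(spec)
    paths["genes"] = outdir / "genes.bed"
    with open(paths["genes"], "w") as handle:
        for g in genes.genes:
            sizes = ",".join(str(e - s) for s, e in g.exons) + ","
            starts = ",".join(str(s - g.start) for s, _ in g.exons) + ","
            handle.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t{len(g.exons)}\t{sizes}\t{starts}\n")

    truth = simulate_truth(spec)
    gmt = simulate_gmt(spec, genes, truth)
    paths["gmt"] = outdir / "genesets.gmt"
    with open(paths["gmt"], "w") as handle:
        for name, members in gmt.items():
            handle.write("\t".join([name, "synthetic"] + sorted(members)) + "\n")

    paths["picard"] = write_picard_metrics(
        outdir / "picard_metrics.txt", spec.duplication_rate)
    return paths


def write_corpus(spec: FixtureSpec, outdir: Path) -> dict[str, Path]:
    """Write the complete corpus: peak files, truth, and all aux inputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = simulate_aux(spec, outdir)
    samples, truth = simulate_peaksets(spec)
    peak_dir = outdir / "peaks"
    peak_dir.mkdir(exist_ok=True)
    for ps in samples:
        paths[ps.label] = write_peaks(ps, peak_dir / f"{ps.label}.narrowPeak")
    paths["truth"] = write_peaks(truth, outdir / "truth.bed")
    return paths
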