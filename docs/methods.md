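# Methods

## Coordinates and overlap semantics

All intervals are BED-convention 0-based half-open `[start, end)`,
everywhere, including internally. Overlap between two intervals means at
least one shared base under that convention, so bookended intervals
(`[100,200)` vs `[200,300)`) do **not** overlap. Overlap is strand-blind
because peak files are in practice unstranded; a `min_overlap_bp`
parameter exists on the comparison functions for stricter use. Chromosome
names are taken verbatim — no silent `chr`-prefix normalization, because
renaming can manufacture false overlaps between files from different
providers.

The overlap engine is an interval tree per chromosome
(`intervaltree`); the test suite holds it against an independent
all-pairs brute-force oracle on random fixtures, so the fast path and the
definition can never drift apart silently.

## Standardization pipeline

Order is fixed as **liftover → blacklist → chromosome tidy**. The
blacklist may be declared on its own genome build, so it is lifted to the
target build once before any filtering; applying the blacklist before
harmonizing builds would compare coordinates from different assemblies.
QC percentages (`pct_blacklisted`, `pct_nonstandard_chrom`) are measured
on the post-liftover, pre-filter set so they describe the file as
delivered.

*Blacklist removal* drops any peak sharing ≥ 1 bp with a blacklisted
region. No minimum-overlap fraction is applied: blacklisted loci produce
artifact signal and a peak touching one is suspect.

*Chromosome tidying* keeps names of the form `chr1..chrN`/`chrX`/`chrY`
(with or without the prefix) that are also present in the supplied
chromosome-sizes table; `chrM`/`MT` is removed unless `keep_mito`;
underscore-bearing contigs, `chrUn*` and similar are always removed.

*Liftover* parses UCSC chain files directly (header + ungapped block
triples, including minus-strand destination chains). Each interval is
routed through the highest-scoring chain overlapping it and mapped block
by block; the lifted interval spans the mapped bases on the destination
chromosome. Intervals with no covering chain or retaining < 95 % of
their width (`liftover_min_fraction`, matching common liftOver practice)
are dropped and counted. Multi-hop routing and reciprocal-best filtering
are out of scope; one chain per declared build pair.

## Strength column and precision–recall

The thresholding column is inferred per file in priority order
**q_value → signal_value → score**, requiring the column to be present
and non-constant; the MACS convention of `-1` meaning "not computed" in
the p/q columns is parsed as missing. SEACR total signal and HOMER tag
counts land in `signal_value` via their dialect readers, so the same
priority rule covers them. When nothing varies, thresholding degrades to
a single keep-all cutoff.

Thresholds are the `n_thresholds` (default 11) equally spaced quantiles
of the sample's own strength values, which makes curves comparable
between callers whose score scales differ by orders of magnitude.
Precision uses retained sample peaks as denominator, recall uses
reference peaks; both follow standard usage. Peaks lacking a strength
value are retained at every threshold (they cannot be ranked, and
dropping them would silently change the keep-all point); zero retained
peaks records precision as missing rather than 0. F1 is the harmonic
mean, defined as 0 when precision and recall are both 0.

## Upset counts and consensus

Both operate on merged regions rather than raw peaks, so a region is
counted once no matter how many fragments a sample contributes. Upset
merging unites intervals that strictly overlap (bookended regions stay
separate — they share no base). Consensus merging additionally unites
intervals within `min_gap` bp (default 0, which merges bookended
intervals); support is the number of distinct members intersecting the
merged interval, counted per interval, not per base. The default
`min_samples=2` mirrors the "replicated peaks" idea. Consensus output
carries no strength column; downstream PR on consensus uses keep-all
thresholding.

## Binned correlation

The genome is tiled into `bin_width` bins (default 1000 bp; the last bin
of each chromosome may be short). A bin's value per sample is 0 when
untouched, else 1 (binary mode) or the **maximum** strength value among
intersecting peaks (score mode; max, not sum, so a peak fragmented by the
caller does not inflate intensity). Bins empty in every sample are
dropped before correlating (on by default — genome-scale tilings are
overwhelmingly empty and the zeros would dominate every coefficient).
Default method is Spearman, robust to score-scale differences between
callers. Two exactly identical columns correlate at 1.0 even when
constant (a duplicated binary sample reduces to an all-ones column after
empty-bin dropping); a constant column against a differing one is
recorded as missing, since the coefficient is undefined there.

## Annotation choices

Chromatin-state composition is **base-pair weighted**: fractions are
state-overlap bases over all peak bases overlapping any state, so they
sum to 1 whenever any overlap exists, and partial overlaps are
represented proportionally. Peak bases and whole peaks outside the
segmentation are reported in an explicit "unannotated" bucket rather
than dropped.

Feature labels use fixed precedence Promoter > Exon > Intron >
Downstream > Distal Intergenic, with a promoter window of (−2000, +500)
bp around the TSS, oriented by strand, and a 3000 bp downstream window
past the transcript end — conventional defaults for this style of
annotator, all configurable. TSS is the span start on `+` and span
end − 1 on `-`.

TSS profiles project peak bodies into TSS-relative coordinates by
mapping the interval endpoints (`[s−T, e−T)` on `+`, mirrored to
`[T−e, T−s)` on `-`), clip to ±3000 bp and increment every bin the body
covers, once per (peak, TSS) pair. The brute-force conservation oracle in
the tests walks peak bases one by one with the same orientation rule.

Gene-set enrichment intersects each GMT set with the universe (default:
all genes of the supplied model), computes the one-sided hypergeometric
tail P(X ≥ k) via `scipy.stats.hypergeom`, and adjusts across the sets of
one GMT file with Benjamini–Hochberg (`statsmodels`). Peaks map to genes
by promoter overlap by default; a nearest-TSS rule (ties keep all tied
genes) is available.

## Synthetic corpus

The generator emulates the *comparison structure* of real experiments,
not the reads: a latent truth set of 300 disjoint 400 bp intervals on a
toy genome of two 1 Mb chromosomes (large enough for ~10³ peaks without
saturation, small enough for brute-force oracles); per sample, a
`shared_fraction` of peaks are truth intervals re-centred with ≤ 50 bp
jitter (bounded below half a peak width, so a truth-derived peak always
still overlaps its truth interval), the rest are background placed
uniformly while avoiding the truth set entirely. Consequently the
expected keep-all precision against the truth equals the shared fraction
exactly, with zero analytic background-overlap contribution — the
property the parameter-recovery checks assert. Strengths are Gaussian
(−log10 scale) with truth-derived peaks centred at 8 and background at
3, making PR curves informative. Default samples are two replicates at
`shared_fraction=0.8` plus one contrast sample at 0.2.

What this does *not* emulate: realistic peak-width/score distributions,
caller-specific artifacts, copy-number or mappability structure, or any
read-level noise. Passing tests demonstrate algorithmic correctness on
the defined geometry, not biological validity on real data.

All randomness flows from one seed; per-sample substreams are derived by
CRC-32 hashing of the sample label into a `SeedSequence` spawn key, so
adding a sample never perturbs existing ones. Auxiliary files (blacklist,
chain implementing a declared per-chromosome shift, exact-tiling
segmentation, evenly spaced two-exon genes, GMT with one set planted
around truth-adjacent promoters, Picard metrics) are all written in their
standard text formats and re-parsed by the package's own readers in
tests.

## Report and determinism

The one-call pipeline runs analyses in a fixed order; a failure or
missing auxiliary input for an optional analysis is logged with a reason
and skipped, never aborting the run. Tables are written as TSV with a
fixed float format, so two runs with the same config and seed are
byte-identical; wall-clock timestamps appear only in `run.log`,
`manifest.json` and the HTML header, never in result tables. The HTML
report is a single self-contained file (figures embedded as base64 PNG)
with three anchored sections — General Metrics, Peak Overlap, Functional
Annotation — and a collapsed echo of the exact configuration used.

## Problem sizes

Tests and the acceptance script run at desk scale by design: random
fixtures of ≤ 500 intervals for oracle comparisons, the two-chromosome
toy genome for corpora, 50 seeded corpora for the parameter-recovery
check, and a scaled-down corpus (2 × 200 kb, 120 peaks/sample) for the
end-to-end determinism runs. These sizes are where the brute-force
oracles remain exact and fast; the algorithms themselves are sorted/tree
based and scale to genome-sized inputs.

## Known limitations

- No bigBed/bigWig/BAM input; peak calling itself is out of scope.
- Only the fast merge-based consensus strategy is implemented; no
  distribution-modelling consensus method.
- ChromHMM segmentations are consumed, never trained; GO/KEGG databases
  are user-supplied GMT files, never downloaded.
- Liftover supports a single declared chain per build pair; no multi-hop
  routing.
- Feature annotation is gene-level, not transcript-isoform aware.
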