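"""Compare two peak files: overlap percentages and upset-style counts.

Builds two small synthetic narrowPeak samples that share most of their
peaks with a common latent truth set, then asks how much they overlap
each other.
"""

from peakcompare import FixtureSpec, SamplePlan, overlap_matrix, upset_counts
from peakcompare.simulate import simulate_peaksets

spec = FixtureSpec(
    seed=11,
    samples=[SamplePlan("atac_rep1", n_peaks=400, shared_fraction=0.8),
             SamplePlan("atac_rep2", n_peaks=400, shared_fraction=0.8)])
samples, truth = simulate_peaksets(spec)

matrix = overlap_matrix(samples)
print("Percent of row-sample peaks overlapping the column sample:")
print(matrix.values.round(1))
# Entry (i, j) uses sample i as denominator, so the matrix is asymmetric:
# high values mean most of i's peaks are recovered in j.

upset = upset_counts(samples)
print("\nMerged-region counts by membership:")
print(upset.to_frame().to_string(index=False))
# Regions private to one replicate are candidate irreproducible peaks;
# the shared bucket approximates the replicated signal.
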