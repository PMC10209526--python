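"""Call consensus peaks across replicates.

Merged intervals supported by at least ``min_samples`` members are
retained — with min_samples=2 the output resembles ENCODE-style
"replicated peaks"."""

from peakcompare import FixtureSpec, SamplePlan, compute_consensus_peaks
from peakcompare.simulate import simulate_peaksets

spec = FixtureSpec(
    seed=21,
    samples=[SamplePlan(f"rep{i}", n_peaks=400, shared_fraction=0.75)
             for i in (1, 2, 3)])
samples, _ = simulate_peaksets(spec)

for k in (1, 2, 3):
    cons = compute_consensus_peaks(samples, min_samples=k)
    print(f"min_samples={k}: {len(cons)} consensus peaks")
# Raising the support requirement can only shrink the consensus set:
# support 1 is a plain merge of everything, support 3 keeps only regions
# every replicate reproduces.

best = compute_consensus_peaks(samples, min_samples=2)
first = best.intervals[0]
print(f"example: {first.interval.chrom}:{first.interval.start}-"
      f"{first.interval.end} supported by {first.members}")
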