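"""Benchmark a sample against a reference with precision-recall curves.

Thresholds sweep the sample's own peak-strength quantiles (-log10
q-values here), so the curve shows how precision trades against recall
as weaker peaks are discarded.
"""

from peakcompare import FixtureSpec, SamplePlan, precision_recall
from peakcompare.simulate import simulate_peaksets

spec = FixtureSpec(
    seed=5,
    samples=[SamplePlan("sample", n_peaks=500, shared_fraction=0.7)])
(sample,), truth = simulate_peaksets(spec)

curve = precision_recall(sample, truth, n_thresholds=7)
print(f"strength column: {curve.strength_column}")
print(curve.to_frame().round(3).to_string(index=False))
# At the lowest threshold everything is kept: precision ~= the fraction of
# peaks that are genuine (0.7 by construction), recall is maximal. Raising
# the cutoff discards weak background peaks first, so precision climbs
# toward 1 while recall falls.
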