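"""Chromatin states, feature labels, TSS profiles and enrichment."""

from __future__ import annotations

import numpy as np
import pytest

from peakcompare.annotation import (FEATURE_LABELS, Gene, GeneModel,
                                    StateSegmentation, chromhmm_annotate,
                                    enrichment_test, feature_annotate,
                                    peaks_to_genes, read_gene_bed, read_gmt,
                                    read_segmentation, tss_profile)
from peakcompare.core import GenomicInterval

from _oracles import hypergeom_tail_enumeration, tss_profile_total_bruteforce
from conftest import make_set, random_intervals


def seg_from(rows) -> StateSegmentation:
    return StateSegmentation([(GenomicInterval(c, s, e), st)
                              for c, s, e, st in rows])


class TestChromHMM:
    def test_single_state_fraction_one(self):
        seg = seg_from([("chr1", 0, 1000, "E1")])
        ann = chromhmm_annotate(make_set("s", [("chr1", 100, 200)]), seg)
        assert ann.fractions["E1"] == 1.0
        assert ann.unannotated_peaks == 0

    def test_split_peak_base_weighted(self):
        seg = seg_from([("chr1", 0, 160, "E1"), ("chr1", 160, 1000, "E2")])
        ann = chromhmm_annotate(make_set("s", [("chr1", 100, 200)]), seg)
        assert ann.fractions["E1"] == pytest.approx(0.6)
        assert ann.fractions["E2"] == pytest.approx(0.4)

    def test_peaks_outside_segmentation_bucketed(self):
        seg = seg_from([("chr2", 0, 1000, "E1")])
        ann = chromhmm_annotate(make_set("s", [("chr1", 0, 100),
                                               ("chr1", 500, 600)]), seg)
        assert (ann.fractions == 0).all()
        assert ann.unannotated_peaks == 2
        assert ann.unannotated_bases == 200

    def test_fractions_sum_to_one_on_random_fixture(self):
        rng = np.random.default_rng(19)
        rows = []
        for chrom in ("chr1", "chr2"):
            pos = 0
            while pos < 100_000:
                end = pos + int(rng.integers(500, 3000))
                rows.append((chrom, pos, min(end, 100_000),
                             f"E{rng.integers(1, 7)}"))
                pos = end
        seg = seg_from(rows)
        peaks = make_set("s", random_intervals(rng, 200))
        ann = chromhmm_annotate(peaks, seg)
        if ann.annotated_bases:
            assert ann.fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_overlapping_segmentation_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            seg_from([("chr1", 0, 100, "E1"), ("chr1", 50, 150, "E2")])

    def test_segmentation_reader(self, tmp_path):
        p = tmp_path / "seg.bed"
        p.write_text("chr1\t0\t100\tE1\nchr1\t100\t200\tE2\n")
        seg = read_segmentation(p)
        assert seg.states == ("E1", "E2")


def toy_genes():
    return GeneModel([
        # + strand gene: TSS 10_000, span 10_000-14_000, exons at both ends
        Gene("G1", "chr1", "+", 10_000, 14_000,
             ((10_000, 10_500), (13_500, 14_000))),
        # - strand gene: TSS 29_999, span 26_000-30_000
        Gene("G2", "chr1", "-", 26_000, 30_000,
             ((26_000, 26_500), (29_500, 30_000))),
    ])


class TestFeatureAnnotate:
    def test_promoter_beats_exon(self):
        # overlaps both G1's promoter window and its first exon
        ann = feature_annotate(make_set("s", [("chr1", 9_900, 10_100)]),
                               toy_genes())
        assert ann.labels == ["Promoter"]

    def test_intron_inside_span_without_exon(self):
        ann = feature_annotate(make_set("s", [("chr1", 11_000, 11_100)]),
                               toy_genes())
        assert ann.labels == ["Intron"]

    def test_exon_label(self):
        ann = feature_annotate(make_set("s", [("chr1", 13_600, 13_700)]),
                               toy_genes())
        assert ann.labels == ["Exon"]

    def test_downstream_strand_aware(self):
        # just past G1's end on + strand
        ann = feature_annotate(make_set("s", [("chr1", 14_500, 14_600)]),
                               toy_genes())
        assert ann.labels == ["Downstream"]
        # before G2's span start = downstream of the - strand gene; must sit
        # outside G2's promoter reach (TSS 29999 is at the far end)
        ann2 = feature_annotate(make_set("s", [("chr1", 24_000, 24_100)]),
                                toy_genes())
        assert ann2.labels == ["Downstream"]

    def test_distal_and_summary_fractions(self):
        peaks = make_set("s", [("chr1", 9_900, 10_100),   # Promoter
                               ("chr1", 8_500, 8_600),    # Promoter (window)
                               ("chr1", 9_000, 9_100),    # Promoter
                               ("chr1", 11_000, 11_100),  # Intron
                               ("chr1", 12_000, 12_100),  # Intron
                               ("chr1", 500_000, 500_100)])  # Distal
        ann = feature_annotate(peaks, toy_genes())
        assert ann.fractions["Promoter"] == pytest.approx(0.5)
        assert ann.fractions["Intron"] == pytest.approx(2 / 6)
        assert ann.fractions["Distal Intergenic"] == pytest.approx(1 / 6)

    def test_labels_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(23)
        peaks = make_set("s", random_intervals(rng, 300))
        ann = feature_annotate(peaks, toy_genes())
        assert len(ann.labels) == len(peaks)
        assert set(ann.labels) <= set(FEATURE_LABELS)
        assert ann.fractions.sum() == pytest.approx(1.0)


class TestTSSProfile:
    def test_plus_strand_hand_geometry(self):
        genes = GeneModel([Gene("G", "chr1", "+", 1000, 3000)])
        peaks = make_set("s", [("chr1", 900, 950)])
        prof = tss_profile(peaks, genes, window=3000, bin_width=50)
        nz = prof.bin_starts[prof.counts > 0]
        assert list(nz) == [-100]  # body covers [-100, -50)
        assert prof.counts.sum() == 1

    def test_minus_strand_mirrors(self):
        genes = GeneModel([Gene("G", "chr1", "-", 0, 1001)])  # TSS at 1000
        peaks = make_set("s", [("chr1", 900, 950)])
        prof = tss_profile(peaks, genes, window=3000, bin_width=50)
        nz = prof.bin_starts[prof.counts > 0]
        assert list(nz) == [50]  # mirrored to [+50, +100)

    def test_no_nearby_peaks_zero_profile(self):
        genes = GeneModel([Gene("G", "chr1", "+", 500_000, 501_000)])
        prof = tss_profile(make_set("s", [("chr1", 0, 100)]), genes)
        assert prof.counts.sum() == 0

    def test_total_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(31)
        genes = GeneModel([
            Gene(f"G{i}", "chr1", "+" if rng.random() < 0.5 else "-",
                 int(p), int(p) + 2000)
            for i, p in enumerate(rng.integers(5000, 90_000, 25))])
        peaks = make_set("s", random_intervals(rng, 60, chroms=("chr1",),
                                               length=95_000, max_width=400))
        prof = tss_profile(peaks, genes, window=3000, bin_width=100)
        assert prof.counts.sum() == tss_profile_total_bruteforce(
            peaks, genes, 3000, 100)

    def test_strand_mirroring_exact(self):
        # same geometry relative to TSS on both strands -> mirrored profile
        genes_p = GeneModel([Gene("G", "chr1", "+", 50_000, 52_000)])
        genes_m = GeneModel([Gene("G", "chr1", "-", 48_000, 50_001)])
        peaks = make_set("s", [("chr1", 49_000, 49_400),
                               ("chr1", 50_200, 50_900)])
        p = tss_profile(peaks, genes_p, window=3000, bin_width=100)
        m = tss_profile(peaks, genes_m, window=3000, bin_width=100)
        assert list(p.counts) == list(m.counts[::-1])

    def test_bad_bin_width_and_empty_genes(self):
        with pytest.raises(ValueError):
            tss_profile(make_set("s", []), GeneModel([Gene("G", "chr1", "+",
                                                           0, 10)]),
                        window=3000, bin_width=700)
        with pytest.raises(ValueError, match="empty"):
            tss_profile(make_set("s", []), GeneModel([]))

    def test_gene_bed12_reader_reconstructs_exons(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text("chr1\t100\t900\tG1\t0\t+\t100\t900\t0\t2\t"
                     "100,200,\t0,600,\n")
        model = read_gene_bed(p)
        g = model.genes[0]
        assert g.exons == ((100, 200), (700, 900))
        assert g.tss == 100


class TestPeaksToGenes:
    def test_promoter_overlap_rule(self):
        hits = peaks_to_genes(make_set("s", [("chr1", 9_000, 9_100)]),
                              toy_genes())
        assert hits == {"G1"}

    def test_nearest_tss_tie_keeps_both(self):
        genes = GeneModel([Gene("A", "chr1", "+", 1000, 2000),
                           Gene("B", "chr1", "+", 3000, 4000)])
        # 1 bp peak equidistant (1000 bp) from both TSSs -> tie keeps both
        tied = make_set("s", [("chr1", 2000, 2001)])
        assert peaks_to_genes(tied, genes, rule="nearest_tss") == {"A", "B"}
        # nudged 1 bp towards A -> unique winner
        nudged = make_set("s", [("chr1", 1999, 2000)])
        assert peaks_to_genes(nudged, genes, rule="nearest_tss") == {"A"}

    def test_multiple_peaks_set_semantics(self):
        peaks = make_set("s", [("chr1", 9_000, 9_100), ("chr1", 9_200, 9_300),
                               ("chr1", 30_200, 30_300)])
        hits = peaks_to_genes(peaks, toy_genes())
        assert hits == {"G1", "G2"}


class TestEnrichment:
    def test_certain_event_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        res = enrichment_test(universe, {"ALL": set(universe)}, universe)
        row = res.iloc[0]
        assert row["k"] == row["n"] == 10
        assert row["p_value"] == pytest.approx(1.0)

    def test_p_matches_enumeration_oracle(self):
        # N=20, K=5, n=5, k=4
        universe = {f"g{i}" for i in range(20)}
        special = {f"g{i}" for i in range(5)}
        query = {"g0", "g1", "g2", "g3", "g10"}
        res = enrichment_test(query, {"S": special}, universe)
        expected = hypergeom_tail_enumeration(20, 5, 5, 4)
        assert res.iloc[0]["p_value"] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("N,K,n,k", [(10, 3, 4, 2), (12, 6, 5, 5),
                                         (15, 7, 6, 0), (8, 2, 3, 1)])
    def test_enumeration_oracle_grid(self, N, K, n, k):
        from scipy.stats import hypergeom
        assert float(hypergeom.sf(k - 1, N, K, n)) == pytest.approx(
            hypergeom_tail_enumeration(N, K, n, k), abs=1e-12)

    def test_bh_hand_case_m2(self):
        # raw p {0.01, 0.04} -> BH {0.02, 0.04}
        universe = {f"g{i}" for i in range(40)}
        res = enrichment_test({"g0"}, {"A": {"g0"}, "B": {"g1"}}, universe)
        from statsmodels.stats.multitest import multipletests
        import numpy as np
        adj = multipletests(np.array([0.01, 0.04]), method="fdr_bh")[1]
        assert list(adj) == pytest.approx([0.02, 0.04])
        # and within the result table q >= p with BH monotonicity
        assert (res["q_value"] >= res["p_value"] - 1e-15).all()
        assert res["q_value"].is_monotonic_increasing

    def test_gmt_reader(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("SET1\tdesc\tg1\tg2\ng3\nSET2\tdesc\tg4\n")
        # note: malformed middle line g3 lacks tabs -> error
        with pytest.raises(ValueError):
            read_gmt(p)
        p.write_text("SET1\tdesc\tg1\tg2\nSET2\tdesc\tg4\n")
        sets = read_gmt(p)
        assert sets == {"SET1": {"g1", "g2"}, "SET2": {"g4"}}

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            enrichment_test(set(), {"A": {"g"}}, {"g"})
        with pytest.raises(ValueError):
            enrichment_test({"g"}, {"A": {"g"}}, set())
        with pytest.raises(ValueError, match="subset"):
            enrichment_test({"x"}, {"A": {"g"}}, {"g"})
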