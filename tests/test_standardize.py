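"""Blacklist removal, chromosome tidying, liftover and QC metrics."""

from __future__ import annotations

import numpy as np
import pytest

from peakcompare.chain import identity_chain, read_chain, shift_chain, write_chain
from peakcompare.core import ChromSizes, GenomicInterval
from peakcompare.standardize import (liftover, parse_picard_metrics,
                                     remove_blacklist, standardize_all,
                                     tidy_chromosomes)
from peakcompare.simulate import write_picard_metrics

from _oracles import brute_overlap_flags
from conftest import make_set, random_intervals


class TestRemoveBlacklist:
    def test_one_bp_overlap_is_removed(self):
        peaks = make_set("s", [("chr1", 100, 200)])
        black = make_set("bl", [("chr1", 199, 300)])
        out, removed = remove_blacklist(peaks, black)
        assert removed == 1 and len(out) == 0

    def test_bookended_adjacency_is_kept(self):
        peaks = make_set("s", [("chr1", 100, 200)])
        black = make_set("bl", [("chr1", 200, 300)])
        out, removed = remove_blacklist(peaks, black)
        assert removed == 0 and len(out) == 1

    def test_counts_match_exhaustive_check(self):
        peaks = make_set("s", [("chr1", 0, 50), ("chr1", 100, 150),
                               ("chr1", 300, 400), ("chr2", 0, 50),
                               ("chr2", 500, 600)])
        black = make_set("bl", [("chr1", 120, 130), ("chr2", 0, 10)])
        out, removed = remove_blacklist(peaks, black)
        assert removed == 2 and len(out) == 3
        assert not any(brute_overlap_flags(out.intervals, black.intervals))

    def test_build_mismatch_rejected(self):
        with pytest.raises(ValueError, match="build"):
            remove_blacklist(make_set("s", [("chr1", 0, 10)], build="hg19"),
                             make_set("bl", [("chr1", 0, 10)], build="hg38"))

    def test_idempotent_and_oracle_clean_on_random_fixture(self):
        rng = np.random.default_rng(11)
        peaks = make_set("s", random_intervals(rng, 400))
        black = make_set("bl", random_intervals(rng, 60))
        once, _ = remove_blacklist(peaks, black)
        twice, removed_again = remove_blacklist(once, black)
        assert removed_again == 0 and twice.intervals == once.intervals
        assert not any(brute_overlap_flags(once.intervals, black.intervals))


class TestTidyChromosomes:
    def test_contigs_and_mito_removed(self, chrom_sizes):
        peaks = make_set("s", [("chr1", 0, 10), ("chrM", 0, 10),
                               ("chr1_gl000191_random", 0, 10),
                               ("chrUn_gl000220", 0, 10)])
        out, removed = tidy_chromosomes(peaks, chrom_sizes)
        assert out.chroms() == ("chr1",) and removed == 3

    def test_keep_mito_flag(self, chrom_sizes):
        peaks = make_set("s", [("chr1", 0, 10), ("chrM", 0, 10)])
        out, _ = tidy_chromosomes(peaks, chrom_sizes, keep_mito=True)
        assert out.chroms() == ("chr1", "chrM")

    def test_empty_input(self, chrom_sizes):
        out, removed = tidy_chromosomes(make_set("s", []), chrom_sizes)
        assert len(out) == 0 and removed == 0

    def test_standard_chrom_absent_from_sizes_removed(self):
        sizes = ChromSizes({"chr1": 1000})
        peaks = make_set("s", [("chr1", 0, 10), ("chr7", 0, 10)])
        out, removed = tidy_chromosomes(peaks, sizes)
        assert out.chroms() == ("chr1",) and removed == 1


class TestLiftover:
    sizes = {"chr1": 10_000, "chr2": 10_000}

    def test_identity_chain_is_identity(self):
        peaks = make_set("s", [("chr1", 100, 200), ("chr2", 5, 50)],
                         build="hg19")
        chain = identity_chain(self.sizes, "hg19", "hg38")
        out, unmapped = liftover(peaks, chain)
        assert unmapped == 0
        assert [(iv.chrom, iv.start, iv.end) for iv in out] == \
            [("chr1", 100, 200), ("chr2", 5, 50)]
        assert out.genome_build == "hg38"

    def test_plus_ten_shift(self):
        chain = shift_chain({"chr1": 10}, self.sizes, "hg19", "hg38",
                            target_sizes={"chr1": 10_010, "chr2": 10_000})
        peaks = make_set("s", [("chr1", 100, 200)], build="hg19")
        out, unmapped = liftover(peaks, chain)
        assert unmapped == 0
        iv = out.intervals[0]
        assert (iv.start, iv.end) == (110, 210)

    def test_shift_then_unshift_roundtrip(self):
        fwd = shift_chain({"chr1": 25}, self.sizes, "hg19", "hg38",
                          target_sizes={"chr1": 10_025, "chr2": 10_000})
        back = shift_chain({"chr1": -25}, {"chr1": 10_025, "chr2": 10_000},
                           "hg38", "hg19", target_sizes=self.sizes)
        peaks = make_set("s", [("chr1", 100, 200), ("chr1", 5000, 5400)],
                         build="hg19")
        there, _ = liftover(peaks, fwd)
        home, unmapped = liftover(there, back)
        assert unmapped == 0
        assert [(iv.start, iv.end) for iv in home] == \
            [(iv.start, iv.end) for iv in peaks]

    def test_interval_outside_all_chains_dropped(self):
        chain = identity_chain({"chr1": 10_000}, "hg19", "hg38")
        peaks = make_set("s", [("chr9", 0, 100)], build="hg19")
        out, unmapped = liftover(peaks, chain)
        assert len(out) == 0 and unmapped == 1

    def test_partial_coverage_below_min_fraction_dropped(self):
        # chain covers only chr1:0-150 of a 200 bp peak -> 75% < 95%
        from peakcompare.chain import AlignmentBlock, Chain, ChainMap
        chain = ChainMap([Chain(1000, "chr1", 10_000, 0, 150, "chr1", 10_000,
                                "+", 0, 150, (AlignmentBlock(0, 0, 150),))],
                         "hg19", "hg38")
        peaks = make_set("s", [("chr1", 0, 200)], build="hg19")
        out, unmapped = liftover(peaks, chain)
        assert unmapped == 1
        out2, unmapped2 = liftover(peaks, chain, min_fraction=0.5)
        assert unmapped2 == 0 and out2.intervals[0].end == 150

    def test_build_mismatch_rejected(self):
        chain = identity_chain(self.sizes, "hg19", "hg38")
        with pytest.raises(ValueError, match="chain maps from"):
            liftover(make_set("s", [("chr1", 0, 10)], build="hg38"), chain)

    def test_aux_fields_preserved(self):
        chain = shift_chain({"chr1": 10}, self.sizes, "hg19", "hg38",
                            target_sizes={"chr1": 10_010, "chr2": 10_000})
        iv = GenomicInterval("chr1", 100, 200, name="p", score=7.0,
                             strand="+", q_value=3.5, summit_offset=42)
        out, _ = liftover(make_set("s", [iv], build="hg19",
                                   fmt="narrowPeak"), chain)
        lifted = out.intervals[0]
        assert (lifted.name, lifted.score, lifted.strand,
                lifted.q_value, lifted.summit_offset) == ("p", 7.0, "+", 3.5, 42)


class TestChainIO:
    def test_chain_file_roundtrip(self, tmp_path):
        original = shift_chain({"chr1": 10, "chr2": -5},
                               {"chr1": 10_000, "chr2": 10_000},
                               "hg19", "hg38",
                               target_sizes={"chr1": 10_010, "chr2": 10_000})
        path = write_chain(original, tmp_path / "hg19ToHg38.over.chain")
        again = read_chain(path)
        assert again.source_build == "hg19" and again.target_build == "hg38"
        peaks = make_set("s", [("chr1", 500, 600), ("chr2", 500, 600)],
                         build="hg19")
        a, _ = liftover(peaks, original)
        b, _ = liftover(peaks, again)
        assert [(i.start, i.end) for i in a] == [(i.start, i.end) for i in b]
        assert [(i.start, i.end) for i in b] == [(510, 610), (495, 595)]


class TestStandardizeAll:
    def test_worked_ten_peak_fixture(self, chrom_sizes):
        # 10 peaks: 2 blacklisted, 1 on chrM -> 7 kept, 20%, 10%
        peaks = make_set("s", [("chr1", i * 1000, i * 1000 + 100)
                               for i in range(9)] + [("chrM", 0, 100)],
                         build="hg38")
        black = make_set("bl", [("chr1", 1050, 1060), ("chr1", 3000, 3010)],
                         build="hg38")
        out, metrics = standardize_all([peaks], black,
                                       target_build="hg38",
                                       chrom_sizes=chrom_sizes)
        m = metrics[0]
        assert m.n_peaks_raw == 10 and m.n_peaks_final == 7
        assert m.pct_blacklisted == pytest.approx(20.0)
        assert m.pct_nonstandard_chrom == pytest.approx(10.0)
        assert m.width_summary["median"] == 100.0

    def test_equal_builds_match_manual_composition(self, chrom_sizes):
        rng = np.random.default_rng(5)
        peaks = make_set("s", random_intervals(rng, 200), build="hg38")
        black = make_set("bl", random_intervals(rng, 30), build="hg38")
        out, _ = standardize_all([peaks], black, target_build="hg38",
                                 chrom_sizes=chrom_sizes)
        manual, _ = remove_blacklist(peaks, black)
        manual, _ = tidy_chromosomes(manual, chrom_sizes)
        assert out[0].intervals == manual.intervals

    def test_cross_build_file_lifted_and_relabelled(self, chrom_sizes):
        chain = identity_chain(dict(chrom_sizes), "hg19", "hg38")
        peaks = make_set("s", [("chr1", 0, 100)], build="hg19")
        black = make_set("bl", [("chr2", 0, 10)], build="hg38")
        out, _ = standardize_all([peaks], black, target_build="hg38",
                                 chains=[chain], chrom_sizes=chrom_sizes)
        assert out[0].genome_build == "hg38" and len(out[0]) == 1

    def test_missing_chain_error_names_pair(self, chrom_sizes):
        peaks = make_set("s", [("chr1", 0, 100)], build="hg19")
        black = make_set("bl", [("chr2", 0, 10)], build="hg38")
        with pytest.raises(ValueError, match="hg19 -> hg38"):
            standardize_all([peaks], black, target_build="hg38",
                            chrom_sizes=chrom_sizes)

    def test_order_independence(self, chrom_sizes):
        rng = np.random.default_rng(6)
        sets = [make_set(f"s{i}", random_intervals(rng, 100), build="hg38")
                for i in range(3)]
        black = make_set("bl", random_intervals(rng, 20), build="hg38")
        fwd, _ = standardize_all(sets, black, target_build="hg38",
                                 chrom_sizes=chrom_sizes)
        rev, _ = standardize_all(sets[::-1], black, target_build="hg38",
                                 chrom_sizes=chrom_sizes)
        assert [s.intervals for s in fwd] == [s.intervals for s in rev[::-1]]


class TestPicardMetrics:
    def test_roundtrip(self, tmp_path):
        path = write_picard_metrics(tmp_path / "m.txt", 0.146)
        assert parse_picard_metrics(path) == pytest.approx(0.146)

    def test_zero_duplication(self, tmp_path):
        path = write_picard_metrics(tmp_path / "m.txt", 0.0)
        assert parse_picard_metrics(path) == 0.0

    def test_missing_column_errors(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("## METRICS CLASS\tpicard.sam.DuplicationMetrics\n"
                        "LIBRARY\tREAD_PAIRS\nlib\t100\n")
        with pytest.raises(ValueError, match="PERCENT_DUPLICATION"):
            parse_picard_metrics(path)
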