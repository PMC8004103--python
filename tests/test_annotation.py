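"""Positional RNA classification, eRNA calling, merging, activity rules."""

import numpy as np
import pandas as pd
import pytest

from encoop.annotation import (Enhancer, PeakSet, ReferenceTranscript,
                               TranscriptionUnit, assign_gencode_class,
                               call_eRNAs, classify_positional, classify_tus,
                               discard_overlapping, enhancer_activity,
                               merge_eRNAs)
from encoop.config import Thresholds

TU = TranscriptionUnit
REF = ReferenceTranscript


def peaks(mark, time_hr, *ivals):
    return PeakSet(mark, time_hr, pd.DataFrame(
        [("chr1", s, e) for s, e in ivals], columns=["chrom", "start", "end"]))


class TestGencodeClass:
    def test_covering_70pct_of_mrna_inherits_mrna(self):
        tu = TU("t", "chr1", 1000, 1700, "+")
        ref = [REF("r", "chr1", 1000, 2000, "+", "protein_coding")]
        assert assign_gencode_class(tu, ref) == "mRNA"

    def test_covering_half_of_every_transcript_is_unassigned(self):
        tu = TU("t", "chr1", 1000, 1500, "+")
        ref = [REF("r", "chr1", 1000, 2000, "+", "protein_coding")]
        assert assign_gencode_class(tu, ref) is None

    def test_maximal_fraction_transcript_wins(self):
        # 65% of an mRNA vs 90% of a lincRNA -> lincRNA
        tu = TU("t", "chr1", 0, 2000, "+")
        ref = [REF("m", "chr1", 0, 3000, "+", "protein_coding"),      # 2000/3000
               REF("l", "chr1", 0, 2200, "+", "lincRNA")]             # 2000/2200
        assert assign_gencode_class(tu, ref) == "lincRNA"

    def test_fraction_relative_to_tu_is_selectable(self):
        # TU covers 100% of its own length inside a huge gene
        tu = TU("t", "chr1", 1000, 1500, "+")
        ref = [REF("r", "chr1", 0, 100_000, "+", "protein_coding")]
        assert assign_gencode_class(tu, ref) is None
        assert assign_gencode_class(tu, ref, relative_to="tu") == "mRNA"


class TestPositional:
    # + strand mRNA with TSS at 10_000
    MRNA = TU("m", "chr1", 10_000, 20_000, "+", rna_class="mRNA")

    def test_antisense_upstream_of_tss_is_uaRNA(self):
        tu = TU("u", "chr1", 8_500, 9_700, "-")   # 5' end at 9699, body upstream
        assert classify_positional(tu, [self.MRNA]) == "uaRNA"

    def test_antisense_overlapping_tss_from_inside_is_convRNA(self):
        tu = TU("c", "chr1", 9_900, 10_400, "-")  # 5' end at 10_399, inside gene
        assert classify_positional(tu, [self.MRNA]) == "convRNA"

    def test_same_strand_downstream_within_1kb_is_dsRNA(self):
        tu = TU("d", "chr1", 20_400, 21_000, "+")  # 400 bp after the 3' end
        assert classify_positional(tu, [self.MRNA]) == "dsRNA"

    def test_downstream_beyond_1kb_needs_decaying_signal(self):
        tu = TU("d", "chr1", 25_000, 27_000, "+")  # 5 kb downstream
        assert classify_positional(tu, [self.MRNA]) is None
        decaying = lambda t: np.linspace(10, 1, 20)
        rising = lambda t: np.linspace(1, 10, 20)
        assert classify_positional(tu, [self.MRNA], signal_fn=decaying) == "dsRNA"
        assert classify_positional(tu, [self.MRNA], signal_fn=rising) is None

    def test_minus_strand_mrna_mirror_case(self):
        mrna = TU("m", "chr1", 10_000, 20_000, "-", rna_class="mRNA")  # TSS 19_999
        ua = TU("u", "chr1", 20_300, 21_500, "+")  # 5' at 20_300, body upstream
        assert classify_positional(ua, [mrna]) == "uaRNA"
        ds = TU("d", "chr1", 9_200, 9_800, "-")    # 200 bp downstream of 3' end
        assert classify_positional(ds, [mrna]) == "dsRNA"

    def test_far_tu_unassigned(self):
        tu = TU("x", "chr1", 50_000, 51_000, "-")
        assert classify_positional(tu, [self.MRNA]) is None


class TestDiscard:
    REFG = [REF("r", "chr1", 0, 10_000, "+", "protein_coding")]

    def test_quarter_overlap_discarded(self):
        tu = TU("t", "chr1", 0, 2_500, "-")
        discard_overlapping([tu], self.REFG)
        assert tu.rna_class == "discarded"

    def test_tenth_overlap_retained(self):
        tu = TU("t", "chr1", 0, 1_000, "-")
        discard_overlapping([tu], self.REFG)
        assert tu.rna_class == "unclassified"

    def test_already_classified_untouched(self):
        tu = TU("t", "chr1", 0, 9_000, "+", rna_class="mRNA")
        discard_overlapping([tu], self.REFG)
        assert tu.rna_class == "mRNA"


class TestCallErnas:
    def test_both_marks_at_any_time_points(self):
        tu = TU("t", "chr1", 10_000, 11_000, "+")
        atac = [peaks("ATAC", 24, (11_800, 12_300))]        # 800 bp away
        h3k4 = [peaks("H3K4me1", 0, (10_500, 10_800))]      # overlapping
        assert call_eRNAs([tu], atac, h3k4) == [tu]
        assert tu.rna_class == "eRNA"

    def test_atac_beyond_1kb_rejected(self):
        tu = TU("t", "chr1", 10_000, 11_000, "+")
        atac = [peaks("ATAC", 0, (12_501, 13_000))]         # 1501 bp away
        h3k4 = [peaks("H3K4me1", 0, (10_000, 10_500))]
        assert call_eRNAs([tu], atac, h3k4) == []
        assert tu.rna_class == "unclassified"

    def test_single_mark_never_suffices(self):
        tu = TU("t", "chr1", 10_000, 11_000, "+")
        atac = [peaks("ATAC", t, (10_200, 10_600)) for t in (0, 24, 96)]
        assert call_eRNAs([tu], atac, []) == []

    def test_boundary_distance_1000_is_accepted(self):
        tu = TU("t", "chr1", 10_000, 11_000, "+")
        atac = [peaks("ATAC", 0, (12_000, 12_400))]         # gap exactly 1000
        h3k4 = [peaks("H3K4me1", 0, (10_000, 10_100))]
        assert call_eRNAs([tu], atac, h3k4) == [tu]


class TestMerge:
    def e(self, i, s, t, strand="+"):
        return TU(f"e{i}", "chr1", s, t, strand, rna_class="eRNA")

    def test_gap_900_merges(self):
        out = merge_eRNAs([self.e(1, 100, 600), self.e(2, 1500, 2000)])
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (100, 2000)
        assert out[0].constituent_tu_ids == ["e1", "e2"]

    def test_gap_1000_merges_but_1001_does_not(self):
        assert len(merge_eRNAs([self.e(1, 0, 500), self.e(2, 1500, 2000)])) == 1
        assert len(merge_eRNAs([self.e(1, 0, 499), self.e(2, 1500, 2000)])) == 2

    def test_merge_ignores_strand(self):
        out = merge_eRNAs([self.e(1, 100, 400, "+"), self.e(2, 600, 900, "-")])
        assert len(out) == 1

    def test_idempotent_and_conserves_constituents(self):
        tus = [self.e(i, 3000 * i, 3000 * i + 500 + 700 * (i % 3))
               for i in range(10)]
        once = merge_eRNAs(tus)
        assert sum(len(e.constituent_tu_ids) for e in once) == 10
        again = merge_eRNAs(
            [TU(e.id, e.chrom, e.start, e.end, ".", rna_class="eRNA")
             for e in once])
        assert [(e.start, e.end) for e in again] == \
               [(e.start, e.end) for e in once]
        gaps = [b.start - a.end for a, b in zip(once, once[1:])]
        assert all(g > 1000 for g in gaps)


class TestActivity:
    def table(self, data):
        return pd.DataFrame(data, columns=["s1"])

    def test_sums_per_kb_normalized_constituents(self):
        counts = pd.DataFrame({"s1": [50, 100]}, index=["a", "b"])
        lengths = pd.Series({"a": 500, "b": 1000})
        enh = Enhancer("E", "chr1", 0, 2000, constituent_tu_ids=["a", "b"])
        act = enhancer_activity(enh, counts, pd.Series({"s1": 1.0}), lengths)
        assert act["s1"] == pytest.approx(50 / 0.5 + 100 / 1.0)  # 200

    def test_single_constituent_and_zero_counts(self):
        counts = pd.DataFrame({"s1": [30]}, index=["a"])
        enh = Enhancer("E", "chr1", 0, 1000, constituent_tu_ids=["a"])
        act = enhancer_activity(enh, counts, pd.Series({"s1": 1.0}),
                                pd.Series({"a": 1000}))
        assert act["s1"] == 30
        counts["s1"] = 0
        assert enhancer_activity(enh, counts, pd.Series({"s1": 1.0}),
                                 pd.Series({"a": 1000}))["s1"] == 0

    def test_scales_inversely_with_size_factor(self):
        counts = pd.DataFrame({"s1": [40]}, index=["a"])
        enh = Enhancer("E", "chr1", 0, 1000, constituent_tu_ids=["a"])
        one = enhancer_activity(enh, counts, pd.Series({"s1": 1.0}),
                                pd.Series({"a": 1000}))
        two = enhancer_activity(enh, counts, pd.Series({"s1": 2.0}),
                                pd.Series({"a": 1000}))
        assert one["s1"] == pytest.approx(2 * two["s1"])

    def test_missing_constituent_raises(self):
        enh = Enhancer("E", "chr1", 0, 1000, constituent_tu_ids=["nope"])
        with pytest.raises(KeyError):
            enhancer_activity(enh, pd.DataFrame({"s1": []}),
                              pd.Series({"s1": 1.0}), pd.Series(dtype=float))


class TestFullPass:
    def test_classification_is_a_partition(self, small_sim):
        sim = small_sim
        tus = [TranscriptionUnit(t.id, t.chrom, t.start, t.end, t.strand)
               for t in sim.annotation.all_tus]
        classify_tus(tus, sim.annotation.reference,
                     sim.peaks["ATAC"], sim.peaks["H3K4me1"])
        from encoop.annotation import RNA_CLASSES
        assert all(t.rna_class in RNA_CLASSES for t in tus)

    def test_erna_recall_1_and_decoy_fp_0(self, small_sim):
        sim = small_sim
        tus = [TranscriptionUnit(t.id, t.chrom, t.start, t.end, t.strand)
               for t in sim.annotation.all_tus]
        classify_tus(tus, sim.annotation.reference,
                     sim.peaks["ATAC"], sim.peaks["H3K4me1"])
        called = {t.id for t in tus if t.rna_class == "eRNA"}
        true_ernas = {tid for e in sim.annotation.enhancers
                      for tid in e.constituent_tu_ids}
        decoys = {t.id for t in sim.annotation.decoy_tus}
        assert true_ernas <= called            # recall = 1.0
        assert not (called & decoys)           # false-positive rate = 0

    def test_merged_enhancers_recover_true_loci(self, small_sim):
        sim = small_sim
        tus = [TranscriptionUnit(t.id, t.chrom, t.start, t.end, t.strand)
               for t in sim.annotation.all_tus]
        classify_tus(tus, sim.annotation.reference,
                     sim.peaks["ATAC"], sim.peaks["H3K4me1"])
        merged = merge_eRNAs([t for t in tus if t.rna_class == "eRNA"])
        assert len(merged) == len(sim.annotation.enhancers)
        truth = sorted((e.chrom, e.start, e.end)
                       for e in sim.annotation.enhancers)
        got = sorted((e.chrom, e.start, e.end) for e in merged)
        assert truth == got
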