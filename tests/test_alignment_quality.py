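"""Element derivation, windowed reference-based QV, indel impact."""

import math

import pytest

from asmqc._intervals import intersect, total_length
from asmqc.alignment_quality import (
    ElementAnnotation,
    aggregate_qv,
    derive_elements,
    indel_impact,
    window_qv,
)
from asmqc.models import DiffRecord
from asmqc.simulate import sim_alignment_diffs


class TestDeriveElements:
    def test_set_arithmetic(self):
        el = derive_elements(
            genes=[("c", 10, 60)],
            exons=[("c", 10, 20), ("c", 40, 60)],
            repeats=[],
            contig_lengths={"c": 100},
        )
        assert el.intervals("intron", "c") == [(20, 40)]
        assert el.intervals("intergenic", "c") == [(0, 10), (60, 100)]

    def test_no_genes_all_intergenic(self):
        el = derive_elements([], [], [], {"c": 100})
        assert el.intervals("intergenic", "c") == [(0, 100)]

    def test_exons_equal_genes_no_introns(self):
        el = derive_elements([("c", 5, 50)], [("c", 5, 50)], [], {"c": 100})
        assert el.intervals("intron", "c") == []

    def test_exon_outside_gene_rejected(self):
        with pytest.raises(ValueError, match="c:70-80"):
            derive_elements([("c", 0, 50)], [("c", 70, 80)], [], {"c": 100})

    def test_partition_covers_contig_exactly(self):
        el = derive_elements(
            genes=[("c", 10, 60), ("c", 70, 90)],
            exons=[("c", 10, 30), ("c", 75, 85)],
            repeats=[("c", 0, 20)],
            contig_lengths={"c": 100},
        )
        pieces = (
            el.intervals("exon", "c")
            + el.intervals("intron", "c")
            + el.intervals("intergenic", "c")
        )
        assert total_length(pieces) == 100
        # pairwise disjoint
        for cls_a, cls_b in [("exon", "intron"), ("exon", "intergenic"),
                             ("intron", "intergenic")]:
            assert intersect(el.intervals(cls_a, "c"), el.intervals(cls_b, "c")) == []


def _whole(windows):
    return [w for w in windows if w.element_class == "whole"]


class TestWindowQV:
    EMPTY = ElementAnnotation(contig_lengths={"c": 100_000}, classes={})

    def test_phred_arithmetic(self):
        diffs = [DiffRecord("c", i * 100, "snv", 1) for i in range(10)]
        (w,) = _whole(window_qv(diffs, {"c": [(0, 100_000)]}, self.EMPTY))
        assert w.aligned_bp == 100_000 and w.snv_bp == 10
        assert w.qv_total == pytest.approx(40.0)
        assert w.qv_snv == pytest.approx(40.0)

    def test_zero_differences_capped_at_60(self):
        (w,) = _whole(window_qv([], {"c": [(0, 100_000)]}, self.EMPTY))
        assert w.qv_total == 60.0

    def test_deletion_split_across_window_boundary(self):
        diffs = [DiffRecord("c", 99_999, "del", 2)]
        ws = _whole(window_qv(diffs, {"c": [(0, 200_000)]}, self.EMPTY))
        assert [(w.window_start, w.del_bp) for w in ws] == [(0, 1), (100_000, 1)]

    def test_insertion_full_length_at_anchor(self):
        diffs = [DiffRecord("c", 99_999, "ins", 500)]
        ws = _whole(window_qv(diffs, {"c": [(0, 200_000)]}, self.EMPTY))
        assert [(w.window_start, w.ins_bp) for w in ws] == [(0, 500), (100_000, 0)]

    def test_zero_denominator_windows_omitted(self):
        ws = _whole(window_qv([], {"c": [(0, 50_000), (250_000, 300_000)]}, self.EMPTY))
        assert [w.window_start for w in ws] == [0, 200_000]
        assert all(w.aligned_bp == 50_000 for w in ws)

    def test_per_class_denominators(self):
        el = derive_elements(
            [("c", 0, 40_000)], [("c", 0, 20_000)], [], {"c": 100_000}
        )
        diffs = [DiffRecord("c", 10_000, "snv", 1), DiffRecord("c", 30_000, "snv", 1)]
        ws = window_qv(diffs, {"c": [(0, 100_000)]}, el)
        by_cls = {w.element_class: w for w in ws}
        assert by_cls["exon"].aligned_bp == 20_000 and by_cls["exon"].snv_bp == 1
        assert by_cls["intron"].aligned_bp == 20_000 and by_cls["intron"].snv_bp == 1
        assert by_cls["intergenic"].snv_bp == 0
        assert by_cls["whole"].snv_bp == 2

    def test_order_independence(self):
        diffs = [
            DiffRecord("c", 500, "snv", 1),
            DiffRecord("c", 100, "del", 3),
            DiffRecord("c", 900, "ins", 2),
        ]
        a = window_qv(diffs, {"c": [(0, 100_000)]}, self.EMPTY)
        b = window_qv(list(reversed(diffs)), {"c": [(0, 100_000)]}, self.EMPTY)
        assert a == b

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            window_qv([], {"c": [(0, 10)]}, self.EMPTY, window_bp=0)

    def test_class_partition_of_error_bp(self):
        # errors over disjoint element classes sum to the whole-class totals
        diffs, beds, truth = sim_alignment_diffs(
            {"exon": 200_000, "intron": 200_000, "intergenic": 200_000},
            {
                "exon": {"snv": 1e-4, "ins": 2e-5, "del": 2e-5},
                "intron": {"snv": 3e-4},
                "intergenic": {"snv": 5e-4, "del": 1e-5},
            },
            seed=21,
        )
        length = truth.extras["contig_length"]
        genes = beds["exon"] + beds["intron"]
        el = derive_elements(genes, beds["exon"], [], {"simref": length})
        ws = window_qv(diffs, {"simref": [(0, length)]}, el)
        per_cls = {}
        for w in ws:
            agg = per_cls.setdefault(w.element_class, [0, 0, 0, 0])
            agg[0] += w.snv_bp
            agg[1] += w.ins_bp
            agg[2] += w.del_bp
            agg[3] += w.aligned_bp
        whole = per_cls.pop("whole")
        parts = [per_cls[c] for c in ("exon", "intron", "intergenic")]
        assert [sum(p[i] for p in parts) for i in range(4)] == whole


class TestAggregateQV:
    def test_identical_windows(self):
        ws = _whole(
            window_qv(
                [DiffRecord("c", i * 100_000 + 5, "snv", 1) for i in range(4)],
                {"c": [(0, 400_000)]},
                TestWindowQV.EMPTY,
            )
        )
        s = aggregate_qv(ws)
        assert s.pooled_qv == s.median_qv == s.percentile_cutoff_qv == ws[0].qv_total

    def test_median_exceeds_pooled_mean_with_one_bad_window(self):
        diffs = [DiffRecord("c", 900_000 + i * 100, "snv", 1) for i in range(100)]
        ws = _whole(window_qv(diffs, {"c": [(0, 1_000_000)]}, TestWindowQV.EMPTY))
        assert len(ws) == 10
        s = aggregate_qv(ws)
        assert s.median_qv == 60.0
        assert s.pooled_qv == pytest.approx(40.0)
        assert s.median_qv > s.pooled_qv

    def test_pooled_within_window_bounds(self):
        diffs = [DiffRecord("c", 5, "snv", 1)]
        ws = _whole(window_qv(diffs, {"c": [(0, 300_000)]}, TestWindowQV.EMPTY))
        s = aggregate_qv(ws)
        assert min(w.qv_total for w in ws) <= s.pooled_qv <= max(w.qv_total for w in ws)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_qv([])

    def test_rate_recovery_within_half_qv(self):
        rate = 1e-3
        diffs, beds, truth = sim_alignment_diffs(
            {"whole_genome": 2_000_000},
            {"whole_genome": {"snv": rate}},
            seed=31,
        )
        length = truth.extras["contig_length"]
        el = ElementAnnotation({"simref": length}, {})
        ws = _whole(window_qv(diffs, {"simref": [(0, length)]}, el))
        s = aggregate_qv(ws)
        assert abs(s.pooled_qv - (-10 * math.log10(rate))) <= 0.5


class TestIndelImpact:
    CODING = {
        "geneA": [("c", 1_000, 2_000)],
        "geneB": [("c", 5_000, 6_000), ("c", 7_000, 8_000)],
        "geneC": [("c", 20_000, 21_000)],
    }

    def test_direct_arithmetic(self):
        diffs = [
            DiffRecord("c", 1_100, "ins", 3),
            DiffRecord("c", 1_200, "ins", 120),
            DiffRecord("c", 5_500, "ins", 4_410),
            DiffRecord("c", 7_500, "del", 2),
        ]
        s = indel_impact(diffs, self.CODING)
        assert s.inserted_bp == 4_533 and s.deleted_bp == 2
        assert s.pct_diff_bp_from_large_insertions == pytest.approx(
            100 * 4_530 / 4_535
        )
        assert s.n_genes_with_indel == 2
        assert (s.n_small_insertions, s.n_large_insertions) == (1, 2)

    def test_no_indels(self):
        s = indel_impact([DiffRecord("c", 1_100, "snv", 1)], self.CODING)
        assert s.n_genes_with_indel == 0 and s.pct_genes_with_indel == 0.0

    def test_indel_outside_coding_ignored(self):
        s = indel_impact([DiffRecord("c", 3_000, "ins", 10)], self.CODING)
        assert s.n_insertions == 0

    def test_deletion_span_intersects_gene(self):
        # starts before the gene but its span reaches into it
        s = indel_impact([DiffRecord("c", 990, "del", 20)], self.CODING)
        assert s.n_genes_with_indel == 1 and s.deleted_bp == 20

    def test_no_genes_rejected(self):
        with pytest.raises(ValueError):
            indel_impact([], {})

    def test_gene_fraction_reported_as_percentage(self):
        coding = {f"g{i}": [("c", i * 100, i * 100 + 50)] for i in range(200)}
        diffs = [DiffRecord("c", i * 100 + 10, "ins", 5) for i in range(3)]
        s = indel_impact(diffs, coding)
        assert s.pct_genes_with_indel == pytest.approx(1.5)
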