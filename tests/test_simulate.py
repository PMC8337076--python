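"""Generator determinism, writer/reader contract, truth consistency."""

import math

import numpy as np
import pytest

from asmqc import io
from asmqc.simulate import (
    MarkerGenomeSpec,
    sim_alignment_diffs,
    sim_marker_assemblies,
    sim_reads_and_depth,
    sim_repeat_annotation,
    sim_variant_calls,
)


class TestMarkerAssemblies:
    def test_single_species_no_rearrangement_keeps_ancestral_order(self):
        spec = MarkerGenomeSpec(
            n_species=1, n_arms=1, markers_per_arm=3,
            inversions_per_species=0, contig_markers_mean=100.0, seed=0,
        )
        (table,), truth = sim_marker_assemblies(spec)
        recs = sorted(table.records, key=lambda r: r.start)
        assert [r.marker_id for r in recs] == ["m00_0000", "m00_0001", "m00_0002"]
        assert len({r.contig for r in recs}) == 1

    def test_contigs_never_span_arms_without_translocation(self):
        spec = MarkerGenomeSpec(n_species=5, n_arms=4, markers_per_arm=30, seed=3)
        tables, truth = sim_marker_assemblies(spec)
        for t in tables:
            by_contig = {}
            for r in t.records:
                by_contig.setdefault(r.contig, set()).add(
                    truth.arm_of_marker[r.marker_id]
                )
            assert all(len(arms) == 1 for arms in by_contig.values())

    def test_seeded_determinism(self):
        spec = MarkerGenomeSpec(n_species=2, seed=42, markers_per_arm=10)
        t1, _ = sim_marker_assemblies(spec)
        t2, _ = sim_marker_assemblies(spec)
        assert t1 == t2

    def test_all_markers_present_in_every_species(self):
        spec = MarkerGenomeSpec(n_species=3, n_arms=2, markers_per_arm=15, seed=7,
                                translocation_rate=1.0)
        tables, truth = sim_marker_assemblies(spec)
        universe = set(truth.arm_of_marker)
        for t in tables:
            assert t.marker_ids() == universe

    def test_too_few_markers_rejected(self):
        with pytest.raises(ValueError):
            MarkerGenomeSpec(markers_per_arm=1)

    def test_emitted_tables_pass_reader(self, tmp_path):
        spec = MarkerGenomeSpec(n_species=1, n_arms=2, markers_per_arm=10, seed=1)
        (table,), _ = sim_marker_assemblies(spec)
        p = tmp_path / "t.tsv"
        io.write_busco_table(table, str(p))
        assert io.read_busco_table(str(p), "x").records == table.records


class TestVariantCalls:
    def test_zero_rates_yield_no_variants(self):
        variants, bands, _ = sim_variant_calls(10_000, 0.0, 0.0, seed=1)
        assert variants == []
        assert sum(b.length for b in bands) == 10_000

    def test_binomial_count(self):
        h, n = 1e-3, 1_000_000
        variants, _, truth = sim_variant_calls(n, h, 0.0, seed=2)
        n_het = sum(1 for v in variants if v.genotype == "het")
        assert abs(n_het - h * n) <= 4 * math.sqrt(h * n)
        assert n_het == truth.extras["n_het"]

    def test_deterministic(self):
        a = sim_variant_calls(5_000, 1e-3, 1e-4, seed=3)
        b = sim_variant_calls(5_000, 1e-3, 1e-4, seed=3)
        assert a[0] == b[0] and a[1] == b[1]

    def test_partition_of_sites(self):
        variants, bands, truth = sim_variant_calls(
            20_000, 1e-3, 1e-3, seed=4, contamination=1e-3
        )
        n_var_sites = len({v.pos for v in variants})
        assert n_var_sites + sum(b.length for b in bands) == 20_000

    def test_vcf_writer_reader_contract(self, tmp_path):
        variants, bands, _ = sim_variant_calls(2_000, 5e-3, 1e-3, seed=5)
        p = tmp_path / "c.vcf"
        io.write_vcf(variants, bands, {"sim1": 2_000}, str(p))
        v2, b2 = io.read_vcf_with_bands(str(p))
        assert len(v2) == len(variants) and len(b2) == len(bands)
        assert sum(b.length for b in b2) == sum(b.length for b in bands)


class TestAlignmentDiffs:
    def test_zero_rates_yield_no_diffs(self):
        diffs, beds, _ = sim_alignment_diffs(
            {"exon": 50_000}, {"exon": {"snv": 0.0}}, seed=1
        )
        assert diffs == []

    def test_poisson_count(self):
        diffs, _, _ = sim_alignment_diffs(
            {"g": 1_000_000}, {"g": {"snv": 1e-4}}, seed=2
        )
        assert abs(len(diffs) - 100) <= 4 * math.sqrt(100)

    def test_diffs_respect_class_intervals(self):
        diffs, beds, _ = sim_alignment_diffs(
            {"exon": 100_000, "intron": 100_000},
            {"exon": {"snv": 1e-3, "del": 1e-4}, "intron": {"ins": 1e-4}},
            seed=3,
        )
        from asmqc._intervals import contains_point, merge

        exon = merge([(s, e) for _, s, e in beds["exon"]])
        intron = merge([(s, e) for _, s, e in beds["intron"]])
        for d in diffs:
            home = exon if d.kind in ("snv", "del") else intron
            assert contains_point(home, d.ref_start)
            if d.kind == "del":  # deletions fully inside their class
                assert contains_point(home, d.ref_start + d.length - 1)

    def test_paf_writer_reader_contract(self, tmp_path):
        diffs, beds, truth = sim_alignment_diffs(
            {"g": 100_000}, {"g": {"snv": 1e-3, "ins": 1e-4, "del": 1e-4}}, seed=4
        )
        length = truth.extras["contig_length"]
        p = tmp_path / "a.paf"
        io.write_paf_cs(diffs, {"simref": [(0, length)]}, {"simref": length}, str(p))
        d2, aligned, lens = io.read_paf_cs(str(p))
        assert [(d.kind, d.ref_start, d.length) for d in d2] == [
            (d.kind, d.ref_start, d.length) for d in diffs
        ]
        assert lens == {"simref": length}


class TestReadsAndDepth:
    def test_uniform_mode_exact(self):
        _, track, _ = sim_reads_and_depth(
            100_000, 50.0, seed=1, depth_mode="uniform", n_track_positions=1_000
        )
        assert (track.depths("simdepth") == 50).all()

    def test_total_bases_within_2pct(self):
        lengths, _, truth = sim_reads_and_depth(10_000_000, 25.0, seed=2)
        assert abs(lengths.sum() - 250e6) / 250e6 < 0.02
        assert truth.total_read_bases == int(lengths.sum())

    def test_realized_n50_within_10pct_of_target(self):
        for target in (20_000, 30_000):
            _, _, truth = sim_reads_and_depth(
                5_000_000, 20.0, length_n50_target=target, seed=3
            )
            assert abs(truth.read_n50_bp - target) / target < 0.10

    def test_deterministic(self):
        a, _, _ = sim_reads_and_depth(1_000_000, 10.0, seed=4)
        b, _, _ = sim_reads_and_depth(1_000_000, 10.0, seed=4)
        assert (a == b).all()

    def test_depth_tsv_contract(self, tmp_path):
        _, track, _ = sim_reads_and_depth(500_000, 15.0, seed=5,
                                          n_track_positions=2_000)
        p = tmp_path / "d.tsv"
        io.write_depth_tsv(track, str(p))
        back = io.read_depth_tsv(str(p))
        assert (back.depths("simdepth") == track.depths("simdepth")).all()


class TestRepeatAnnotation:
    def test_zero_proportions_empty(self):
        assert sim_repeat_annotation({"c": 10_000}, {}, seed=1) == []

    def test_proportions_within_band(self):
        records = sim_repeat_annotation({"c": 1_000_000}, {"LTR": 0.2}, seed=2)
        ltr_bp = sum(r.end - r.start for r in records if r.repeat_class == "LTR")
        assert 190_000 <= ltr_bp <= 210_000

    def test_intervals_within_bounds_and_disjoint(self):
        records = sim_repeat_annotation(
            {"c": 100_000}, {"LTR": 0.3, "LINE": 0.2, "DNA": 0.1}, seed=3
        )
        prev_end = 0
        for r in sorted(records, key=lambda r: r.start):
            assert 0 <= r.start < r.end <= 100_000
            assert r.start >= prev_end
            prev_end = r.end

    def test_rm_out_contract(self, tmp_path):
        records = sim_repeat_annotation({"c": 50_000}, {"LTR": 0.1}, seed=4)
        p = tmp_path / "rm.out"
        io.write_repeatmasker_out(records, str(p))
        assert io.read_repeatmasker_out(str(p)) == records
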