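"""Simulator: architecture construction, truth consistency, read generation."""

import dataclasses

import numpy as np
import pytest

import taltfinder as tf
from taltfinder.core import revcomp
from taltfinder.simulate import _build_chassis
from tests.conftest import SMALL


def template_segments(truth, contig):
    return [s for s in truth.segments[contig] if s.label.startswith("template")]


class TestGenomeConstruction:
    def test_pre_alt_has_two_template_copies_per_haplotype(self, small_pre):
        genome, truth = small_pre
        assert truth.copy_number == 2.0
        for contig in truth.segments:
            n = len(template_segments(truth, contig))
            assert n == (1 if contig.startswith(("chr1", "chr2")) else 0)

    def test_alt_copy_number_matches_segment_count(self, small_config, small_alt):
        _, truth = small_alt
        expected = 1 + 2 * small_config.alt_copies_per_end
        assert truth.copy_number == expected
        assert truth.recomputed_copy_number() == truth.copy_number

    def test_segments_tile_contigs_without_gaps(self, small_alt, small_pre):
        for genome, truth in (small_alt, small_pre):
            lengths = {c.name: len(c) for c in genome}
            for name, segs in truth.segments.items():
                pos = 0
                for s in segs:
                    assert s.start == pos
                    assert s.end > s.start
                    pos = s.end
                assert pos == lengths[name]

    def test_zero_markers_makes_paralogs_identical(self):
        cfg = tf.SimConfig(seed=5, paralog_marker_count=0, **SMALL)
        chassis = _build_chassis(cfg)
        assert chassis.template_a == chassis.template_b
        assert chassis.markers == []

    def test_marker_positions_unique_and_away_from_edges(self, small_config):
        chassis = _build_chassis(small_config)
        positions = [p for p, _, _ in chassis.markers]
        assert len(positions) == len(set(positions)) == small_config.paralog_marker_count
        margin = small_config.marker_edge_margin
        assert all(margin <= p < small_config.template_length - margin for p in positions)
        for p, a, b in chassis.markers:
            assert chassis.template_a[p] == a
            assert chassis.template_b[p] == b
            assert a != b

    def test_selected_paralog_b_fills_end_arrays(self, small_alt):
        _, truth = small_alt
        array_segs = template_segments(truth, "chr2_h1")
        assert len(array_segs) == 16
        assert all(s.label == "template_B" for s in array_segs)

    def test_selected_paralog_a_variant(self):
        cfg = tf.SimConfig(seed=1, selected_paralog="A", **SMALL)
        _, truth = tf.build_alt_genome(cfg)
        assert all(s.label == "template_A" for s in template_segments(truth, "chr2_h1"))
        assert truth.selected_paralog == "A"

    def test_orientation_flag_flips_truth(self):
        fwd = tf.SimConfig(seed=1, **SMALL)
        rev = dataclasses.replace(fwd, array_orientation="reverse")
        _, t_fwd = tf.build_alt_genome(fwd)
        _, t_rev = tf.build_alt_genome(rev)
        assert t_fwd.expected_orientation == "FORWARD"
        assert t_rev.expected_orientation == "REVERSE"

    def test_genome_is_deterministic(self, small_config, small_alt):
        genome, _ = small_alt
        again, _ = tf.build_alt_genome(small_config)
        assert [c.sequence for c in genome] == [c.sequence for c in again]

    def test_reference_contains_single_template_locus(self, small_config, small_reference):
        chassis = _build_chassis(small_config)
        ref = {c.name: c.sequence for c in small_reference}
        assert ref["chr1"].count(chassis.template_a) == 1
        assert chassis.template_b not in ref["chr2"]
        assert revcomp(chassis.template_b) not in ref["chr2"]

    def test_invalid_config_raises(self):
        with pytest.raises(tf.ConfigurationError):
            tf.SimConfig(seed=1, template_length=100).validate()
        with pytest.raises(tf.ConfigurationError):
            tf.SimConfig(seed=1, selected_paralog="C").validate()
        with pytest.raises(tf.ConfigurationError):
            tf.SimConfig(seed=1, substitution_error_rate=1.5).validate()


class TestTruthAnnotations:
    def test_junction_and_orientation_expectations(self, small_pre, small_alt):
        _, pre = small_pre
        _, alt = small_alt
        assert pre.expected_junction_class is None
        assert alt.expected_junction_class == "HEAD_TO_TAIL"
        assert pre.expected_orientation is None

    def test_per_end_telomere_bases(self, small_config, small_pre):
        _, truth = small_pre
        unit = len(small_config.telomere_unit)
        tract = round(small_config.pre_alt_telomere_length / unit) * unit
        assert truth.per_end_telomere_bases["chr1_h1:L"] == tract
        # the subterminal paralog end also carries its joining spacer
        spacer = small_config.spacer_units_between_copies * unit
        assert truth.per_end_telomere_bases["chr2_h1:R"] == tract + spacer
        assert truth.n_ends == 8

    def test_reference_locus_annotation_matches_sequence(self, small_config, small_reference):
        chassis = _build_chassis(small_config)
        _, truth = tf.build_pre_alt_genome(small_config)
        chr1 = next(c for c in small_reference if c.name == "chr1")
        iv = truth.template_locus_ref
        assert chr1.sequence[iv.start : iv.end] == chassis.template_a
        assert len(truth.control_locus_ref) == len(iv)
        for contig, pos, ref_allele, _alt in truth.marker_sites_ref:
            assert contig == "chr1"
            assert chr1.sequence[pos] == ref_allele


class TestReadSimulation:
    def test_pair_count_arithmetic(self):
        cfg = tf.SimConfig(seed=2, coverage=30, read_length=150, **{k: v for k, v in SMALL.items() if k != "coverage"})
        genome = [tf.Contig("c1", "ACGT" * 250_000)]  # 1 Mb
        pairs = tf.simulate_reads(genome, cfg)
        assert len(pairs) == 100_000

    def test_error_free_reads_are_substrings(self):
        cfg = tf.SimConfig(seed=3, substitution_error_rate=0.0, coverage=3.0,
                           **{k: v for k, v in SMALL.items() if k != "coverage"})
        genome, _ = tf.build_alt_genome(cfg)
        seqs = {c.name: c.sequence for c in genome}
        for p in tf.simulate_reads(genome, cfg)[:300]:
            contig = p.id.split(":")[1]
            hay = seqs[contig]
            assert p.mate1_seq in hay
            assert revcomp(p.mate2_seq) in hay

    def test_reads_are_deterministic(self, small_config, small_alt, small_alt_reads):
        genome, _ = small_alt
        again = tf.simulate_reads(genome, small_config)
        sample = slice(0, 2000)
        assert [(p.id, p.mate1_seq, p.mate2_seq) for p in small_alt_reads[sample]] == [
            (p.id, p.mate1_seq, p.mate2_seq) for p in again[sample]
        ]

    def test_realised_depth_near_configured_coverage(self, small_alt_reads, small_config):
        # 10 kb interstitial window on chr1_h1; fragment coordinates are in ids
        lo, hi = 30_000, 40_000
        rl = small_config.read_length
        covered = 0
        for p in small_alt_reads:
            _, contig, span = p.id.split(":")
            if contig != "chr1_h1":
                continue
            s, e = map(int, span.split("-"))
            for rs, re_ in ((s, s + rl), (e - rl, e)):
                covered += max(0, min(re_, hi) - max(rs, lo))
        depth = covered / (hi - lo)
        assert abs(depth - small_config.coverage) / small_config.coverage < 0.10

    def test_fastq_roundtrip(self, tmp_path, small_config):
        from taltfinder.seqio import read_fastq_pair, write_fastq_pair

        cfg = dataclasses.replace(small_config, coverage=0.5)
        genome, _ = tf.build_pre_alt_genome(cfg)
        pairs = tf.simulate_reads(genome, cfg)
        r1, r2 = tmp_path / "r_1.fq", tmp_path / "r_2.fq"
        write_fastq_pair(pairs, str(r1), str(r2))
        back = list(read_fastq_pair(str(r1), str(r2)))
        assert [(p.id, p.mate1_seq, p.mate2_seq) for p in pairs] == [
            (p.id, p.mate1_seq, p.mate2_seq) for p in back
        ]
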