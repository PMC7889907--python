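"""Seed index, unique-best mapping, region calling, orientation."""

import numpy as np
import pytest

import taltfinder as tf
from taltfinder.anchors import (
    AnchorHit,
    CandidateTemplateRegion,
    RegionOrientation,
    _seed_offsets,
)
from taltfinder.core import random_dna, revcomp
from taltfinder.telreads import MateType


@pytest.fixture(scope="module")
def ref2kb():
    rng = np.random.default_rng(77)
    return [tf.Contig("ref", random_dna(rng, 2000))]


@pytest.fixture(scope="module")
def idx2kb(ref2kb):
    return tf.build_seed_index(ref2kb, k=15)


class TestSeedIndex:
    def test_position_count_is_length_minus_k_plus_one(self):
        rng = np.random.default_rng(1)
        idx = tf.build_seed_index([tf.Contig("c", random_dna(rng, 100))], k=15)
        assert idx.n_positions == 86

    def test_all_n_contig_contributes_nothing(self):
        rng = np.random.default_rng(2)
        contigs = [tf.Contig("n", "N" * 100), tf.Contig("c", random_dna(rng, 50))]
        idx = tf.build_seed_index(contigs, k=15)
        assert idx.n_positions == 36
        assert idx.mappable_length == 50

    def test_indexed_positions_regenerate_their_kmer(self, idx2kb, ref2kb):
        seq = ref2kb[0].sequence
        for packed in idx2kb.packed[::101]:
            gpos = int(packed) >> 1
            assert idx2kb.kmer_at(gpos) == seq[gpos : gpos + 15]

    def test_k_larger_than_contigs_rejected(self):
        with pytest.raises(ValueError):
            tf.build_seed_index([tf.Contig("c", "ACGTACGT")], k=15)

    def test_interval_kmers_cover_the_locus(self, idx2kb):
        kmers = idx2kb.interval_kmers([tf.GenomicInterval("ref", 500, 700)])
        assert len(kmers) == 200 - 15 + 1


class TestMapRead:
    def test_exact_read_maps_forward(self, ref2kb, idx2kb):
        read = ref2kb[0].sequence[1000:1100]
        hit = tf.map_read(read, idx2kb)
        assert (hit.contig, hit.start, hit.end, hit.strand) == ("ref", 1000, 1100, "+")
        assert hit.n_mismatch == 0 and hit.score == 100

    def test_reverse_complement_maps_same_interval_minus(self, ref2kb, idx2kb):
        read = revcomp(ref2kb[0].sequence[1000:1100])
        hit = tf.map_read(read, idx2kb)
        assert (hit.start, hit.end, hit.strand) == (1000, 1100, "-")

    def test_rc_symmetry_on_error_bearing_reads(self, ref2kb, idx2kb, rng):
        seq = ref2kb[0].sequence
        for _ in range(50):
            s = int(rng.integers(0, 1900))
            read = list(seq[s : s + 100])
            p = int(rng.integers(0, 100))
            read[p] = "ACGT"[(("ACGT".index(read[p])) + 1) % 4]
            read = "".join(read)
            fwd = tf.map_read(read, idx2kb)
            rev = tf.map_read(revcomp(read), idx2kb)
            assert fwd is not None
            assert (fwd.contig, fwd.start, fwd.end) == (rev.contig, rev.start, rev.end)
            assert {fwd.strand, rev.strand} == {"+", "-"}

    def test_duplicated_sequence_is_ambiguous(self, rng):
        block = random_dna(rng, 300)
        ref = [tf.Contig("dup", random_dna(rng, 500) + block + random_dna(rng, 400) + block)]
        idx = tf.build_seed_index(ref, k=15)
        read = block[100:200]
        assert tf.map_read(read, idx) is None  # tie -> discarded
        hit = tf.map_read(read, idx, mode="random", rng=np.random.default_rng(0))
        assert hit is not None and hit.start in (600, 1300)

    def test_excessive_divergence_rejected(self, ref2kb, idx2kb):
        read = list(ref2kb[0].sequence[500:600])
        for p in range(0, 30, 4):  # 8 substitutions > 5% of 100
            read[p] = "ACGT"[("ACGT".index(read[p]) + 1) % 4]
        assert tf.map_read("".join(read), idx2kb) is None

    def test_seed_offsets_tile_and_include_tail(self):
        assert _seed_offsets(100, 15) == [0, 15, 30, 45, 60, 75, 85]
        assert _seed_offsets(30, 15) == [0, 15]

    def test_agreement_with_exhaustive_alignment_oracle(self, ref2kb, idx2kb, rng):
        """map_read must equal a brute-force full-scan best-alignment search."""
        from taltfinder.core import encode

        seq = ref2kb[0].sequence
        ref_enc = encode(seq)
        windows = np.lib.stride_tricks.sliding_window_view(ref_enc, 100)

        def oracle(read):
            r = encode(read)
            rc = encode(revcomp(read))
            mm_f = (windows != r).sum(axis=1)
            mm_r = (windows != rc).sum(axis=1)
            mm_all = np.concatenate([mm_f, mm_r])
            best = int(mm_all.min())
            if best > 5 or (mm_all == best).sum() > 1:
                return None
            i = int(mm_all.argmin())
            if i < len(mm_f):
                return (i, i + 100, "+", best)
            i -= len(mm_f)
            return (i, i + 100, "-", best)

        n_checked = 0
        for _ in range(200):
            s = int(rng.integers(0, 1900))
            read = list(seq[s : s + 100])
            for p in rng.choice(100, size=int(rng.integers(1, 4)), replace=False):
                read[p] = "ACGT"[("ACGT".index(read[p]) + 1) % 4]
            read = "".join(read)
            if rng.random() < 0.5:
                read = revcomp(read)
            expected = oracle(read)
            hit = tf.map_read(read, idx2kb)
            if expected is None:
                assert hit is None
            else:
                assert (hit.start, hit.end, hit.strand, hit.n_mismatch) == expected
                n_checked += 1
        assert n_checked > 150  # nearly all reads should place


def uniform_hits(rng, n, length, window_hot=None, hot_count=0):
    hits = []
    starts = rng.integers(0, length - 150, size=n - hot_count)
    for i, s in enumerate(starts):
        hits.append(AnchorHit(f"r{i}", "ref", int(s), int(s) + 150, "+", 150, 0))
    if window_hot is not None:
        for j in range(hot_count):
            s = window_hot + (j * 17) % 800
            hits.append(AnchorHit(f"h{j}", "ref", s, s + 150, "+", 150, 0))
    return hits


@pytest.fixture(scope="module")
def idx500kb():
    rng = np.random.default_rng(9)
    return tf.build_seed_index([tf.Contig("ref", random_dna(rng, 500_000))], k=15)


class TestRegionCalling:
    def test_no_hits_no_regions(self, idx500kb):
        assert tf.collect_candidate_regions([], idx500kb) == []

    def test_concentrated_anchors_form_a_region(self, idx500kb, rng):
        hits = uniform_hits(rng, 60, 500_000, window_hot=250_000, hot_count=50)
        regions = tf.collect_candidate_regions(hits, idx500kb, window=1000, alpha=0.01)
        assert len(regions) >= 1
        top = regions[0]
        assert top.start <= 250_000 < top.end
        assert top.anchor_count >= 50
        assert top.enrichment_p < 0.01
        assert top.anchor_count == sum(top.counts.values())

    def test_uniform_scatter_rarely_calls_regions(self, idx500kb, rng):
        false_calls = 0
        for _ in range(20):
            hits = uniform_hits(rng, 60, 500_000)
            false_calls += bool(tf.collect_candidate_regions(hits, idx500kb))
        assert false_calls <= 1


def region_with_hits(g3=0, g5=0, c3=0, c5=0):
    region = CandidateTemplateRegion("ref", 10_000, 18_000, 0)
    hits = []
    i = 0
    for count, partner, side in ((g3, MateType.G, "3"), (g5, MateType.G, "5"),
                                 (c3, MateType.C, "3"), (c5, MateType.C, "5")):
        for _ in range(count):
            start = 10_050 + (i % 40) * 10 if side == "5" else 17_400 + (i % 40) * 10
            hits.append(AnchorHit(f"x{i}", "ref", start, start + 150, "+", 150, 0, partner))
            i += 1
    return region, hits


class TestOrientation:
    def test_g_at_3prime_c_at_5prime_is_forward(self):
        region, hits = region_with_hits(g3=30, c5=25)
        assert tf.call_orientation(region, hits) is RegionOrientation.FORWARD

    def test_mirror_arrangement_is_reverse(self):
        region, hits = region_with_hits(g5=30, c3=25)
        assert tf.call_orientation(region, hits) is RegionOrientation.REVERSE

    def test_even_split_is_inconsistent(self):
        region, hits = region_with_hits(g3=10, g5=10, c3=10, c5=10)
        assert tf.call_orientation(region, hits) is RegionOrientation.INCONSISTENT

    def test_sparse_evidence_is_nocall(self):
        region, hits = region_with_hits(g3=5, c5=4)
        assert tf.call_orientation(region, hits) is RegionOrientation.NOCALL

    def test_simulated_post_alt_orientation_matches_truth(
        self, small_alt_classified, small_index, small_alt
    ):
        _, truth = small_alt
        hits = tf.map_anchorable_mates(small_alt_classified, small_index)
        regions = tf.collect_candidate_regions(hits, small_index)
        top = regions[0]
        assert top.interval.jaccard(truth.template_locus_ref) >= 0.5
        assert tf.call_orientation(top, hits).value == truth.expected_orientation
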