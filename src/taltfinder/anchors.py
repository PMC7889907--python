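"""Anchor mapping of non-telomeric mates and candidate-region discovery.

The aligner is deliberately minimal: a canonical k-mer index over the
reference, ungapped extension of every seeded locus across the full read, and
a *unique-best* acceptance rule — a read is placed only when one locus scores
strictly better than every other and its mismatch count stays below
``max_mismatch_frac`` of the read length.  Ambiguity discards the read, which
keeps anchor evidence free of paralog cross-talk.  For depth estimation the
same machinery can instead break ties uniformly at random (``mode="random"``),
mirroring how standard aligners place multi-mappers.

Candidate template regions are 1 kb windows whose anchor counts beat a
Bonferroni-corrected Poisson upper tail under a uniform-scatter null; adjacent
significant windows merge.  Orientation of a region is called from the strand
type (G/C) of the telomeric partners of anchors near its two boundaries:
G-partners concentrated at the 3' end together with C-partners at the 5' end
is FORWARD, the mirror image REVERSE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .core import ENCODE_LUT as ENCODE_LUT_VIEW
from .core import Contig, DataError, GenomicInterval, encode
from .telreads import MateType, PairCategory, ReadPair, TelomereClassification


@dataclass(frozen=True)
class AnchorHit:
    """Unique-best ungapped placement of a read on the reference."""

    read_id: str | None
    contig: str
    start: int
    end: int
    strand: str  # '+' or '-'
    score: int  # matches - mismatch_penalty * mismatches
    n_mismatch: int
    partner_type: MateType = MateType.NONE


class SeedIndex:
    """Canonical k-mer index over a set of contigs.

    Positions whose window touches an N are excluded.  Internally the contigs
    are concatenated; ``kmers`` is the sorted array of canonical k-mer codes
    and ``packed`` the aligned ``(global_position << 1) | forward_is_canonical``
    values.
    """

    def __init__(self, reference: Sequence[Contig], k: int = 15):
        if k < 8:
            raise ValueError("k must be >= 8")
        if not reference:
            raise ValueError("reference must be non-empty")
        if all(len(c) <= k for c in reference):
            raise ValueError("k exceeds the length of every contig")
        self.k = k
        self.contig_names = [c.name for c in reference]
        self.contig_lengths = np.array([len(c) for c in reference], dtype=np.int64)
        self.offsets = np.concatenate([[0], np.cumsum(self.contig_lengths)])
        self.ref = np.concatenate([encode(c.sequence) for c in reference])
        self.mappable_length = int(np.count_nonzero(self.ref != 4))

        all_kmers: list[np.ndarray] = []
        all_packed: list[np.ndarray] = []
        for ci, contig in enumerate(reference):
            enc = self.ref[self.offsets[ci] : self.offsets[ci + 1]]
            if len(enc) < k:
                continue
            fwd, rev, valid = _kmer_codes(enc, k)
            pos = np.nonzero(valid)[0].astype(np.int64)
            if len(pos) == 0:
                continue
            f, r = fwd[pos], rev[pos]
            canonical = np.minimum(f, r)
            fwd_bit = (f <= r).astype(np.int64)
            gpos = pos + self.offsets[ci]
            all_kmers.append(canonical)
            all_packed.append((gpos << 1) | fwd_bit)
        if all_kmers:
            kmers = np.concatenate(all_kmers)
            packed = np.concatenate(all_packed)
            order = np.argsort(kmers, kind="stable")
            self.kmers = kmers[order]
            self.packed = packed[order]
        else:
            self.kmers = np.empty(0, dtype=np.int64)
            self.packed = np.empty(0, dtype=np.int64)

    @property
    def n_positions(self) -> int:
        return len(self.kmers)

    def lookup(self, canonical_kmer: int) -> np.ndarray:
        """Packed positions of one canonical k-mer (empty if absent)."""
        i0 = np.searchsorted(self.kmers, canonical_kmer, side="left")
        i1 = np.searchsorted(self.kmers, canonical_kmer, side="right")
        return self.packed[i0:i1]

    def contig_of(self, gpos: int) -> int:
        return int(np.searchsorted(self.offsets, gpos, side="right") - 1)

    def kmer_at(self, gpos: int) -> str:
        """Regenerate the forward-strand k-mer at a global position."""
        from .core import decode

        return decode(self.ref[gpos : gpos + self.k])

    def interval_kmers(self, intervals: Iterable[GenomicInterval], margin: int = 0) -> set[int]:
        """Canonical k-mer codes occurring within the given reference intervals
        (grown by ``margin``); used as a cheap read prefilter."""
        out: set[int] = set()
        for iv in intervals:
            ci = self.contig_names.index(iv.contig)
            lo = max(0, iv.start - margin)
            hi = min(int(self.contig_lengths[ci]), iv.end + margin)
            enc = self.ref[self.offsets[ci] + lo : self.offsets[ci] + hi]
            if len(enc) < self.k:
                continue
            fwd, rev, valid = _kmer_codes(enc, self.k)
            out.update(np.minimum(fwd, rev)[valid].tolist())
        return out


def _kmer_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward and reverse-complement k-mer codes at every start of ``enc``,
    plus a validity mask (False where the window contains a non-ACGT code)."""
    n = len(enc) - k + 1
    base = enc.astype(np.int64)
    fwd = np.zeros(n, dtype=np.int64)
    rev = np.zeros(n, dtype=np.int64)
    for j in range(k):
        fwd = (fwd << 2) | (base[j : j + n] & 3)
        rev |= ((3 - base[j : j + n]) & 3) << (2 * j)
    bad = (enc == 4).astype(np.int64)
    cs = np.concatenate([[0], np.cumsum(bad)])
    valid = (cs[k:] - cs[:-k]) == 0
    return fwd, rev, valid


def build_seed_index(reference: Sequence[Contig], k: int = 15) -> SeedIndex:
    return SeedIndex(reference, k)


def _seed_offsets(L: int, k: int) -> list[int]:
    """Non-overlapping seed start offsets tiling the read, plus one flush with
    the read end, so < L // k substitutions always leave an intact seed."""
    offsets = list(range(0, L - k + 1, k))
    if offsets[-1] != L - k:
        offsets.append(L - k)
    return offsets


def _map_batch(
    seqs: Sequence[str],
    index: SeedIndex,
    max_mismatch_frac: float = 0.05,
    mismatch_penalty: int = 1,
    max_occurrences: int = 64,
    mode: str = "unique",
    rng: np.random.Generator | None = None,
    kmer_filter: set[int] | None = None,
) -> list[AnchorHit | None]:
    """Vectorised core shared by every mapping entry point.

    Seed k-mer codes and index lookups are computed for all equal-length reads
    at once; per-read work is limited to candidate enumeration and ungapped
    scoring.  Returns one entry per input read (None = unmapped / filtered).
    """
    if mode == "random" and rng is None:
        raise ValueError("mode='random' requires an rng")
    k = index.k
    results: list[AnchorHit | None] = [None] * len(seqs)
    ref = index.ref
    ref_len = len(ref)
    offsets_arr = index.offsets

    # group reads by length so each group forms a rectangular matrix
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        if len(s) >= k:
            by_len.setdefault(len(s), []).append(i)

    filter_arr = (
        np.fromiter(kmer_filter, dtype=np.int64, count=len(kmer_filter))
        if kmer_filter
        else None
    )
    if filter_arr is not None:
        filter_arr.sort()

    for L, idxs in by_len.items():
        seed_offs = _seed_offsets(L, k)
        S = len(seed_offs)
        mat = np.frombuffer(
            b"".join(seqs[i].encode() for i in idxs), dtype=np.uint8
        ).reshape(len(idxs), L)
        mat = ENCODE_LUT_VIEW[mat]
        n = len(idxs)
        fwd = np.zeros((n, S), dtype=np.int64)
        rev = np.zeros((n, S), dtype=np.int64)
        bad = np.cumsum(mat == 4, axis=1, dtype=np.int32)
        valid = np.empty((n, S), dtype=bool)
        for si, o in enumerate(seed_offs):
            f = np.zeros(n, dtype=np.int64)
            r = np.zeros(n, dtype=np.int64)
            for j in range(k):
                col = mat[:, o + j].astype(np.int64)
                f = (f << 2) | (col & 3)
                r |= ((3 - col) & 3) << (2 * j)
            fwd[:, si] = f
            rev[:, si] = r
            prev = bad[:, o - 1] if o > 0 else 0
            valid[:, si] = (bad[:, o + k - 1] - prev) == 0
        canonical = np.minimum(fwd, rev)
        read_fwd_canon = fwd <= rev

        keep = np.ones(n, dtype=bool)
        if filter_arr is not None:
            pos = np.searchsorted(filter_arr, canonical)
            pos = np.minimum(pos, len(filter_arr) - 1)
            present = (filter_arr[pos] == canonical) & valid
            keep = present.any(axis=1)

        i0 = np.searchsorted(index.kmers, canonical)
        i1 = np.searchsorted(index.kmers, canonical, side="right")
        max_mm = math.floor(max_mismatch_frac * L)
        packed = index.packed

        for row in np.nonzero(keep)[0]:
            candidates: set[tuple[int, bool]] = set()
            for si, o in enumerate(seed_offs):
                if not valid[row, si]:
                    continue
                lo, hi = int(i0[row, si]), int(i1[row, si])
                cnt = hi - lo
                if cnt == 0 or cnt > max_occurrences:
                    continue
                hits_packed = packed[lo:hi]
                gpos = hits_packed >> 1
                same = (hits_packed & 1).astype(bool) == bool(read_fwd_canon[row, si])
                for g, s in zip(gpos.tolist(), same.tolist()):
                    start = g - o if s else g - (L - k - o)
                    candidates.add((start, s))
            if not candidates:
                continue

            enc = mat[row]
            rc_enc = None
            best: list[tuple[int, bool, int]] = []
            best_score: int | None = None
            for start, is_fwd in candidates:
                if start < 0 or start + L > ref_len:
                    continue
                ci = int(np.searchsorted(offsets_arr, start, side="right") - 1)
                if start < offsets_arr[ci] or start + L > offsets_arr[ci + 1]:
                    continue  # would span a contig boundary / run off the end
                if is_fwd:
                    query = enc
                else:
                    if rc_enc is None:
                        rc_enc = np.where(enc == 4, 4, 3 - enc)[::-1].astype(np.uint8)
                    query = rc_enc
                mm = int(np.count_nonzero(ref[start : start + L] != query))
                score = (L - mm) - mismatch_penalty * mm
                if best_score is None or score > best_score:
                    best_score = score
                    best = [(start, is_fwd, mm)]
                elif score == best_score:
                    best.append((start, is_fwd, mm))
            if not best:
                continue
            if len(best) > 1:
                if mode != "random":
                    continue
                best = [best[int(rng.integers(len(best)))]]
            start, is_fwd, mm = best[0]
            if mm > max_mm:
                continue
            ci = int(np.searchsorted(offsets_arr, start, side="right") - 1)
            local = start - int(offsets_arr[ci])
            results[idxs[row]] = AnchorHit(
                read_id=None,
                contig=index.contig_names[ci],
                start=local,
                end=local + L,
                strand="+" if is_fwd else "-",
                score=(L - mm) - mismatch_penalty * mm,
                n_mismatch=mm,
            )
    return results


def map_read(
    seq: str,
    index: SeedIndex,
    max_mismatch_frac: float = 0.05,
    mismatch_penalty: int = 1,
    max_occurrences: int = 64,
    mode: str = "unique",
    rng: np.random.Generator | None = None,
) -> AnchorHit | None:
    """Place one read; ``None`` when unseeded, too diverged, or ambiguous.

    Seeds are non-overlapping k-mers tiling the read (plus one flush with the
    read end), each seeded locus is scored by ungapped extension over the full
    read, and the best locus is reported only when it is strictly better than
    every other (``mode="unique"``); ``mode="random"`` resolves ties uniformly
    with ``rng`` instead, mirroring multi-mapper placement.  Seeds occurring
    more than ``max_occurrences`` times are skipped as uninformative.
    """
    return _map_batch(
        [seq],
        index,
        max_mismatch_frac=max_mismatch_frac,
        mismatch_penalty=mismatch_penalty,
        max_occurrences=max_occurrences,
        mode=mode,
        rng=rng,
    )[0]


def map_anchorable_mates(
    classified: Iterable[tuple[ReadPair, TelomereClassification]],
    index: SeedIndex,
    max_mismatch_frac: float = 0.05,
) -> list[AnchorHit]:
    """Map the non-telomeric mate of every SINGLE pair (unique-best mode),
    tagging each hit with the telomeric partner's strand type."""
    singles = [
        (pair, cls)
        for pair, cls in classified
        if cls.category is PairCategory.SINGLE
    ]
    seqs = [
        p.mate1_seq if c.anchorable_mate == 1 else p.mate2_seq for p, c in singles
    ]
    mapped = _map_batch(seqs, index, max_mismatch_frac=max_mismatch_frac)
    return [
        replace(hit, read_id=pair.id, partner_type=cls.partner_type)
        for (pair, cls), hit in zip(singles, mapped)
        if hit is not None
    ]


def map_reads_for_depth(
    reads: Sequence[tuple[str, str]],
    index: SeedIndex,
    rng: np.random.Generator,
    max_mismatch_frac: float = 0.05,
    kmer_filter: set[int] | None = None,
) -> list[AnchorHit]:
    """Map (id, sequence) pairs with random tie-breaking, for coverage tracks.

    ``kmer_filter`` restricts work to reads sharing at least one seed k-mer
    with a set of reference intervals (see ``SeedIndex.interval_kmers``) —
    useful when only the depth of specific loci is needed.
    """
    reads = list(reads)
    mapped = _map_batch(
        [s for _, s in reads],
        index,
        max_mismatch_frac=max_mismatch_frac,
        mode="random",
        rng=rng,
        kmer_filter=kmer_filter,
    )
    return [
        replace(hit, read_id=read_id)
        for (read_id, _), hit in zip(reads, mapped)
        if hit is not None
    ]


# --------------------------------------------------------------------------
# candidate regions and orientation


class RegionOrientation(str, Enum):
    FORWARD = "FORWARD"
    REVERSE = "REVERSE"
    INCONSISTENT = "INCONSISTENT"
    NOCALL = "NOCALL"


@dataclass
class CandidateTemplateRegion:
    """A window run whose anchor count is unexplainable by uniform scatter."""

    contig: str
    start: int
    end: int
    anchor_count: int
    counts: dict[str, int] = field(default_factory=dict)  # e.g. {"5prime_G": 3, ...}
    enrichment_p: float = 1.0
    orientation: RegionOrientation = RegionOrientation.NOCALL

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.contig, self.start, self.end)


def collect_candidate_regions(
    hits: Sequence[AnchorHit],
    index: SeedIndex,
    window: int = 1000,
    alpha: float = 0.01,
    merge_gap_windows: int = 10,
) -> list[CandidateTemplateRegion]:
    """Poisson-enriched windows of anchor starts, merged into regions.

    With N anchors over mappable length L, a window of width w is significant
    when P(Poisson(N*w/L) >= count) < alpha / n_windows (Bonferroni).
    Significant windows separated by at most ``merge_gap_windows`` quiet
    windows merge into one region: anchor evidence is junction-borne and
    therefore concentrates at the boundaries of a template locus, leaving its
    interior windows sparse even when the locus itself is massively amplified.
    """
    if not hits:
        return []
    n_windows_per_contig = [int(math.ceil(l / window)) for l in index.contig_lengths]
    n_windows = sum(n_windows_per_contig)
    N = len(hits)
    L = index.mappable_length

    counts: dict[tuple[str, int], int] = {}
    for h in hits:
        counts[(h.contig, h.start // window)] = counts.get((h.contig, h.start // window), 0) + 1

    significant: set[tuple[str, int]] = set()
    pvals: dict[tuple[str, int], float] = {}
    for (contig, wi), c in counts.items():
        ci = index.contig_names.index(contig)
        w_len = min(window, int(index.contig_lengths[ci]) - wi * window)
        lam = N * w_len / L
        p = float(stats.poisson.sf(c - 1, lam))
        pvals[(contig, wi)] = p
        if p < alpha / n_windows:
            significant.add((contig, wi))

    regions: list[CandidateTemplateRegion] = []
    for contig in index.contig_names:
        wins = sorted(wi for (c, wi) in significant if c == contig)
        if not wins:
            continue
        run = [wins[0]]
        runs = []
        for wi in wins[1:]:
            if wi - run[-1] <= merge_gap_windows + 1:
                run.append(wi)
            else:
                runs.append(run)
                run = [wi]
        runs.append(run)
        clen = int(index.contig_lengths[index.contig_names.index(contig)])
        for run in runs:
            start = run[0] * window
            end = min((run[-1] + 1) * window, clen)
            in_region = [h for h in hits if h.contig == contig and start <= h.start < end]
            region = CandidateTemplateRegion(
                contig=contig,
                start=start,
                end=end,
                anchor_count=len(in_region),
                enrichment_p=min(1.0, min(pvals[(contig, wi)] for wi in run) * n_windows),
            )
            region.counts = _stratified_counts(region, in_region)
            regions.append(region)
    regions.sort(key=lambda r: -r.anchor_count)
    return regions


def _stratified_counts(
    region: CandidateTemplateRegion, hits: Iterable[AnchorHit]
) -> dict[str, int]:
    counts = {"5prime_G": 0, "5prime_C": 0, "3prime_G": 0, "3prime_C": 0, "other": 0}
    mid_region = (region.start + region.end) / 2
    for h in hits:
        if h.partner_type not in (MateType.G, MateType.C):
            counts["other"] += 1
            continue
        side = "5prime" if (h.start + h.end) / 2 < mid_region else "3prime"
        counts[f"{side}_{h.partner_type.value}"] += 1
    return counts


def call_orientation(
    region: CandidateTemplateRegion,
    hits: Sequence[AnchorHit],
    end_margin: int = 1000,
    tau: float = 0.9,
    min_informative: int = 20,
) -> RegionOrientation:
    """Strand-typed orientation of a candidate region.

    Only anchors lying within ``end_margin`` of the region's 5' or 3'
    boundary and carrying a G- or C-typed telomeric partner are informative.
    5'/3' refer to forward-strand reference coordinate order.  An empty
    partner class imposes no constraint; the informative-anchor floor guards
    against calling from noise.
    """
    g5 = g3 = c5 = c3 = 0
    for h in hits:
        if h.contig != region.contig or h.partner_type not in (MateType.G, MateType.C):
            continue
        in5 = region.start <= h.start < region.start + end_margin
        in3 = region.end - end_margin < h.end <= region.end
        if not (in5 or in3):
            continue
        if in5 and in3:  # tiny region: assign by midpoint
            in5 = (h.start + h.end) / 2 < (region.start + region.end) / 2
            in3 = not in5
        if h.partner_type is MateType.G:
            g5, g3 = g5 + (1 if in5 else 0), g3 + (1 if in3 else 0)
        else:
            c5, c3 = c5 + (1 if in5 else 0), c3 + (1 if in3 else 0)
    informative = g5 + g3 + c5 + c3
    region.counts.update({"5prime_G": g5, "5prime_C": c5, "3prime_G": g3, "3prime_C": c3})
    if informative < min_informative:
        region.orientation = RegionOrientation.NOCALL
        return region.orientation
    frac_g3 = g3 / (g3 + g5) if (g3 + g5) else 1.0
    frac_c5 = c5 / (c3 + c5) if (c3 + c5) else 1.0
    frac_g5 = 1.0 - frac_g3 if (g3 + g5) else 1.0
    frac_c3 = 1.0 - frac_c5 if (c3 + c5) else 1.0
    if frac_g3 >= tau and frac_c5 >= tau:
        region.orientation = RegionOrientation.FORWARD
    elif frac_g5 >= tau and frac_c3 >= tau:
        region.orientation = RegionOrientation.REVERSE
    else:
        region.orientation = RegionOrientation.INCONSISTENT
    return region.orientation


def anchors_table(hits: Iterable[AnchorHit]):
    import pandas as pd

    return pd.DataFrame(
        [
            (h.read_id, h.contig, h.start, h.end, h.strand, h.score, h.n_mismatch,
             h.partner_type.value)
            for h in hits
        ],
        columns=["read_id", "contig", "start", "end", "strand", "score", "n_mismatch",
                 "partner_type"],
    )
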