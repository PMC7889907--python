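"""Allele pileups, zygosity calls, subtelomeric LOH gradients, and selection
of the amplified template paralog across timepoints.

Because template copies cross-map onto the single reference locus, the pileup
there pools every paralog in the sample; the frequency of a paralog-private
marker allele therefore tracks that paralog's share of total template dosage.
The selection rule exploits exactly this: the amplified paralog is the one
whose private-allele frequency rises substantially over the timecourse,
finishes near fixation, and does so while template copy number is
non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _stats

from .anchors import AnchorHit
from .core import DataError, revcomp
from .quant import CopyNumberEstimate


@dataclass(frozen=True)
class SnpSite:
    """A known biallelic site; ``paralog_label`` names the paralog whose
    private allele is the alt allele ('none' for ordinary sites)."""

    contig: str
    position: int  # 0-based
    ref_allele: str
    alt_allele: str
    paralog_label: str = "none"  # "A" | "B" | "none"

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise DataError(f"alleles at {self.contig}:{self.position} must differ")
        if self.paralog_label not in ("A", "B", "none"):
            raise DataError("paralog_label must be 'A', 'B', or 'none'")


@dataclass(frozen=True)
class AlleleDepth:
    site: SnpSite
    ref_depth: int
    alt_depth: int
    other_depth: int


class Zygosity(str, Enum):
    HOM_REF = "HOM_REF"
    HET = "HET"
    HOM_ALT = "HOM_ALT"
    NOCALL = "NOCALL"


@dataclass(frozen=True)
class ZygosityCall:
    site: SnpSite
    ref_depth: int
    alt_depth: int
    alt_frequency: float | None  # defined when depth >= min_depth
    call: Zygosity


def pileup_alleles(
    hits: Sequence[AnchorHit],
    read_seqs: Mapping[str, str],
    sites: Sequence[SnpSite],
) -> list[AlleleDepth]:
    """Ref/alt/other base counts per site from ungapped anchored reads.

    '-'-strand hits store the read as sequenced, so the base over reference
    position p is the complement of the read base at the mirrored offset.
    """
    by_contig: dict[str, list[AnchorHit]] = {}
    for h in hits:
        by_contig.setdefault(h.contig, []).append(h)
    for hs in by_contig.values():
        hs.sort(key=lambda h: h.start)

    out: list[AlleleDepth] = []
    for site in sites:
        ref_n = alt_n = other_n = 0
        for h in by_contig.get(site.contig, []):
            if h.start > site.position:
                break
            if h.end <= site.position:
                continue
            seq = read_seqs[h.read_id]
            off = site.position - h.start
            if h.strand == "+":
                base = seq[off]
            else:
                base = revcomp(seq[len(seq) - 1 - off])
            if base == site.ref_allele:
                ref_n += 1
            elif base == site.alt_allele:
                alt_n += 1
            else:
                other_n += 1
        out.append(AlleleDepth(site, ref_n, alt_n, other_n))
    return out


def call_zygosity(
    depth: AlleleDepth, min_depth: int = 5, hom_cut: float = 0.9
) -> ZygosityCall:
    """HOM_ALT above ``hom_cut`` alt frequency, HOM_REF below ``1 - hom_cut``,
    HET in between; NOCALL under ``min_depth`` informative reads."""
    total = depth.ref_depth + depth.alt_depth
    if total < min_depth:
        return ZygosityCall(depth.site, depth.ref_depth, depth.alt_depth, None, Zygosity.NOCALL)
    af = depth.alt_depth / total
    if af > hom_cut:
        z = Zygosity.HOM_ALT
    elif af < 1 - hom_cut:
        z = Zygosity.HOM_REF
    else:
        z = Zygosity.HET
    return ZygosityCall(depth.site, depth.ref_depth, depth.alt_depth, af, z)


def call_zygosities(
    depths: Sequence[AlleleDepth], min_depth: int = 5, hom_cut: float = 0.9
) -> list[ZygosityCall]:
    return [call_zygosity(d, min_depth, hom_cut) for d in depths]


def loh_gradient(
    calls: Sequence[ZygosityCall],
    chrom_length: int,
    bin_size: int = 100_000,
) -> list[tuple[int, float | None]]:
    """Homozygous fraction per bin of distance from the nearest chromosome end.

    Returns (bin index, HOM / (HOM + HET)) ordered from the distal end inward;
    bins without informative calls carry None.
    """
    contigs = {c.site.contig for c in calls}
    if len(contigs) > 1:
        raise DataError("loh_gradient expects calls from a single contig")
    n_bins = (chrom_length // 2) // bin_size + 1
    hom = np.zeros(n_bins)
    het = np.zeros(n_bins)
    for c in calls:
        if c.call is Zygosity.NOCALL:
            continue
        dist = min(c.site.position, chrom_length - 1 - c.site.position)
        b = min(dist // bin_size, n_bins - 1)
        if c.call is Zygosity.HET:
            het[b] += 1
        else:
            hom[b] += 1
    out: list[tuple[int, float | None]] = []
    for b in range(n_bins):
        total = hom[b] + het[b]
        out.append((b, float(hom[b] / total) if total else None))
    return out


# --------------------------------------------------------------------------
# longitudinal paralog selection


@dataclass(frozen=True)
class ParalogSelectionResult:
    af_a: list[float]  # mean paralog-A private-allele frequency per timepoint
    af_b: list[float]
    ratios: list[float]  # copy-number ratio per timepoint
    score_a: float  # AF_A(last) - AF_A(first)
    score_b: float
    selected: str  # "A" | "B" | "none"


def _paralog_afs(calls: Sequence[ZygosityCall]) -> tuple[float, float]:
    """Mean private-allele frequency of paralogs A and B over labelled sites."""
    fa: list[float] = []
    fb: list[float] = []
    for c in calls:
        if c.site.paralog_label == "none" or c.alt_frequency is None:
            continue
        alt_owner_freq = c.alt_frequency
        if c.site.paralog_label == "A":
            fa.append(alt_owner_freq)
            fb.append(1 - alt_owner_freq)
        else:
            fb.append(alt_owner_freq)
            fa.append(1 - alt_owner_freq)
    if not fa:
        raise DataError("no informative paralog-labelled marker sites")
    return float(np.mean(fa)), float(np.mean(fb))


def select_amplified_paralog(
    series: Sequence[tuple[Sequence[ZygosityCall], CopyNumberEstimate | float]],
    min_gain: float = 0.25,
    min_final_af: float = 0.75,
    ratio_tolerance: float = 0.10,
) -> ParalogSelectionResult:
    """Identify which paralog the amplified template copies came from.

    ``series`` is ordered by population doubling: per timepoint, zygosity
    calls at paralog-labelled marker sites plus a copy-number estimate.  A
    paralog is selected when its private-allele frequency gained at least
    ``min_gain`` from first to last timepoint, ended at ``min_final_af`` or
    higher, and the copy-number ratio never dropped by more than
    ``ratio_tolerance`` (relative) between consecutive timepoints.
    """
    if len(series) < 2:
        raise DataError("paralog selection needs at least two timepoints")
    af_a: list[float] = []
    af_b: list[float] = []
    ratios: list[float] = []
    for calls, cn in series:
        a, b = _paralog_afs(calls)
        af_a.append(a)
        af_b.append(b)
        ratios.append(cn.ratio if isinstance(cn, CopyNumberEstimate) else float(cn))
    score_a = af_a[-1] - af_a[0]
    score_b = af_b[-1] - af_b[0]
    non_decreasing = all(
        ratios[i + 1] >= ratios[i] * (1 - ratio_tolerance) for i in range(len(ratios) - 1)
    )
    selected = "none"
    if non_decreasing:
        a_ok = score_a >= min_gain and af_a[-1] >= min_final_af
        b_ok = score_b >= min_gain and af_b[-1] >= min_final_af
        if a_ok and not b_ok:
            selected = "A"
        elif b_ok and not a_ok:
            selected = "B"
    return ParalogSelectionResult(af_a, af_b, ratios, score_a, score_b, selected)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (thin wrapper, used for gradient checks)."""
    return float(_stats.spearmanr(x, y).statistic)
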