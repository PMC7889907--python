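"""Depth-of-coverage quantification: copy number and windowed CNV.

Template copy number is the mean depth of the template locus divided by the
mean depth of an equal-length single-copy control interval (conventionally on
the same chromosome), i.e. copies per haploid genome relative to a
single-copy region.  Two-sample CNV profiles are library-size-normalised 1 kb
log2 ratios segmented by recursive binary segmentation with a BIC-style
penalty — a deliberately simple stand-in for circular binary segmentation
that is adequate at the scale this package works at.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .anchors import AnchorHit
from .core import Contig, DataError, GenomicInterval, InsufficientDataError


class DepthTrack(dict):
    """Per-contig arrays of per-base read depth ({name: int64 array})."""

    @property
    def total_aligned_bases(self) -> int:
        return int(sum(int(a.sum()) for a in self.values()))


def depth_from_anchors(
    hits: Sequence[AnchorHit], reference: Sequence[Contig] | Mapping[str, int]
) -> DepthTrack:
    """Per-base depth: the number of anchor intervals covering each base."""
    if isinstance(reference, Mapping):
        lengths = dict(reference)
    else:
        lengths = {c.name: len(c) for c in reference}
    diffs = {name: np.zeros(length + 1, dtype=np.int64) for name, length in lengths.items()}
    for h in hits:
        if h.contig not in diffs:
            raise DataError(f"hit on unknown contig {h.contig!r}")
        if h.start < 0 or h.end > lengths[h.contig]:
            raise DataError(f"hit {h.contig}:{h.start}-{h.end} outside contig bounds")
        diffs[h.contig][h.start] += 1
        diffs[h.contig][h.end] -= 1
    track = DepthTrack()
    for name in lengths:
        track[name] = np.cumsum(diffs[name][:-1])
    return track


@dataclass(frozen=True)
class CopyNumberEstimate:
    target: GenomicInterval
    control: GenomicInterval
    mean_depth_target: float
    mean_depth_control: float

    @property
    def ratio(self) -> float:
        return self.mean_depth_target / self.mean_depth_control


def copy_number_ratio(
    depth: DepthTrack, target: GenomicInterval, control: GenomicInterval
) -> CopyNumberEstimate:
    """Depth ratio of target vs single-copy control."""
    mt = _interval_mean(depth, target)
    mc = _interval_mean(depth, control)
    if mc <= 0:
        raise InsufficientDataError("control interval has zero depth")
    return CopyNumberEstimate(target, control, mt, mc)


def _interval_mean(depth: DepthTrack, iv: GenomicInterval) -> float:
    if iv.contig not in depth:
        raise DataError(f"interval on unknown contig {iv.contig!r}")
    arr = depth[iv.contig]
    if iv.end > len(arr):
        raise DataError(f"interval {iv.contig}:{iv.start}-{iv.end} outside contig bounds")
    return float(arr[iv.start : iv.end].mean())


@dataclass
class CnvProfile:
    """Windowed two-sample log2 ratios plus (optionally) segments."""

    window: int
    contigs: list[str]
    starts: dict[str, np.ndarray]  # window start coordinates per contig
    log2: dict[str, np.ndarray]
    segments: dict[str, list[tuple[int, int, float]]] = field(default_factory=dict)
    # segments: (first window idx, one-past-last window idx, mean log2)


def windowed_log2_ratio(
    test: DepthTrack,
    ref: DepthTrack,
    window: int = 1000,
    pseudocount: float = 0.5,
) -> CnvProfile:
    """Per-window log2((t_i+pc)/T / ((r_i+pc)/R)); T, R are genome-wide sums,
    so the profile is invariant to global library-size differences."""
    if set(test) != set(ref):
        raise DataError("test and reference depth tracks cover different contigs")
    T = max(test.total_aligned_bases, 1)
    R = max(ref.total_aligned_bases, 1)
    starts: dict[str, np.ndarray] = {}
    log2: dict[str, np.ndarray] = {}
    for name in test:
        if len(test[name]) != len(ref[name]):
            raise DataError(f"contig {name!r} length differs between tracks")
        t = _window_sums(test[name], window)
        r = _window_sums(ref[name], window)
        starts[name] = np.arange(len(t), dtype=np.int64) * window
        log2[name] = np.log2(((t + pseudocount) / T) / ((r + pseudocount) / R))
    return CnvProfile(window=window, contigs=sorted(test), starts=starts, log2=log2)


def _window_sums(arr: np.ndarray, window: int) -> np.ndarray:
    n = (len(arr) + window - 1) // window
    padded = np.zeros(n * window, dtype=np.float64)
    padded[: len(arr)] = arr
    return padded.reshape(n, window).sum(axis=1)


# --------------------------------------------------------------------------
# binary segmentation


def _best_split(x: np.ndarray, min_segment: int) -> tuple[int | None, float]:
    """Best single breakpoint by residual-sum-of-squares reduction.

    Returns (split index, RSS decrease); the split index b partitions
    x[:b] / x[b:].  None when no admissible split exists.
    """
    n = len(x)
    if n < 2 * min_segment:
        return None, 0.0
    cs = np.cumsum(x)
    total = cs[-1]
    b = np.arange(min_segment, n - min_segment + 1)
    left_mean = cs[b - 1] / b
    right_mean = (total - cs[b - 1]) / (n - b)
    # RSS reduction of splitting at b (constant-mean model per side)
    gain = b * left_mean**2 + (n - b) * right_mean**2 - total**2 / n
    i = int(np.argmax(gain))
    return int(b[i]), float(gain[i])


def segment_values(
    x: np.ndarray, min_segment: int = 5, penalty: float | None = None
) -> list[tuple[int, int, float]]:
    """Recursive binary segmentation of one value series.

    A split is accepted when it lowers the penalised cost
    RSS + penalty * n_breakpoints; the default penalty is 2 * var_hat * log n
    with var_hat estimated from first differences.  A final pass merges any
    adjacent pair whose merge would lower the cost, so the output is locally
    optimal under the same criterion.
    """
    x = np.asarray(x, dtype=np.float64)
    n = len(x)
    if n == 0:
        return []
    if penalty is None:
        var_hat = float(np.var(np.diff(x)) / 2) if n > 1 else 0.0
        penalty = 2.0 * max(var_hat, 1e-12) * np.log(max(n, 2))
    if n < min_segment:
        return [(0, n, float(x.mean()))]

    boundaries = [0, n]

    def recurse(lo: int, hi: int) -> None:
        split, gain = _best_split(x[lo:hi], min_segment)
        if split is None or gain <= penalty:
            return
        boundaries.append(lo + split)
        recurse(lo, lo + split)
        recurse(lo + split, hi)

    recurse(0, n)
    boundaries = sorted(set(boundaries))

    # merge pass: collapse adjacent segments whose merge lowers penalised cost
    def rss(lo: int, hi: int) -> float:
        seg = x[lo:hi]
        return float(((seg - seg.mean()) ** 2).sum())

    changed = True
    while changed and len(boundaries) > 2:
        changed = False
        for i in range(1, len(boundaries) - 1):
            lo, mid, hi = boundaries[i - 1], boundaries[i], boundaries[i + 1]
            if rss(lo, hi) - (rss(lo, mid) + rss(mid, hi)) <= penalty:
                del boundaries[i]
                changed = True
                break
    return [
        (boundaries[i], boundaries[i + 1], float(x[boundaries[i] : boundaries[i + 1]].mean()))
        for i in range(len(boundaries) - 1)
    ]


def segment_profile(
    profile: CnvProfile, min_segment: int = 5, penalty: float | None = None
) -> CnvProfile:
    """Segment each contig's log2 window series in place and return the profile."""
    for name in profile.log2:
        profile.segments[name] = segment_values(
            profile.log2[name], min_segment=min_segment, penalty=penalty
        )
    return profile
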