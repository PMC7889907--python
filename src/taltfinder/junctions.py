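"""Split-read typing of template-template junctions in tandem arrays.

A junction read shows the end of one template copy, an optional run of
telomere repeat units, and the start of the next copy.  With HEAD the first
``probe_len`` bases of the template and TAIL the last, the patterns are the
in-silico analogue of direction-distinguishing PCR primers:

* TAIL ... HEAD in the same orientation     -> HEAD_TO_TAIL
* TAIL ... reverse-complement(TAIL)         -> TAIL_TO_TAIL
* reverse-complement(HEAD) ... HEAD         -> HEAD_TO_HEAD

Probes are matched exactly (no mismatches): like PCR primers, the point is
specificity, and at realistic substitution error rates most junction reads
still carry both probes intact.  Both the read and its reverse complement are
scanned, and the spacer between the probes may be a clean run of telomere
units in either strand sense.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .core import TELOMERE_UNIT, revcomp


class JunctionClass(str, Enum):
    HEAD_TO_TAIL = "HEAD_TO_TAIL"
    HEAD_TO_HEAD = "HEAD_TO_HEAD"
    TAIL_TO_TAIL = "TAIL_TO_TAIL"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class JunctionCall:
    read_id: str | None
    junction_class: JunctionClass
    spacer_units_observed: int | None  # defined only when classified


def _spacer_units(gap: str, unit: str) -> int | None:
    """Number of complete telomere units filling ``gap`` exactly, in either
    strand sense; None when the gap is not a clean (possibly empty) run."""
    if gap == "":
        return 0
    for u in (unit, revcomp(unit)):
        if len(gap) % len(u) == 0 and gap == u * (len(gap) // len(u)):
            return len(gap) // len(u)
    return None


def _scan_one_strand(
    seq: str, left: str, right: str, unit: str, max_spacer_units: int
) -> int | None:
    """Spacer unit count if ``left`` is followed by ``right`` within the
    allowed spacer span, else None.  Every occurrence of ``left`` is tried."""
    max_gap = max_spacer_units * len(unit)
    start = 0
    while True:
        i = seq.find(left, start)
        if i < 0:
            return None
        tail_end = i + len(left)
        j = seq.find(right, tail_end, tail_end + max_gap + len(right))
        if j >= 0:
            units = _spacer_units(seq[tail_end:j], unit)
            if units is not None and units <= max_spacer_units:
                return units
        start = i + 1


def scan_junction_read(
    seq: str,
    template: str,
    probe_len: int = 30,
    max_spacer_units: int = 30,
    telomere_unit: str = TELOMERE_UNIT,
    read_id: str | None = None,
) -> JunctionCall:
    """Classify one read against head/tail probes of the template."""
    if probe_len < 8 or 2 * probe_len > len(template):
        raise ValueError("probe_len must be >= 8 and at most half the template length")
    head = template[:probe_len]
    tail = template[-probe_len:]
    strands = (seq.upper(), revcomp(seq.upper()))

    for s in strands:
        units = _scan_one_strand(s, tail, head, telomere_unit, max_spacer_units)
        if units is not None:
            return JunctionCall(read_id, JunctionClass.HEAD_TO_TAIL, units)
    for s in strands:
        units = _scan_one_strand(s, tail, revcomp(tail), telomere_unit, max_spacer_units)
        if units is not None:
            return JunctionCall(read_id, JunctionClass.TAIL_TO_TAIL, units)
    for s in strands:
        units = _scan_one_strand(s, revcomp(head), head, telomere_unit, max_spacer_units)
        if units is not None:
            return JunctionCall(read_id, JunctionClass.HEAD_TO_HEAD, units)
    return JunctionCall(read_id, JunctionClass.UNCLASSIFIED, None)


def scan_junction_reads(
    reads: Iterable[tuple[str, str]],
    template: str,
    probe_len: int = 30,
    max_spacer_units: int = 30,
    telomere_unit: str = TELOMERE_UNIT,
) -> list[JunctionCall]:
    """Classify (id, sequence) reads, keeping only classified calls."""
    calls = []
    for read_id, seq in reads:
        call = scan_junction_read(
            seq, template, probe_len, max_spacer_units, telomere_unit, read_id=read_id
        )
        if call.junction_class is not JunctionClass.UNCLASSIFIED:
            calls.append(call)
    return calls


@dataclass(frozen=True)
class JunctionSummary:
    counts: dict[str, int]
    dominant_class: str | None
    dominant_fraction: float | None
    spacer_histogram: dict[int, int]

    @property
    def modal_spacer_units(self) -> int | None:
        if not self.spacer_histogram:
            return None
        return max(self.spacer_histogram.items(), key=lambda kv: (kv[1], -kv[0]))[0]


def summarize_junctions(
    calls: Sequence[JunctionCall], dominance: float = 0.8, min_classified: int = 10
) -> JunctionSummary:
    """Class counts, a dominant class (if one holds ``dominance`` of at least
    ``min_classified`` classified calls), and the spacer-unit histogram."""
    counts = Counter(c.junction_class.value for c in calls)
    full = {jc.value: counts.get(jc.value, 0) for jc in JunctionClass}
    classified = sum(
        v for k, v in full.items() if k != JunctionClass.UNCLASSIFIED.value
    )
    dominant = None
    frac = None
    if classified >= min_classified:
        top, top_n = max(
            ((k, v) for k, v in full.items() if k != JunctionClass.UNCLASSIFIED.value),
            key=lambda kv: kv[1],
        )
        frac = top_n / classified
        if frac >= dominance:
            dominant = top
    hist = Counter(
        c.spacer_units_observed
        for c in calls
        if c.spacer_units_observed is not None
    )
    return JunctionSummary(
        counts=full,
        dominant_class=dominant,
        dominant_fraction=frac,
        spacer_histogram=dict(sorted(hist.items())),
    )
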