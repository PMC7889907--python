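"""Telomeric read detection and genome-wide telomere content estimation.

A mate is telomeric when it contains the G-strand unit (TTAGGG) or the
C-strand unit (CCCTAA) at least ``threshold`` times (default 3), counted as
exact, non-overlapping, case-insensitive occurrences.  Read pairs are then
PAIR (both mates telomeric), SINGLE (exactly one), or NONE; the non-telomeric
mate of a SINGLE pair is the *anchorable* mate, whose placement on a
reference reveals sequence adjacent to telomere repeats.

Telomere content is a coverage-normalised estimate: with B_tel the summed
length of telomeric mates, d = B_total / G the mean sequencing depth, and E
the number of chromosome ends, the mean telomere length per end is

    L_hat = B_tel / (d * E)

Reads are scanned as written; no reverse-complement pass is needed because
CCCTAA is the reverse complement of TTAGGG and both are counted.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import pandas as pd

from .core import TELOMERE_UNIT, InsufficientDataError, revcomp

C_STRAND_UNIT = revcomp(TELOMERE_UNIT)  # CCCTAA


class MateType(str, Enum):
    G = "G"
    C = "C"
    AMBIGUOUS = "AMBIGUOUS"
    NONE = "NONE"


class PairCategory(str, Enum):
    PAIR = "PAIR"
    SINGLE = "SINGLE"
    NONE = "NONE"


@dataclass(frozen=True)
class ReadPair:
    """Two sequenced mates of one fragment."""

    id: str
    mate1_seq: str
    mate2_seq: str
    mate1_qual: str
    mate2_qual: str

    def __post_init__(self) -> None:
        if len(self.mate1_seq) != len(self.mate1_qual) or len(self.mate2_seq) != len(
            self.mate2_qual
        ):
            raise ValueError(f"sequence/quality length mismatch in pair {self.id!r}")


@dataclass(frozen=True)
class TelomereClassification:
    g1: int
    c1: int
    g2: int
    c2: int
    mate1_type: MateType
    mate2_type: MateType
    category: PairCategory
    anchorable_mate: int | None  # 1 or 2 for SINGLE pairs, else None
    partner_type: MateType | None  # strand type of the telomeric mate of a SINGLE pair


def count_motif(seq: str, motif: str) -> int:
    """Non-overlapping, case-insensitive occurrences in a left-to-right greedy scan."""
    if not motif:
        raise ValueError("motif must be non-empty")
    return seq.upper().count(motif.upper())


def classify_mate(seq: str, threshold: int = 3) -> tuple[MateType, int, int]:
    """Type one mate by G-strand and C-strand motif counts."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    g = count_motif(seq, TELOMERE_UNIT)
    c = count_motif(seq, C_STRAND_UNIT)
    if g >= threshold and c >= threshold:
        t = MateType.AMBIGUOUS
    elif g >= threshold:
        t = MateType.G
    elif c >= threshold:
        t = MateType.C
    else:
        t = MateType.NONE
    return t, g, c


def classify_pair(pair: ReadPair, threshold: int = 3) -> TelomereClassification:
    t1, g1, c1 = classify_mate(pair.mate1_seq, threshold)
    t2, g2, c2 = classify_mate(pair.mate2_seq, threshold)
    tel1, tel2 = t1 is not MateType.NONE, t2 is not MateType.NONE
    if tel1 and tel2:
        category, anchorable, partner = PairCategory.PAIR, None, None
    elif tel1 or tel2:
        category = PairCategory.SINGLE
        anchorable = 2 if tel1 else 1
        partner = t1 if tel1 else t2
    else:
        category, anchorable, partner = PairCategory.NONE, None, None
    return TelomereClassification(
        g1=g1, c1=c1, g2=g2, c2=c2,
        mate1_type=t1, mate2_type=t2,
        category=category, anchorable_mate=anchorable, partner_type=partner,
    )


def classify_pairs(
    pairs: Iterable[ReadPair], threshold: int = 3
) -> list[tuple[ReadPair, TelomereClassification]]:
    return [(p, classify_pair(p, threshold)) for p in pairs]


@dataclass(frozen=True)
class TelomereContentEstimate:
    telomeric_base_count: int
    total_base_count: int
    genome_size: int
    n_ends: int

    @property
    def mean_depth(self) -> float:
        return self.total_base_count / self.genome_size

    @property
    def length_per_end(self) -> float:
        return self.telomeric_base_count / (self.mean_depth * self.n_ends)


def estimate_telomere_content(
    classified: Iterable[tuple[ReadPair, TelomereClassification]],
    genome_size: int,
    n_ends: int,
) -> TelomereContentEstimate:
    """Coverage-normalised telomere length per chromosome end.

    AMBIGUOUS mates count as telomeric: they carry repeat sequence even if
    their strand is uninformative.
    """
    if genome_size <= 0 or n_ends <= 0:
        raise ValueError("genome_size and n_ends must be positive")
    b_tel = 0
    b_total = 0
    for pair, cls in classified:
        for seq, mate_type in ((pair.mate1_seq, cls.mate1_type), (pair.mate2_seq, cls.mate2_type)):
            b_total += len(seq)
            if mate_type is not MateType.NONE:
                b_tel += len(seq)
    if b_total == 0:
        raise InsufficientDataError("no reads observed")
    return TelomereContentEstimate(
        telomeric_base_count=b_tel,
        total_base_count=b_total,
        genome_size=genome_size,
        n_ends=n_ends,
    )


def category_counts(
    classified: Iterable[tuple[ReadPair, TelomereClassification]]
) -> dict[str, int]:
    counts = Counter(cls.category.value for _, cls in classified)
    return {cat.value: counts.get(cat.value, 0) for cat in PairCategory}


def classification_table(
    classified: Iterable[tuple[ReadPair, TelomereClassification]]
) -> pd.DataFrame:
    """Per-pair TSV-ready table: id, motif counts, category, anchorable mate."""
    rows = [
        (
            p.id, c.g1, c.c1, c.g2, c.c2, c.category.value,
            c.anchorable_mate if c.anchorable_mate is not None else ".",
        )
        for p, c in classified
    ]
    return pd.DataFrame(
        rows, columns=["read_id", "g1", "c1", "g2", "c2", "category", "anchorable_mate"]
    )
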