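"""Shared primitives: sequences, intervals, errors, and known mouse loci.

The canonical vertebrate telomere repeat is TTAGGG on the G-rich strand;
CCCTAA is its reverse complement on the C-rich strand.  Everything in this
package treats DNA as uppercase strings over {A, C, G, T, N}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

TELOMERE_UNIT = "TTAGGG"

#: Error classes -----------------------------------------------------------


class TaltError(Exception):
    """Base class for package errors."""


class ConfigurationError(TaltError):
    """A configuration value violates an invariant."""


class DataError(TaltError):
    """Input data is inconsistent (out-of-bounds hit, mismatched contigs...)."""


class InsufficientDataError(TaltError):
    """Not enough observations to compute the requested quantity."""


#: Sequence utilities ------------------------------------------------------

_COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")

# base -> 2-bit code; anything else (incl. N) -> 4
ENCODE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    ENCODE_LUT[_b] = _i
    ENCODE_LUT[_b + 32] = _i  # lowercase

DECODE_LUT = np.frombuffer(b"ACGTN", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case preserved per base)."""
    return seq.encode()[::-1].translate(_COMPLEMENT).decode()


def revcomp_bytes(seq: bytes) -> bytes:
    return seq[::-1].translate(_COMPLEMENT)


def encode(seq: str | bytes) -> np.ndarray:
    """Encode DNA into uint8 codes (A=0 C=1 G=2 T=3, other=4)."""
    if isinstance(seq, str):
        seq = seq.encode()
    return ENCODE_LUT[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return DECODE_LUT[np.minimum(codes, 4)].tobytes().decode()


def random_dna(rng: np.random.Generator, n: int) -> str:
    """Uniform random DNA of length ``n`` drawn from ``rng``."""
    return decode(rng.integers(0, 4, size=n, dtype=np.uint8))


@dataclass(frozen=True)
class Contig:
    """A named DNA sequence (uppercase over {A,C,G,T,N})."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.name:
            raise DataError("contig name must be non-empty")
        if not self.sequence:
            raise DataError(f"contig {self.name!r} has empty sequence")
        if set(self.sequence) - set("ACGTN"):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise DataError(f"contig {self.name!r} contains invalid characters {bad}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a contig."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise DataError(f"invalid interval {self.contig}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    @classmethod
    def from_one_based(cls, contig: str, start: int, end: int) -> "GenomicInterval":
        """Build from 1-based inclusive coordinates as printed in genome browsers."""
        return cls(contig, start - 1, end)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.contig == other.contig and self.start < other.end and other.start < self.end

    def jaccard(self, other: "GenomicInterval") -> float:
        """Jaccard overlap of two intervals (0 if on different contigs)."""
        if self.contig != other.contig:
            return 0.0
        inter = max(0, min(self.end, other.end) - max(self.start, other.start))
        union = len(self) + len(other) - inter
        return inter / union if union else 0.0


#: Known mouse (mm10) loci --------------------------------------------------
#
# The mouse TALT element sits on chromosome 13; copy number is conventionally
# expressed relative to a same-chromosome single-copy block of equal length.

MTALT_LOCUS_MM10 = GenomicInterval.from_one_based("chr13", 120_311_821, 120_319_190)
SINGLE_COPY_CONTROL_MM10 = GenomicInterval.from_one_based("chr13", 109_998_778, 110_006_148)
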