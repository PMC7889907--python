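"""In-silico restriction digestion.

Terminal restriction fragment (TRF) logic: enzymes whose recognition sites
cannot occur in the canonical telomere repeat (AluI, MboI, HinfI) leave pure
repeat arrays uncut, while telomeres that carry template elements are cleaved
inside every copy and release discrete, periodically recurring fragments.

All three built-ins recognise palindromic sites (GANTC included, since N
pairs with N), so a single-strand scan finds every cut; a user-supplied
non-palindromic enzyme triggers an automatic scan of the opposite strand with
the mirrored cut offset.  Circular sequences are not supported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .core import revcomp

_IUPAC = {"A": "A", "C": "C", "G": "G", "T": "T", "N": "[ACGT]"}


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: recognition pattern over {A,C,G,T,N} and the cut
    offset from the pattern start (on the scanned strand)."""

    name: str
    pattern: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.pattern or set(self.pattern) - set("ACGTN"):
            raise ValueError(f"{self.name}: pattern must be over {{A,C,G,T,N}}")
        if not 0 <= self.cut_offset <= len(self.pattern):
            raise ValueError(f"{self.name}: cut_offset outside pattern")

    @property
    def is_palindromic(self) -> bool:
        return revcomp(self.pattern) == self.pattern

    def regex(self) -> re.Pattern:
        # lookahead so overlapping occurrences all contribute cuts
        return re.compile("(?=" + "".join(_IUPAC[b] for b in self.pattern) + ")")


#: AluI AG^CT, MboI ^GATC, HinfI G^ANTC — none can cut (TTAGGG)n
BUILTIN_ENZYMES = {
    "AluI": Enzyme("AluI", "AGCT", 2),
    "MboI": Enzyme("MboI", "GATC", 0),
    "HinfI": Enzyme("HinfI", "GANTC", 1),
}


def find_sites(seq: str, enzyme: Enzyme) -> list[int]:
    """Sorted, deduplicated cut positions of one enzyme on ``seq``."""
    s = seq.upper()
    cuts = {m.start() + enzyme.cut_offset for m in enzyme.regex().finditer(s)}
    if not enzyme.is_palindromic:
        # scan the bottom strand: a site at top-strand position i..i+m cuts the
        # bottom strand; in top-strand coordinates the offset mirrors
        rc_enzyme = Enzyme(enzyme.name, revcomp(enzyme.pattern), 0)
        m = len(enzyme.pattern)
        for match in rc_enzyme.regex().finditer(s):
            cuts.add(match.start() + (m - enzyme.cut_offset))
    return sorted(c for c in cuts if 0 <= c <= len(s))


@dataclass(frozen=True)
class DigestResult:
    enzymes: tuple[str, ...]
    sequence_length: int
    cut_positions: tuple[int, ...]  # strictly increasing
    fragment_lengths: tuple[int, ...]  # sums to sequence_length


def digest(seq: str, enzymes: Iterable[Enzyme]) -> DigestResult:
    """Union of all enzymes' cuts; fragments between consecutive cuts plus the
    two terminal fragments."""
    enzymes = list(enzymes)
    cuts = sorted({c for e in enzymes for c in find_sites(seq, e)} - {0, len(seq)})
    edges = [0, *cuts, len(seq)]
    fragments = tuple(edges[i + 1] - edges[i] for i in range(len(edges) - 1))
    return DigestResult(
        enzymes=tuple(e.name for e in enzymes),
        sequence_length=len(seq),
        cut_positions=tuple(cuts),
        fragment_lengths=fragments,
    )


def fragment_histogram(result: DigestResult, bin_size: int = 100) -> dict[int, int]:
    """Fragment counts binned by length (bin start -> count)."""
    hist: dict[int, int] = {}
    for f in result.fragment_lengths:
        b = (f // bin_size) * bin_size
        hist[b] = hist.get(b, 0) + 1
    return dict(sorted(hist.items()))
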