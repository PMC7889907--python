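"""Simulator of pre-ALT and post-ALT telomere architectures.

The toy genome is a diploid with ``n_chromosomes`` chromosomes, each carried
as two explicit haplotype contigs (homozygous by default).  Two near-identical
template paralogs are planted, distinguished only by marker SNPs:

* paralog A sits interstitially in chromosome 1 (like the reference-borne
  copy on mouse chr13), and
* paralog B sits just inside the q-telomere of chromosome 2, behind a short
  tract of telomere repeats joined to the subtelomere (like the subterminal
  copy on chr11 of ALT-prone strains).

``build_pre_alt_genome`` returns that two-copy state with long terminal
telomere tracts.  ``build_alt_genome`` rebuilds both ends of chromosome 2 as
tandem head-to-tail arrays of the selected paralog, each copy separated by a
fixed number of telomere units and capped by a short terminal tract — the
architecture inferred for ALT survivors.  The mapping reference
(``build_reference_genome``) is haploid and carries only paralog A, so reads
from every template copy in a sample pile onto a single reference locus;
paralog-private marker alleles then appear as alternate alleles whose
frequency tracks the amplified copy's dosage.

Read simulation draws fragment midpoints uniformly, fragment lengths from a
truncated normal, and independent per-base substitution errors; qualities are
constant Q30 because no downstream stage is quality-aware.

Orientation convention: with ``array_orientation="forward"`` each array copy
points its template 5' (head) end toward the chromosome terminus.  Strand-
typed anchor evidence from that geometry places G-strand partners at the
reference locus 3' end and C-strand partners at its 5' end, which the anchors
module calls FORWARD.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core import (
    TELOMERE_UNIT,
    ConfigurationError,
    Contig,
    GenomicInterval,
    random_dna,
    revcomp,
    revcomp_bytes,
)

_CHASSIS_STREAM = 11
_READ_STREAM = 29

# transitions, so marker alleles stay maximally boring
_MARKER_SUBST = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass(frozen=True)
class SimConfig:
    """Architecture and sequencing parameters of one simulated scenario.

    Defaults describe the study conditions the package is exercised under: a
    2-chromosome 500 kb-per-chromosome diploid, a 7,370 bp template, eight
    tandem copies per rebuilt end separated by eight telomere units, 150 bp
    paired-end reads at 30-fold coverage with a 0.2% substitution error rate.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 500_000
    template_length: int = 7_370
    paralog_marker_count: int = 10
    telomere_unit: str = TELOMERE_UNIT
    pre_alt_telomere_length: int = 5_000
    alt_copies_per_end: int = 8
    spacer_units_between_copies: int = 8
    selected_paralog: str = "B"
    read_length: int = 150
    fragment_mean: float = 450.0
    fragment_sd: float = 50.0
    coverage: float = 30.0
    substitution_error_rate: float = 0.002
    # architecture knobs beyond the core set
    array_orientation: str = "forward"
    terminal_telomere_units: int = 10
    marker_edge_margin: int = 200
    alt_all_ends: bool = False

    def validate(self) -> None:
        errors = []
        if self.n_chromosomes < 2:
            errors.append("n_chromosomes must be >= 2 (paralogs live on two chromosomes)")
        if self.template_length <= 3 * self.read_length:
            errors.append("template_length must exceed 3x read_length")
        if self.fragment_mean <= 2 * self.read_length:
            errors.append("fragment_mean must exceed 2x read_length")
        for name in ("chrom_length", "template_length", "pre_alt_telomere_length",
                     "read_length", "alt_copies_per_end", "terminal_telomere_units"):
            if getattr(self, name) <= 0:
                errors.append(f"{name} must be positive")
        if self.spacer_units_between_copies < 0:
            errors.append("spacer_units_between_copies must be >= 0")
        if self.paralog_marker_count < 0:
            errors.append("paralog_marker_count must be >= 0")
        if not self.telomere_unit or set(self.telomere_unit) - set("ACGT"):
            errors.append("telomere_unit must be a non-empty ACGT string")
        if self.selected_paralog not in ("A", "B"):
            errors.append("selected_paralog must be 'A' or 'B'")
        if self.array_orientation not in ("forward", "reverse"):
            errors.append("array_orientation must be 'forward' or 'reverse'")
        if not 0.0 <= self.substitution_error_rate <= 1.0:
            errors.append("substitution_error_rate must be in [0, 1]")
        if self.fragment_sd < 0:
            errors.append("fragment_sd must be >= 0")
        if self.paralog_marker_count > 0:
            usable = self.template_length - 2 * self.marker_edge_margin
            if usable < self.paralog_marker_count:
                errors.append("template too short for requested marker count and edge margin")
        spacer = self.spacer_units_between_copies * len(self.telomere_unit)
        if self.chrom_length < 2 * self.template_length + spacer + 10_000:
            errors.append("chrom_length too small for the template architecture")
        if errors:
            raise ConfigurationError("; ".join(errors))

    @property
    def spacer_length(self) -> int:
        return self.spacer_units_between_copies * len(self.telomere_unit)


@dataclass(frozen=True)
class Segment:
    """One architectural block of a simulated chromosome (0-based half-open)."""

    label: str  # subtelomere | telomere_repeat | template_A | template_B | spacer
    start: int
    end: int
    orientation: str  # '+', '-', or '.' for strandless blocks


@dataclass
class SimTruth:
    """Ground truth of one simulated genome, for parameter-recovery tests."""

    architecture: str  # "pre_alt" | "alt"
    ploidy: int
    segments: dict[str, list[Segment]]  # per sample contig
    copy_number: float  # template copies per haploid genome
    selected_paralog: str
    markers: list[tuple[int, str, str]]  # (pos in template, allele A, allele B)
    expected_junction_class: str | None
    expected_orientation: str | None
    per_end_telomere_bases: dict[str, int]  # "contig:L" / "contig:R"
    template_locus_ref: GenomicInterval  # paralog-A locus on the haploid reference
    control_locus_ref: GenomicInterval  # equal-length single-copy control
    marker_sites_ref: list[tuple[str, int, str, str]]  # (contig, pos, ref=A, alt=B)

    @property
    def n_ends(self) -> int:
        return 2 * len(self.segments)

    def template_segment_count(self) -> int:
        return sum(
            1 for segs in self.segments.values() for s in segs if s.label.startswith("template")
        )

    def recomputed_copy_number(self) -> float:
        return self.template_segment_count() / self.ploidy

    def mean_telomere_bases_per_end(self) -> float:
        return sum(self.per_end_telomere_bases.values()) / self.n_ends

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["template_locus_ref"] = dataclasses.asdict(self.template_locus_ref)
        payload["control_locus_ref"] = dataclasses.asdict(self.control_locus_ref)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    def segments_bed(self, path) -> None:
        from .seqio import write_bed

        rows = [
            (name, s.start, s.end, s.label, 0, s.orientation if s.orientation != "." else "+")
            for name, segs in sorted(self.segments.items())
            for s in segs
        ]
        write_bed(rows, path)


# --------------------------------------------------------------------------
# chassis: the seed-determined base sequences shared by every architecture


@dataclass(frozen=True)
class _Chassis:
    template_a: str
    template_b: str
    markers: list[tuple[int, str, str]]
    chr1_core: str  # locus A already planted
    chr2_base: str  # no template material
    extra_cores: list[str]
    locus_a_start: int  # within chr1_core
    control_start: int  # within chr1_core


def _build_chassis(config: SimConfig) -> _Chassis:
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), _CHASSIS_STREAM]))
    lt = config.template_length
    template_a = random_dna(rng, lt)

    markers: list[tuple[int, str, str]] = []
    template_b = template_a
    if config.paralog_marker_count:
        m, margin = config.paralog_marker_count, config.marker_edge_margin
        step = (lt - 2 * margin) / m
        positions = sorted({int(margin + (i + 0.5) * step) for i in range(m)})
        b = bytearray(template_a.encode())
        for p in positions:
            a_allele = template_a[p]
            b_allele = _MARKER_SUBST[a_allele]
            b[p] = ord(b_allele)
            markers.append((p, a_allele, b_allele))
        template_b = b.decode()

    chr1 = bytearray(random_dna(rng, config.chrom_length).encode())
    locus_a_start = config.chrom_length // 2
    control_start = config.chrom_length // 5
    chr1[locus_a_start : locus_a_start + lt] = template_a.encode()
    chr2_base = random_dna(rng, config.chrom_length - lt - config.spacer_length)
    extra = [random_dna(rng, config.chrom_length) for _ in range(config.n_chromosomes - 2)]
    return _Chassis(
        template_a=template_a,
        template_b=template_b,
        markers=markers,
        chr1_core=chr1.decode(),
        chr2_base=chr2_base,
        extra_cores=extra,
        locus_a_start=locus_a_start,
        control_start=control_start,
    )


class _Assembler:
    """Concatenates labelled blocks and records their coordinates."""

    def __init__(self) -> None:
        self.parts: list[str] = []
        self.segments: list[Segment] = []
        self.pos = 0

    def add(self, label: str, seq: str, orientation: str = ".") -> None:
        if not seq:
            return
        self.segments.append(Segment(label, self.pos, self.pos + len(seq), orientation))
        self.parts.append(seq)
        self.pos += len(seq)

    def sequence(self) -> str:
        return "".join(self.parts)


def _telomere_tract(config: SimConfig, n_units: int, side: str) -> str:
    """Terminal telomere repeats: G-rich unit on the right end of the forward
    strand, its complement on the left end."""
    unit = config.telomere_unit if side == "R" else revcomp(config.telomere_unit)
    return unit * n_units


def _pre_alt_units(config: SimConfig) -> int:
    return max(1, round(config.pre_alt_telomere_length / len(config.telomere_unit)))


def _selected_template(config: SimConfig, chassis: _Chassis) -> str:
    return chassis.template_a if config.selected_paralog == "A" else chassis.template_b


def _array_copy(template: str, side: str, orientation: str) -> tuple[str, str]:
    """Sequence and strand of one array copy.

    ``forward`` points the template head (5') toward the chromosome terminus:
    reverse-complemented on the q (right) end, as-is on the p (left) end.
    """
    head_to_telomere = orientation == "forward"
    if side == "R":
        return (revcomp(template), "-") if head_to_telomere else (template, "+")
    return (template, "+") if head_to_telomere else (revcomp(template), "-")


def _build_end_array(asm: _Assembler, config: SimConfig, chassis: _Chassis, side: str) -> None:
    """Tandem template array for one rebuilt chromosome end."""
    template = _selected_template(config, chassis)
    label = f"template_{config.selected_paralog}"
    copy_seq, strand = _array_copy(template, side, config.array_orientation)
    spacer = _telomere_tract(config, config.spacer_units_between_copies, side)
    terminal = _telomere_tract(config, config.terminal_telomere_units, side)
    if side == "L":
        asm.add("telomere_repeat", terminal)
        for _ in range(config.alt_copies_per_end):
            asm.add(label, copy_seq, strand)
            asm.add("spacer", spacer)
    else:
        for _ in range(config.alt_copies_per_end):
            asm.add("spacer", spacer)
            asm.add(label, copy_seq, strand)
        asm.add("telomere_repeat", terminal)


def _assemble_chromosome(
    config: SimConfig, chassis: _Chassis, chrom_index: int, architecture: str
) -> tuple[str, list[Segment]]:
    """One haploid chromosome blueprint; chromosomes are 1-based."""
    asm = _Assembler()
    alt_left = architecture == "alt" and (config.alt_all_ends or chrom_index == 2)
    alt_right = alt_left
    pre_units = _pre_alt_units(config)

    if alt_left:
        _build_end_array(asm, config, chassis, "L")
    else:
        asm.add("telomere_repeat", _telomere_tract(config, pre_units, "L"))

    if chrom_index == 1:
        la, lt = chassis.locus_a_start, config.template_length
        asm.add("subtelomere", chassis.chr1_core[:la])
        asm.add("template_A", chassis.template_a, "+")
        asm.add("subtelomere", chassis.chr1_core[la + lt :])
    elif chrom_index == 2:
        asm.add("subtelomere", chassis.chr2_base)
        if architecture == "pre_alt":
            # the natural subterminal paralog-B locus, joined to the
            # subtelomere by a short tract of telomere repeats
            asm.add("spacer", _telomere_tract(config, config.spacer_units_between_copies, "R"))
            seq, strand = _array_copy(chassis.template_b, "R", config.array_orientation)
            asm.add("template_B", seq, strand)
    else:
        asm.add("subtelomere", chassis.extra_cores[chrom_index - 3])

    if alt_right:
        _build_end_array(asm, config, chassis, "R")
    else:
        asm.add("telomere_repeat", _telomere_tract(config, pre_units, "R"))
    return asm.sequence(), asm.segments


def _end_telomere_bases(segments: Sequence[Segment]) -> tuple[int, int]:
    """Telomere-repeat bases (incl. array spacers) in each terminal complex."""

    def scan(segs: Iterable[Segment]) -> int:
        total = 0
        for s in segs:
            if s.label == "subtelomere":
                break
            if s.label in ("telomere_repeat", "spacer"):
                total += s.end - s.start
        return total

    return scan(segments), scan(reversed(segments))


def _build_genome(config: SimConfig, architecture: str) -> tuple[list[Contig], SimTruth]:
    config.validate()
    chassis = _build_chassis(config)
    contigs: list[Contig] = []
    segments: dict[str, list[Segment]] = {}
    per_end: dict[str, int] = {}
    for ci in range(1, config.n_chromosomes + 1):
        seq, segs = _assemble_chromosome(config, chassis, ci, architecture)
        left, right = _end_telomere_bases(segs)
        for hap in (1, 2):
            name = f"chr{ci}_h{hap}"
            contigs.append(Contig(name, seq))
            segments[name] = list(segs)
            per_end[f"{name}:L"] = left
            per_end[f"{name}:R"] = right

    n_template = sum(1 for segs in segments.values() for s in segs if s.label.startswith("template"))
    pre_units = _pre_alt_units(config)
    telo_len = pre_units * len(config.telomere_unit)
    locus_a = GenomicInterval(
        "chr1", telo_len + chassis.locus_a_start, telo_len + chassis.locus_a_start + config.template_length
    )
    control = GenomicInterval(
        "chr1", telo_len + chassis.control_start, telo_len + chassis.control_start + config.template_length
    )
    truth = SimTruth(
        architecture=architecture,
        ploidy=2,
        segments=segments,
        copy_number=n_template / 2,
        selected_paralog=config.selected_paralog,
        markers=chassis.markers,
        expected_junction_class="HEAD_TO_TAIL" if architecture == "alt" else None,
        expected_orientation=(
            ("FORWARD" if config.array_orientation == "forward" else "REVERSE")
            if architecture == "alt"
            else None
        ),
        per_end_telomere_bases=per_end,
        template_locus_ref=locus_a,
        control_locus_ref=control,
        marker_sites_ref=[
            ("chr1", locus_a.start + p, a, b) for p, a, b in chassis.markers
        ],
    )
    return contigs, truth


def build_pre_alt_genome(config: SimConfig) -> tuple[list[Contig], SimTruth]:
    """Diploid genome before ALT: two template copies, long terminal telomeres."""
    return _build_genome(config, "pre_alt")


def build_alt_genome(config: SimConfig) -> tuple[list[Contig], SimTruth]:
    """Diploid genome after ALT: chromosome-2 ends rebuilt as tandem
    head-to-tail arrays of the selected paralog (all ends if ``alt_all_ends``)."""
    return _build_genome(config, "alt")


def build_reference_genome(config: SimConfig) -> list[Contig]:
    """Haploid mapping reference carrying only the interstitial paralog-A locus,
    the analogue of a reference assembly from a strain without the subterminal
    copy."""
    config.validate()
    chassis = _build_chassis(config)
    pre_units = _pre_alt_units(config)
    left = _telomere_tract(config, pre_units, "L")
    right = _telomere_tract(config, pre_units, "R")
    contigs = [Contig("chr1", left + chassis.chr1_core + right)]
    contigs.append(Contig("chr2", left + chassis.chr2_base + right))
    for i, core in enumerate(chassis.extra_cores, start=3):
        contigs.append(Contig(f"chr{i}", left + core + right))
    return contigs


# --------------------------------------------------------------------------
# read simulation


def simulate_reads(genome: Sequence[Contig], config: SimConfig) -> list["ReadPair"]:
    """Paired-end reads over the given contigs.

    Pair count is ``round(total_bases * coverage / (2 * read_length))``;
    fragments fall uniformly within contigs (length-weighted across contigs)
    with truncated-normal lengths; mate 1 reports the fragment start on the
    forward strand, mate 2 the reverse complement of the fragment end.
    """
    from .telreads import ReadPair

    config.validate()
    if not genome:
        raise ConfigurationError("genome must contain at least one contig")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), _READ_STREAM]))
    rl = config.read_length
    total = sum(len(c) for c in genome)
    n_pairs = round(total * config.coverage / (2 * rl))
    weights = np.array([len(c) for c in genome], dtype=float) / total
    counts = rng.multinomial(n_pairs, weights)
    qual = chr(30 + 33) * rl  # constant Q30

    pairs: list[ReadPair] = []
    idx = 0
    for contig, n in zip(genome, counts):
        if n == 0:
            continue
        cbytes = contig.sequence.encode()
        clen = len(cbytes)
        lens = np.rint(rng.normal(config.fragment_mean, config.fragment_sd, size=n)).astype(np.int64)
        lens = np.clip(lens, 2 * rl, clen)
        starts = (rng.random(n) * (clen - lens + 1)).astype(np.int64)
        nerr = (
            rng.binomial(rl, config.substitution_error_rate, size=(n, 2))
            if config.substitution_error_rate > 0
            else np.zeros((n, 2), dtype=np.int64)
        )
        for j in range(n):
            s, e = int(starts[j]), int(starts[j] + lens[j])
            m1 = cbytes[s : s + rl]
            m2 = revcomp_bytes(cbytes[e - rl : e])
            e1, e2 = int(nerr[j, 0]), int(nerr[j, 1])
            if e1:
                m1 = _substitute(m1, rng, e1)
            if e2:
                m2 = _substitute(m2, rng, e2)
            pairs.append(
                ReadPair(
                    id=f"frag{idx:07d}:{contig.name}:{s}-{e}",
                    mate1_seq=m1.decode(),
                    mate2_seq=m2.decode(),
                    mate1_qual=qual,
                    mate2_qual=qual,
                )
            )
            idx += 1
    return pairs


_BASES = b"ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}


def _substitute(seq: bytes, rng: np.random.Generator, n_errors: int) -> bytes:
    out = bytearray(seq)
    positions = rng.integers(0, len(seq), size=n_errors)
    shifts = rng.integers(1, 4, size=n_errors)
    for p, sh in zip(positions, shifts):
        old = _CODE.get(out[p])
        if old is None:  # leave N untouched
            continue
        out[p] = _BASES[(old + int(sh)) % 4]
    return bytes(out)
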