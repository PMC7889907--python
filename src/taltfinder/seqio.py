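"""Reading and writing of the plain-text formats the pipeline exchanges.

FASTA goes through Biopython; FASTQ writing is a tight local loop because the
simulator emits hundreds of thousands of records and needs nothing beyond
Phred+33 plain text.  Tabular outputs are TSV with a single ``#``-prefixed
header line so they survive both pandas and awk.
"""

from __future__ import annotations

import os
from typing import TYPE_CHECKING, Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import Contig, DataError

if TYPE_CHECKING:  # pragma: no cover
    from .telreads import ReadPair


def write_fasta(contigs: Iterable[Contig], path: str | os.PathLike) -> None:
    """Write contigs as 60-column wrapped FASTA."""
    records = [SeqRecord(Seq(c.sequence), id=c.name, description="") for c in contigs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def read_fasta(path: str | os.PathLike) -> list[Contig]:
    return [Contig(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fastq_pair(pairs: Iterable["ReadPair"], r1_path: str, r2_path: str) -> int:
    """Write mates to two FASTQ files with /1 and /2 id suffixes; returns count."""
    n = 0
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.id}/1\n{p.mate1_seq}\n+\n{p.mate1_qual}\n")
            f2.write(f"@{p.id}/2\n{p.mate2_seq}\n+\n{p.mate2_qual}\n")
            n += 1
    return n


def read_fastq_pair(r1_path: str, r2_path: str) -> Iterator["ReadPair"]:
    """Stream mate pairs from two parallel FASTQ files."""
    from .telreads import ReadPair  # local import to avoid a cycle

    with open(r1_path) as f1, open(r2_path) as f2:
        it1, it2 = SeqIO.parse(f1, "fastq"), SeqIO.parse(f2, "fastq")
        for r1, r2 in zip(it1, it2, strict=True):
            id1 = r1.id.removesuffix("/1")
            id2 = r2.id.removesuffix("/2")
            if id1 != id2:
                raise DataError(f"mate id mismatch: {r1.id} vs {r2.id}")
            yield ReadPair(
                id=id1,
                mate1_seq=str(r1.seq).upper(),
                mate2_seq=str(r2.seq).upper(),
                mate1_qual="".join(chr(q + 33) for q in r1.letter_annotations["phred_quality"]),
                mate2_qual="".join(chr(q + 33) for q in r2.letter_annotations["phred_quality"]),
            )


def write_bed(rows: Iterable[tuple], path: str | os.PathLike) -> None:
    """Write (contig, start, end[, name[, score[, strand]]]) rows as BED."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """TSV with one '#'-prefixed header line."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().lstrip("#").rstrip("\n").split("\t")
        return pd.read_csv(fh, sep="\t", names=header)
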