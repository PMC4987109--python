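"""Sequence I/O and small-format writers (FASTA, FASTQ, BED6, GFF3, TSV).

Internally every coordinate is 0-based half-open; the GFF3 writer converts
to 1-based inclusive at the boundary and nowhere else.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (result in DNA alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class FastqRecord:
    id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"FASTQ record {self.id!r}: sequence and quality lengths differ"
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> uppercase sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str] | Iterable[tuple[str, str]],
                path: str | Path, width: int = 70) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_fastq(path: str | Path) -> Iterator[FastqRecord]:
    """Stream FASTQ records; malformed records raise with their index."""
    for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
        try:
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            yield FastqRecord(rec.id, str(rec.seq).upper(), qual)
        except (KeyError, ValueError) as exc:  # pragma: no cover - defensive
            raise ValueError(f"malformed FASTQ record at index {i}: {exc}") from exc


def write_fastq(records: Iterable[FastqRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{rec.qual}\n")


def fastq_to_string(records: Iterable[FastqRecord]) -> str:
    buf = io.StringIO()
    for rec in records:
        buf.write(f"@{rec.id}\n{rec.seq}\n+\n{rec.qual}\n")
    return buf.getvalue()


@dataclass
class BedInterval:
    """A BED6 feature; start/end are 0-based half-open, as in BED itself."""

    chrom: str
    start: int
    end: int
    name: str
    score: float = 0.0
    strand: str = "+"


def write_bed6(intervals: Iterable[BedInterval], path: str | Path,
               header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}"
                     f"\t{iv.score:g}\t{iv.strand}\n")


@dataclass
class Gff3Feature:
    """A GFF3 feature carried in internal 0-based half-open coordinates."""

    seqid: str
    type: str
    start: int
    end: int
    strand: str
    attributes: dict[str, str]
    score: str = "."
    source: str = "mirdup"


def write_gff3(features: Iterable[Gff3Feature], path: str | Path,
               header: str | None = None) -> None:
    """Write GFF3, converting to the format's 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if header:
            fh.write(f"#{header}\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items())
            fh.write(f"{f.seqid}\t{f.source}\t{f.type}\t{f.start + 1}\t{f.end}"
                     f"\t{f.score}\t{f.strand}\t.\t{attrs}\n")
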