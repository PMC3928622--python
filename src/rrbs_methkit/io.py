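"""Standard-format adapters: FASTA, FASTQ, BED6, GFF3, bedGraph, TSV.

All genomic intervals inside the package are 0-based half-open; these
adapters are the only place coordinates are translated for on-disk
conventions (BED and bedGraph are natively 0-based half-open; report TSVs
use the single-base start/start+1 style).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Raised on malformed input files; message carries the line number."""


# ---------------------------------------------------------------- FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: uppercase sequence} dict."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise FormatError(f"{path}: no FASTA records found")
    return seqs


def write_fasta(path: str | Path, seqs: dict[str, str] | Iterable[tuple[str, str]],
                width: int = 70) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    del width  # Biopython controls wrapping


# ---------------------------------------------------------------- FASTQ


@dataclass(frozen=True)
class FastqRecord:
    read_id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise FormatError(
                f"read {self.read_id}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}")


def read_fastq(path: str | Path) -> Iterator[FastqRecord]:
    """Parse 4-line FASTQ, validating structure and reporting line numbers."""
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            if not header.startswith("@"):
                raise FormatError(f"{path}:{lineno}: expected '@' header, got {header[:20]!r}")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not qual and not plus:
                raise FormatError(f"{path}:{lineno}: truncated record")
            lineno += 3
            if not plus.startswith("+"):
                raise FormatError(f"{path}:{lineno - 1}: expected '+' separator")
            if len(seq) != len(qual):
                raise FormatError(
                    f"{path}:{lineno}: quality length {len(qual)} does not match "
                    f"sequence length {len(seq)}")
            yield FastqRecord(header[1:].split()[0], seq.upper(), qual)


def write_fastq(path: str | Path, records: Iterable[FastqRecord]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.read_id}\n{rec.seq}\n+\n{rec.qual}\n")


# ---------------------------------------------------------------- BED


@dataclass(frozen=True)
class BedRecord:
    contig: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError(
                f"BED interval {self.contig}:{self.start}-{self.end}: end <= start")


def read_bed6(path: str | Path) -> list[BedRecord]:
    out: list[BedRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has fewer than 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = parts[3] if len(parts) > 3 else "."
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            strand = parts[5] if len(parts) > 5 else "."
            try:
                out.append(BedRecord(parts[0], start, end, name, score, strand))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed6(path: str | Path, records: Iterable[BedRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{r.name}\t{r.score:g}\t{r.strand}\n")


# ---------------------------------------------------------------- GFF3


def read_gff3_genes(path: str | Path) -> tuple[list[BedRecord], list[BedRecord]]:
    """Extract gene and exon features from a GFF3 file as BED-like records.

    Exon names carry the parent gene id so exons can be grouped per gene.
    """
    genes: list[BedRecord] = []
    exons: list[BedRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: GFF3 line has {len(parts)} columns, expected 9")
            contig, _, ftype, start, end, _, strand, _, attrs = parts
            try:
                start_i, end_i = int(start) - 1, int(end)  # GFF3 is 1-based closed
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                genes.append(BedRecord(contig, start_i, end_i,
                                       attr.get("ID", attr.get("Name", ".")), 0.0, strand))
            elif ftype == "exon":
                exons.append(BedRecord(contig, start_i, end_i,
                                       attr.get("Parent", "."), 0.0, strand))
    return genes, exons


def write_gff3_genes(path: str | Path, genes: Iterable[BedRecord],
                     exons: Iterable[BedRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.contig}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t."
                     f"\tID={g.name}\n")
        for e in exons:
            fh.write(f"{e.contig}\tsim\texon\t{e.start + 1}\t{e.end}\t.\t{e.strand}\t."
                     f"\tParent={e.name}\n")


# ---------------------------------------------------------------- bedGraph


def write_bedgraph(path: str | Path, rows: Iterable[tuple[str, int, int, float]],
                   track_name: str = "methylation") -> None:
    """Write a bedGraph track. Rows must be (contig, start, end, value)."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track_name}"\n')
        for contig, start, end, value in rows:
            if end <= start:
                raise FormatError(f"bedGraph interval {contig}:{start}-{end}: end <= start")
            fh.write(f"{contig}\t{start}\t{end}\t{value:.6g}\n")


def validate_bedgraph(path: str | Path) -> int:
    """Strictly validate a bedGraph file; returns the number of data rows.

    Checks start < end on every row and sorted, non-overlapping intervals
    per contig.
    """
    n = 0
    last: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            float(parts[3])
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            if start < last.get(contig, -1):
                raise FormatError(f"{path}:{lineno}: intervals not sorted on {contig}")
            last[contig] = end
            n += 1
    return n


# ---------------------------------------------------------------- TSV


def write_tsv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, quoting=csv.QUOTE_NONE)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
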