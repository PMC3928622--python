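"""Per-cytosine methylation calling from kept alignments.

The methylation level of a cytosine is the number of reads reporting C
divided by the reads reporting C or T; reads showing any other base at the
site are excluded. Context (CpG / CHG / CHH, H in {A, C, T}) is classified
from the unconverted reference genome, never from reads. Top- and
bottom-strand cytosines are separate records throughout.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from rrbs_methkit import io as mkio
from rrbs_methkit.align import AlignmentHit
from rrbs_methkit.digest import ReferenceDB

CALL_COLUMNS = ["contig", "pos", "strand", "context", "count_C", "count_T"]


def classify_context(seq: str, pos: int, strand: str) -> str | None:
    """Classify the context of the cytosine at `pos` on `strand`.

    `seq` is the unconverted top-strand reference. Returns "CpG", "CHG" or
    "CHH", or None when the two downstream bases are unavailable or contain
    N (such sites are skipped by the pileup).
    """
    if strand == "+":
        if seq[pos] != "C":
            raise ValueError(f"no C at +{pos}")
        if pos + 2 >= len(seq):
            return None
        nxt, nxt2 = seq[pos + 1], seq[pos + 2]
    elif strand == "-":
        if seq[pos] != "G":
            raise ValueError(f"no C at -{pos} (top-strand base must be G)")
        if pos - 2 < 0:
            return None
        # downstream on the bottom strand = upstream on top, complemented
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        nxt = comp.get(seq[pos - 1], "N")
        nxt2 = comp.get(seq[pos - 2], "N")
    else:
        raise ValueError(f"bad strand {strand!r}")
    if "N" in (nxt, nxt2):
        return None
    if nxt == "G":
        return "CpG"
    if nxt2 == "G":
        return "CHG"
    return "CHH"


def pileup(kept: Iterable[tuple[str, AlignmentHit]], db: ReferenceDB,
           genome: Mapping[str, str]) -> pd.DataFrame:
    """Accumulate C/T counts at every reference cytosine covered by kept reads.

    `kept` yields (raw read sequence, resolved hit) pairs — one pair per
    kept read, so each read contributes at most once per site even where
    fragment-end entries overlap. Returns a calls table with one row per
    (contig, pos, strand) and a `level` column.
    """
    counts: dict[tuple[str, int, str], list[int]] = {}
    for raw_seq, hit in kept:
        entry = db.by_id(hit.entry_id)
        ref = entry.raw_seq
        strand = "+" if entry.strand == "top" else "-"
        for i, read_base in enumerate(raw_seq):
            j = hit.offset + i
            if ref[j] != "C":
                continue
            if read_base == "C":
                slot = 0
            elif read_base == "T":
                slot = 1
            else:
                continue  # sequencing error to another base: excluded
            key = (entry.contig, entry.genome_coord(j), strand)
            counts.setdefault(key, [0, 0])[slot] += 1
    rows = []
    for (contig, pos, strand), (c, t) in sorted(counts.items()):
        ctx = classify_context(genome[contig], pos, strand)
        if ctx is None:
            continue
        rows.append({"contig": contig, "pos": pos, "strand": strand,
                     "context": ctx, "count_C": c, "count_T": t})
    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return finalize_calls(df)


def finalize_calls(df: pd.DataFrame) -> pd.DataFrame:
    """Attach coverage/level columns and drop zero-coverage rows."""
    df = df[df["count_C"] + df["count_T"] >= 1].copy()
    df["coverage"] = df["count_C"] + df["count_T"]
    df["level"] = df["count_C"] / df["coverage"]
    return df.sort_values(["contig", "pos", "strand"]).reset_index(drop=True)


def pool_calls(call_tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Pool replicate call tables by summing C/T counts per site."""
    if not call_tables:
        raise ValueError("nothing to pool")
    cat = pd.concat([t[CALL_COLUMNS] for t in call_tables], ignore_index=True)
    pooled = (cat.groupby(["contig", "pos", "strand", "context"], as_index=False)
              [["count_C", "count_T"]].sum())
    return finalize_calls(pooled)


def export_tracks(calls: pd.DataFrame, out_prefix: str | Path,
                  track_name: str = "methylation") -> tuple[Path, Path]:
    """Write a bedGraph track and a full TSV for a calls table.

    TSV positions use the single-base (start, end = start + 1) convention.
    """
    out_prefix = Path(out_prefix)
    bg_path = out_prefix.with_suffix(".bedGraph")
    tsv_path = out_prefix.with_suffix(".tsv")
    ordered = calls.sort_values(["contig", "pos", "strand"])
    mkio.write_bedgraph(
        bg_path,
        ((r.contig, int(r.pos), int(r.pos) + 1, float(r.level))
         for r in ordered.drop_duplicates(["contig", "pos"]).itertuples()),
        track_name=track_name)
    table = ordered.copy()
    table.insert(1, "start", table.pop("pos"))
    table.insert(2, "end", table["start"] + 1)
    mkio.write_tsv(tsv_path, table[["contig", "start", "end", "strand", "context",
                                    "count_C", "count_T", "level"]])
    return bg_path, tsv_path


def read_calls(path: str | Path) -> pd.DataFrame:
    """Read a calls TSV written by :func:`export_tracks` back into the
    internal representation (pos = start)."""
    table = mkio.read_tsv(path)
    if len(table) == 0:
        return pd.DataFrame(columns=CALL_COLUMNS + ["coverage", "level"])
    df = table.rename(columns={"start": "pos"})[CALL_COLUMNS]
    return finalize_calls(df)
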