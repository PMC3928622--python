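"""Bisulfite-aware three-letter read alignment.

Reads are fully C->T converted (noting each conversion) and matched
ungapped against the converted fragment-end reference. Mismatches are then
recounted between the UNconverted read and reference, ignoring read-T /
reference-C pairs (the bisulfite-compatible case) but counting read-C /
reference-T. A read is kept only when its best placement beats the second
best by the uniqueness margin (default 2 mismatches).

The candidate search is exact: a pigeonhole seed index (max_mismatches + 1
read chunks, one of which must match exactly in any placement within the
mismatch budget) prunes the scan without losing hits; short reads fall back
to a full scan over every offset of every entry.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from rrbs_methkit.digest import ReferenceDB, convert_c_to_t


@dataclass(frozen=True)
class AlignConfig:
    max_mismatches: int = 3
    uniqueness_margin: int = 2   # "second best at least this many more mismatches"
    seed_length: int = 20        # below this read length the index is bypassed

    def __post_init__(self) -> None:
        if self.uniqueness_margin < 1:
            raise ValueError("uniqueness_margin must be >= 1")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass(frozen=True)
class ConvertedRead:
    read_id: str
    raw_seq: str
    conv_seq: str
    converted_positions: tuple[int, ...]


@dataclass(frozen=True)
class AlignmentHit:
    entry_id: str
    offset: int
    strand: str
    conv_mismatches: int
    bs_mismatches: int | None = None


def convert_read(read_id: str, raw_seq: str) -> ConvertedRead:
    """C->T convert a read, recording which positions were converted."""
    raw_seq = raw_seq.upper()
    positions = tuple(i for i, b in enumerate(raw_seq) if b == "C")
    return ConvertedRead(read_id, raw_seq, convert_c_to_t(raw_seq), positions)


def hamming(a: str, b: str, limit: int | None = None) -> int:
    """Mismatch count between equal-length strings; N always mismatches.

    With `limit`, stops early once the count exceeds it (the exact value
    above limit is not needed by callers).
    """
    n = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            n += 1
            if limit is not None and n > limit:
                return n
    return n


def bisulfite_mismatches(read_raw: str, ref_raw: str) -> int:
    """Mismatches between unconverted read and reference under the
    bisulfite rule: read T over reference C is compatible (not counted);
    read C over reference T IS counted; N always counts."""
    n = 0
    for r, g in zip(read_raw, ref_raw):
        if r == g and r != "N":
            continue
        if r == "T" and g == "C":
            continue
        n += 1
    return n


def recount_bisulfite(hit: AlignmentHit, read_raw: str, ref_raw_entry: str) -> AlignmentHit:
    """Attach the unconverted-space mismatch count to a converted-space hit."""
    window = ref_raw_entry[hit.offset:hit.offset + len(read_raw)]
    return replace(hit, bs_mismatches=bisulfite_mismatches(read_raw, window))


def resolve_unique(hits: Sequence[AlignmentHit], cfg: AlignConfig) -> AlignmentHit | None:
    """Keep the best hit iff the second best has >= uniqueness_margin more
    (bisulfite-recounted) mismatches; ties or close seconds discard the read."""
    if not hits:
        return None
    ranked = sorted(hits, key=lambda h: (h.bs_mismatches, h.entry_id, h.offset))
    if len(ranked) == 1:
        return ranked[0]
    if ranked[1].bs_mismatches - ranked[0].bs_mismatches >= cfg.uniqueness_margin:
        return ranked[0]
    return None


class Aligner:
    """Exact ungapped aligner over a converted fragment-end reference."""

    def __init__(self, db: ReferenceDB, cfg: AlignConfig | None = None) -> None:
        self.db = db
        self.cfg = cfg or AlignConfig()
        self._indexes: dict[int, dict] = {}  # read length -> pigeonhole index

    # -- candidate search ------------------------------------------------

    def _windows(self, read_len: int) -> list[tuple[int, int]]:
        """All (entry index, offset) placements admitting this read length."""
        out = []
        for ei, entry in enumerate(self.db.entries):
            for off in range(len(entry.conv_seq) - read_len + 1):
                out.append((ei, off))
        return out

    def _build_index(self, read_len: int) -> dict:
        """Pigeonhole index: for each of k = max_mm + 1 read chunks, map the
        chunk substring of every reference window to the window id."""
        k = self.cfg.max_mismatches + 1
        step = read_len // k
        chunks = [(j * step, (j + 1) * step if j < k - 1 else read_len) for j in range(k)]
        buckets: list[dict[str, list[tuple[int, int]]]] = [defaultdict(list) for _ in chunks]
        for ei, entry in enumerate(self.db.entries):
            seq = entry.conv_seq
            for off in range(len(seq) - read_len + 1):
                for j, (a, b) in enumerate(chunks):
                    buckets[j][seq[off + a:off + b]].append((ei, off))
        return {"chunks": chunks, "buckets": buckets}

    def candidate_hits(self, conv_read: ConvertedRead) -> list[AlignmentHit]:
        """All placements with converted-space mismatches <= max_mismatches.

        Exact: the seed index is lossless up to max_mismatches; reads
        shorter than seed_length (or too short to chunk) use the full scan.
        """
        read = conv_read.conv_seq
        L = len(read)
        use_index = L >= max(self.cfg.seed_length, self.cfg.max_mismatches + 1)
        if use_index:
            if L not in self._indexes:
                self._indexes[L] = self._build_index(L)
            idx = self._indexes[L]
            cand: set[tuple[int, int]] = set()
            for j, (a, b) in enumerate(idx["chunks"]):
                cand.update(idx["buckets"][j].get(read[a:b], ()))
        else:
            cand = set(self._windows(L))
        hits = []
        maxmm = self.cfg.max_mismatches
        for ei, off in cand:
            entry = self.db.entries[ei]
            mm = hamming(read, entry.conv_seq[off:off + L], limit=maxmm)
            if mm <= maxmm:
                hits.append(AlignmentHit(entry.entry_id, off, entry.strand, mm))
        hits.sort(key=lambda h: (h.entry_id, h.offset))
        return hits

    # -- full per-read pipeline -----------------------------------------

    def align_read(self, read_id: str, raw_seq: str) -> tuple[AlignmentHit | None, list[AlignmentHit]]:
        """Convert, search, recount, and resolve one read.

        Returns (kept hit or None, all recounted candidates).
        """
        conv = convert_read(read_id, raw_seq)
        candidates = self.candidate_hits(conv)
        recounted = [recount_bisulfite(h, conv.raw_seq, self.db.by_id(h.entry_id).raw_seq)
                     for h in candidates]
        return resolve_unique(recounted, self.cfg), recounted

    def align_many(self, reads: Iterable[tuple[str, str]]) -> pd.DataFrame:
        """Align reads; one row per read with the verdict.

        Columns: read_id, verdict ({unique, non-unique, unmapped}), entry_id,
        offset, strand, bs_mismatches (entry fields empty unless unique).
        """
        rows = []
        for read_id, seq in reads:
            kept, cands = self.align_read(read_id, seq)
            if kept is not None:
                rows.append({"read_id": read_id, "verdict": "unique",
                             "entry_id": kept.entry_id, "offset": kept.offset,
                             "strand": kept.strand, "bs_mismatches": kept.bs_mismatches})
            else:
                rows.append({"read_id": read_id,
                             "verdict": "non-unique" if cands else "unmapped",
                             "entry_id": "", "offset": -1, "strand": "",
                             "bs_mismatches": -1})
        return pd.DataFrame(rows, columns=["read_id", "verdict", "entry_id",
                                           "offset", "strand", "bs_mismatches"])
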