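"""In-silico restriction digest and converted fragment-end reference.

The digest models sequential MspI (C^CGG) + TaqI (T^CGA) cutting as the
union of both enzymes' cut sites; size selection keeps fragments of
40-350 bp flanked by enzyme cuts on both sides. The alignment reference is
the set of <=50-bp fragment-end sequences on both strands with every C
replaced by T.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from rrbs_methkit import io as mkio

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme: recognition site and cut offset within it."""
    name: str
    site: str
    cut_offset: int


MSPI = EnzymeSpec("MspI", "CCGG", 1)
TAQI = EnzymeSpec("TaqI", "TCGA", 1)
CONTIG_END = "contig-end"


@dataclass(frozen=True)
class DigestConfig:
    size_min: int = 40
    size_max: int = 350
    end_length: int = 50
    enzymes: tuple[EnzymeSpec, ...] = (TAQI, MSPI)

    def __post_init__(self) -> None:
        if not (0 < self.size_min < self.size_max):
            raise ValueError("require 0 < size_min < size_max")
        if self.end_length <= 0:
            raise ValueError("end_length must be positive")


@dataclass(frozen=True)
class Fragment:
    contig: str
    start: int  # 0-based half-open
    end: int
    left_enzyme: str
    right_enzyme: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"fragment {self.contig}:{self.start}-{self.end}: end <= start")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def fragment_id(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}"


def find_sites(seq: str, enzyme: EnzymeSpec) -> list[int]:
    """Return every cut coordinate of `enzyme` in `seq`, in order.

    Overlapping recognition-site occurrences are all reported. N never
    matches (the scan compares exact uppercase bases only).
    """
    site = enzyme.site
    cuts = []
    pos = seq.find(site)
    while pos != -1:
        cuts.append(pos + enzyme.cut_offset)
        pos = seq.find(site, pos + 1)
    return cuts


def digest(genome: Mapping[str, str], cfg: DigestConfig | None = None) -> list[Fragment]:
    """Digest every contig at the union of all enzymes' cut sites.

    Returns ALL fragments, including the two contig-end fragments, labeled
    with their flanking enzymes. Concatenating the fragments of one contig
    reconstructs it exactly. Apply :func:`size_select` for the analysis set.
    """
    cfg = cfg or DigestConfig()
    fragments: list[Fragment] = []
    for contig, seq in genome.items():
        cutmap: dict[int, str] = {}
        for enz in cfg.enzymes:
            for cut in find_sites(seq, enz):
                # identical cut coordinate from two enzymes cannot happen for
                # MspI/TaqI (sites differ at the cut base); keep first label
                cutmap.setdefault(cut, enz.name)
        bounds = [(0, CONTIG_END)] + sorted(cutmap.items()) + [(len(seq), CONTIG_END)]
        for (start, left), (end, right) in zip(bounds, bounds[1:]):
            if end > start:
                fragments.append(Fragment(contig, start, end, left, right))
    return fragments


def size_select(fragments: Iterable[Fragment], cfg: DigestConfig | None = None) -> list[Fragment]:
    """Keep fragments inside [size_min, size_max] with enzyme cuts at BOTH ends."""
    cfg = cfg or DigestConfig()
    return [f for f in fragments
            if cfg.size_min <= f.length <= cfg.size_max
            and f.left_enzyme != CONTIG_END and f.right_enzyme != CONTIG_END]


@dataclass(frozen=True)
class FragmentEndRef:
    """One strand-specific fragment-end reference entry.

    `raw_seq` reads 5'->3' on `strand`; `conv_seq` is raw_seq with C->T.
    `genome_start`/`genome_end` bound the entry on top-strand coordinates;
    position i of the entry maps to genome coordinate
    genome_start + i (top) or genome_end - 1 - i (bottom).
    """
    entry_id: str
    fragment_id: str
    contig: str
    which_end: str  # 5prime | 3prime | whole (ends coincide)
    strand: str     # top | bottom
    raw_seq: str
    conv_seq: str
    genome_start: int
    genome_end: int

    def genome_coord(self, i: int) -> int:
        if not 0 <= i < len(self.raw_seq):
            raise IndexError(i)
        if self.strand == "top":
            return self.genome_start + i
        return self.genome_end - 1 - i

    def offset_map(self) -> list[int]:
        return [self.genome_coord(i) for i in range(len(self.raw_seq))]


def convert_c_to_t(seq: str) -> str:
    return seq.replace("C", "T")


@dataclass
class ReferenceDB:
    """The converted fragment-end reference database."""
    entries: list[FragmentEndRef] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def by_id(self, entry_id: str) -> FragmentEndRef:
        if not hasattr(self, "_index"):
            self._index = {e.entry_id: e for e in self.entries}
        return self._index[entry_id]

    def to_fasta(self, path: str | Path) -> None:
        mkio.write_fasta(path, [(e.entry_id, e.conv_seq) for e in self.entries])

    def offset_table(self) -> pd.DataFrame:
        rows = [{
            "entry_id": e.entry_id, "fragment_id": e.fragment_id, "contig": e.contig,
            "which_end": e.which_end, "strand": e.strand, "raw_seq": e.raw_seq,
            "genome_start": e.genome_start, "genome_end": e.genome_end,
        } for e in self.entries]
        return pd.DataFrame(rows, columns=["entry_id", "fragment_id", "contig", "which_end",
                                           "strand", "raw_seq", "genome_start", "genome_end"])

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_fasta(directory / "reference.fa")
        mkio.write_tsv(directory / "offsets.tsv", self.offset_table())

    @classmethod
    def load(cls, directory: str | Path) -> "ReferenceDB":
        directory = Path(directory)
        table = mkio.read_tsv(directory / "offsets.tsv")
        entries = [FragmentEndRef(
            entry_id=r.entry_id, fragment_id=r.fragment_id, contig=r.contig,
            which_end=r.which_end, strand=r.strand, raw_seq=r.raw_seq,
            conv_seq=convert_c_to_t(r.raw_seq),
            genome_start=int(r.genome_start), genome_end=int(r.genome_end),
        ) for r in table.itertuples()]
        return cls(entries)


def build_reference(fragments: Iterable[Fragment], genome: Mapping[str, str],
                    cfg: DigestConfig | None = None) -> ReferenceDB:
    """Build the C->T-converted fragment-end database.

    Up to four entries per fragment (5'/3' end x top/bottom strand). When a
    fragment is no longer than end_length the two ends of a strand coincide
    and are stored once as a single "whole" entry.
    """
    cfg = cfg or DigestConfig()
    e = cfg.end_length
    entries: list[FragmentEndRef] = []
    for frag in fragments:
        top = genome[frag.contig][frag.start:frag.end]
        bottom = revcomp(top)
        length = frag.length
        if length <= e:
            spans = [("whole", "top", top, frag.start, frag.end),
                     ("whole", "bottom", bottom, frag.start, frag.end)]
        else:
            spans = [
                ("5prime", "top", top[:e], frag.start, frag.start + e),
                ("3prime", "top", top[-e:], frag.end - e, frag.end),
                ("5prime", "bottom", bottom[:e], frag.end - e, frag.end),
                ("3prime", "bottom", bottom[-e:], frag.start, frag.start + e),
            ]
        for which_end, strand, raw, gstart, gend in spans:
            entries.append(FragmentEndRef(
                entry_id=f"{frag.fragment_id}|{which_end}|{strand}",
                fragment_id=frag.fragment_id, contig=frag.contig,
                which_end=which_end, strand=strand,
                raw_seq=raw, conv_seq=convert_c_to_t(raw),
                genome_start=gstart, genome_end=gend))
    return ReferenceDB(entries)
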