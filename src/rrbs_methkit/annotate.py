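"""Genomic annotation of methylation sites.

Each site is assigned exactly one of {promoter, exon, intron, intergenic}
with precedence promoter > exon > intron > intergenic, plus an independent
CpG-island membership flag. A Gardiner-Garden–Frommer sliding-window island
detector is provided as a fallback when no island BED is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from rrbs_methkit.io import BedRecord

CATEGORIES = ("promoter", "exon", "intron", "intergenic")


@dataclass(frozen=True)
class Gene:
    name: str
    contig: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class FeatureModel:
    """Gene models, CpG islands, and the promoter window definition."""
    genes: list[Gene] = field(default_factory=list)
    islands: list[tuple[str, int, int]] = field(default_factory=list)
    promoter_upstream: int = 1000
    promoter_downstream: int = 500

    @classmethod
    def from_bed(cls, gene_records: Sequence[BedRecord],
                 exon_records: Sequence[BedRecord],
                 island_records: Sequence[BedRecord] = (),
                 promoter_upstream: int = 1000,
                 promoter_downstream: int = 500) -> "FeatureModel":
        """Build a model from BED6 genes and exons (exon name = gene name)."""
        exon_map: dict[str, list[tuple[int, int]]] = {}
        for e in exon_records:
            exon_map.setdefault(e.name, []).append((e.start, e.end))
        genes = [Gene(g.name, g.contig, g.strand, g.start, g.end,
                      tuple(sorted(exon_map.get(g.name, [(g.start, g.end)]))))
                 for g in gene_records]
        islands = [(r.contig, r.start, r.end) for r in island_records]
        return cls(genes, islands, promoter_upstream, promoter_downstream)

    def promoter_window(self, gene: Gene) -> tuple[int, int]:
        """[TSS - upstream, TSS + downstream + 1) on the gene's strand."""
        if gene.strand == "+":
            return (gene.tss - self.promoter_upstream,
                    gene.tss + self.promoter_downstream + 1)
        return (gene.tss - self.promoter_downstream,
                gene.tss + self.promoter_upstream + 1)


def assign_feature(contig: str, pos: int, model: FeatureModel) -> tuple[str, bool]:
    """Assign (category, island_flag) to one genomic position."""
    in_promoter = in_exon = in_gene = False
    for g in model.genes:
        if g.contig != contig:
            continue
        ps, pe = model.promoter_window(g)
        if ps <= pos < pe:
            in_promoter = True
        if g.start <= pos < g.end:
            in_gene = True
            if any(es <= pos < ee for es, ee in g.exons):
                in_exon = True
    if in_promoter:
        category = "promoter"
    elif in_exon:
        category = "exon"
    elif in_gene:
        category = "intron"
    else:
        category = "intergenic"
    island = any(c == contig and s <= pos < e for c, s, e in model.islands)
    return category, island


def annotate_sites(sites: pd.DataFrame, model: FeatureModel) -> pd.DataFrame:
    """Add `category` and `cpg_island` columns to a site table.

    Expects `contig` and `start` columns (single-base site convention).
    Sites on contigs absent from the model come out intergenic.
    """
    cats, isl = [], []
    for r in sites.itertuples():
        c, i = assign_feature(r.contig, int(r.start), model)
        cats.append(c)
        isl.append(i)
    out = sites.copy()
    out["category"] = cats
    out["cpg_island"] = isl
    return out


def category_distribution(annotated: pd.DataFrame) -> pd.DataFrame:
    """Category counts and fractions split by island membership and
    context class (CpG vs non-CpG i.e. CHG/CHH). Fractions sum to 1 within
    each non-empty split."""
    work = annotated.copy()
    work["context_class"] = np.where(work["context"] == "CpG", "CpG", "CHG/CHH")
    rows = []
    for (island, cclass), sub in work.groupby(["cpg_island", "context_class"]):
        counts = sub["category"].value_counts()
        total = len(sub)
        for cat in CATEGORIES:
            n = int(counts.get(cat, 0))
            rows.append({"cpg_island": island, "context_class": cclass,
                         "category": cat, "count": n, "fraction": n / total})
    return pd.DataFrame(rows, columns=["cpg_island", "context_class",
                                       "category", "count", "fraction"])


def detect_cpg_islands(seq: str, min_length: int = 200, min_gc: float = 0.5,
                       min_obs_exp: float = 0.6) -> list[tuple[int, int]]:
    """Gardiner-Garden–Frommer CpG island scan on one contig.

    Finds maximal intervals of length >= min_length with GC fraction >=
    min_gc and observed/expected CpG >= min_obs_exp, by greedy extension of
    qualifying min_length windows. Every returned interval satisfies all
    three criteria when rechecked.
    """
    n = len(seq)
    if n < min_length:
        return []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(np.int32)
    is_g = (arr == ord("G")).astype(np.int32)
    is_cg = np.zeros(n, dtype=np.int32)
    is_cg[:-1] = is_c[:-1] & is_g[1:]
    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    cum_cg = np.concatenate([[0], np.cumsum(is_cg)])

    def ok(s: int, e: int) -> bool:
        L = e - s
        c = cum_c[e] - cum_c[s]
        g = cum_g[e] - cum_g[s]
        cg = cum_cg[max(0, e - 1)] - cum_cg[s]  # CpG starting within [s, e-1)
        if (c + g) / L < min_gc:
            return False
        if c == 0 or g == 0:
            return False
        return cg * L / (c * g) >= min_obs_exp

    starts = [s for s in range(0, n - min_length + 1) if ok(s, s + min_length)]
    islands: list[tuple[int, int]] = []
    i = 0
    while i < len(starts):
        s = starts[i]
        e = s + min_length
        while e < n and ok(s, e + 1):
            e += 1
        islands.append((s, e))
        # skip seed windows already inside the extended island
        while i < len(starts) and starts[i] < e:
            i += 1
    # merge identical / overlapping results from adjacent seeds
    merged: list[tuple[int, int]] = []
    for s, e in islands:
        if merged and s <= merged[-1][1] and ok(merged[-1][0], max(e, merged[-1][1])):
            merged[-1] = (merged[-1][0], max(e, merged[-1][1]))
        elif not merged or s >= merged[-1][1]:
            merged.append((s, e))
    return merged


def islands_to_bed(contig: str, islands: Iterable[tuple[int, int]]) -> list[BedRecord]:
    return [BedRecord(contig, s, e, f"island_{i}", 0.0, ".")
            for i, (s, e) in enumerate(islands)]
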