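"""Synthetic RRBS libraries with known ground truth.

Generates a toy genome (with planted CpG islands, gene models, and
MspI/TaqI sites), assigns every cytosine a true methylation probability
per group (a configurable fraction of CpG sites made differential), and
simulates bisulfite-converted 50-bp reads from the 5' ends of both strands
of size-selected MspI-TaqI fragments. A single seeded RNG stream makes
runs byte-reproducible; read names carry no truth — per-read origins and
per-site probabilities live in the truth tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from rrbs_methkit import io as mkio
from rrbs_methkit.digest import DigestConfig, Fragment, digest, revcomp, size_select
from rrbs_methkit.io import BedRecord, FastqRecord
from rrbs_methkit.methcall import classify_context

DEFAULT_CONTEXT_METHYLATION = {"CpG": 0.7, "CHG": 0.02, "CHH": 0.02}


@dataclass(frozen=True)
class SimConfig:
    genome_length: int = 50_000
    gc_content: float = 0.42
    island_count: int = 4
    island_length: int = 400
    enzyme_site_rate: float = 4.0      # expected planted sites per kb, per enzyme
    group_labels: tuple[str, str] = ("LMFA", "HMFA")
    replicates_per_group: int = 3
    mean_context_methylation: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTEXT_METHYLATION))
    dm_fraction: float = 0.16
    dm_effect: float = 0.8
    coverage_target: float = 12.0      # mean reads per site per replicate
    conversion_efficiency: float = 0.995
    sequencing_error_rate: float = 0.001
    read_length: int = 50
    end_trim: int = 0
    size_min: int = 40
    size_max: int = 350
    contig_name: str = "chrS"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.replicates_per_group < 1:
            raise ValueError("replicates_per_group must be >= 1")
        for name, frac in (("gc_content", self.gc_content),
                           ("dm_fraction", self.dm_fraction),
                           ("dm_effect", self.dm_effect),
                           ("conversion_efficiency", self.conversion_efficiency),
                           ("sequencing_error_rate", self.sequencing_error_rate)):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name}={frac} outside [0, 1]")
        for ctx, m in self.mean_context_methylation.items():
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"mean_context_methylation[{ctx}]={m} outside [0, 1]")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.enzyme_site_rate < 0:
            raise ValueError("enzyme_site_rate must be >= 0")

    def digest_config(self) -> DigestConfig:
        return DigestConfig(size_min=self.size_min, size_max=self.size_max)


@dataclass
class SimulationResult:
    """Everything a downstream stage or a parameter-recovery test needs."""
    config: SimConfig
    genome: dict[str, str]
    genes: list[BedRecord]
    exons: list[BedRecord]
    islands: list[BedRecord]
    truth_sites: pd.DataFrame   # contig pos strand context p_<group1> p_<group2> is_dm
    reads: dict[tuple[str, int], list[FastqRecord]]
    read_records: pd.DataFrame  # read_id group replicate fragment_id strand ...

    def write(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []

        def _w(path: Path):
            written.append(path)
            return path

        mkio.write_fasta(_w(outdir / "genome.fa"), self.genome)
        mkio.write_bed6(_w(outdir / "genes.bed"), self.genes)
        mkio.write_bed6(_w(outdir / "exons.bed"), self.exons)
        mkio.write_bed6(_w(outdir / "islands.bed"), self.islands)
        mkio.write_gff3_genes(_w(outdir / "genes.gff3"), self.genes, self.exons)
        mkio.write_tsv(_w(outdir / "truth_sites.tsv"), self.truth_sites)
        mkio.write_tsv(_w(outdir / "truth_reads.tsv"), self.read_records)
        for (group, rep), recs in sorted(self.reads.items()):
            mkio.write_fastq(_w(outdir / f"reads_{group}_rep{rep}.fastq"), recs)
        return written


# ------------------------------------------------------------ genome


def _island_segment(length: int, rng: np.random.Generator) -> str:
    """CpG-dense, GC-rich segment (CpG frequency >= ~3x background)."""
    out: list[str] = []
    while len(out) < length:
        if rng.random() < 0.2:
            out.extend("CG")
        else:
            out.append("GC"[rng.integers(2)] if rng.random() < 0.6
                       else "AT"[rng.integers(2)])
    return "".join(out[:length])


def generate_genome(cfg: SimConfig, rng: np.random.Generator
                    ) -> tuple[dict[str, str], list[BedRecord], list[BedRecord],
                               list[BedRecord]]:
    """Generate one contig plus gene/island annotations.

    Raises ValueError when the configuration cannot yield at least one
    size-selected MspI-TaqI fragment (e.g. enzyme_site_rate = 0 or a
    too-small genome).
    """
    L = cfg.genome_length
    gc, at = cfg.gc_content / 2, (1 - cfg.gc_content) / 2
    seq = rng.choice(np.array(list("ACGT")), size=L, p=[at, gc, gc, at])

    # plant CpG islands (non-overlapping, away from contig edges)
    islands: list[BedRecord] = []
    occupied: list[tuple[int, int]] = []
    attempts = 0
    while len(islands) < cfg.island_count and attempts < 200 * max(cfg.island_count, 1):
        attempts += 1
        if cfg.island_length >= L:
            break
        s = int(rng.integers(0, L - cfg.island_length))
        e = s + cfg.island_length
        if any(s < oe and os_ < e for os_, oe in occupied):
            continue
        seq[s:e] = list(_island_segment(cfg.island_length, rng))
        occupied.append((s, e))
        islands.append(BedRecord(cfg.contig_name, s, e, f"island_{len(islands)}", 0.0, "."))
    islands.sort(key=lambda r: r.start)

    # plant restriction sites so the digest has material in the size window
    for motif in ("CCGG", "TCGA"):
        n_sites = rng.poisson(cfg.enzyme_site_rate * L / 1000.0)
        for _ in range(n_sites):
            p = int(rng.integers(0, L - len(motif)))
            seq[p:p + len(motif)] = list(motif)

    genome = {cfg.contig_name: "".join(seq)}

    # gene models: random spans with 2-4 exons each
    genes: list[BedRecord] = []
    exons: list[BedRecord] = []
    for gi in range(max(1, L // 5000)):
        span = int(rng.integers(1000, 3001))
        if span >= L:
            continue
        gs = int(rng.integers(0, L - span))
        ge = gs + span
        strand = "+" if rng.random() < 0.5 else "-"
        name = f"gene_{gi}"
        genes.append(BedRecord(cfg.contig_name, gs, ge, name, 0.0, strand))
        n_ex = int(rng.integers(2, 5))
        cuts = np.sort(rng.choice(np.arange(gs + 1, ge), size=2 * n_ex - 2, replace=False))
        bounds = [gs, *cuts.tolist(), ge]
        for k in range(0, len(bounds) - 1, 2):
            if bounds[k + 1] > bounds[k]:
                exons.append(BedRecord(cfg.contig_name, bounds[k], bounds[k + 1],
                                       name, 0.0, strand))

    if not size_select(digest(genome, cfg.digest_config()), cfg.digest_config()):
        raise ValueError(
            "no digestible fragments in the size window: increase genome_length "
            "or enzyme_site_rate")
    return genome, genes, exons, islands


# ------------------------------------------------------------ methylation truth


def assign_methylation(genome: Mapping[str, str], cfg: SimConfig,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Assign each cytosine (both strands) a true methylation probability
    per group.

    Non-differential sites get the context mean in both groups. A
    dm_fraction subset of CpG sites gets two probabilities exactly
    dm_effect apart (direction random); with dm_effect = 1 these are
    {0, 1}.
    """
    g1, g2 = cfg.group_labels
    rows = []
    for contig, seq in genome.items():
        for pos, base in enumerate(seq):
            if base == "C":
                strand = "+"
            elif base == "G":
                strand = "-"
            else:
                continue
            ctx = classify_context(seq, pos, strand)
            if ctx is None:
                continue
            rows.append((contig, pos, strand, ctx))
    truth = pd.DataFrame(rows, columns=["contig", "pos", "strand", "context"])
    base_p = truth["context"].map(
        lambda c: cfg.mean_context_methylation.get(c, 0.0)).to_numpy(dtype=float)
    p1 = base_p.copy()
    p2 = base_p.copy()
    eligible = (truth["context"] == "CpG").to_numpy()
    flags = np.zeros(len(truth), dtype=bool)
    flags[eligible] = rng.random(int(eligible.sum())) < cfg.dm_fraction
    idx = np.flatnonzero(flags)
    low = rng.random(len(idx)) * (1.0 - cfg.dm_effect)
    high = low + cfg.dm_effect
    swap = rng.random(len(idx)) < 0.5
    p1[idx] = np.where(swap, high, low)
    p2[idx] = np.where(swap, low, high)
    truth[f"p_{g1}"] = p1
    truth[f"p_{g2}"] = p2
    truth["is_dm"] = flags
    return truth


# ------------------------------------------------------------ reads


def _strand_template(frag: Fragment, genome: Mapping[str, str], strand: str,
                     cfg: SimConfig) -> tuple[str, list[int]]:
    """Read template: first read_length bases of the fragment strand
    (after end_trim), plus the genome coordinate of each template base."""
    top = genome[frag.contig][frag.start:frag.end]
    if strand == "top":
        coords = list(range(frag.start, frag.end))
        s = top
    else:
        s = revcomp(top)
        coords = list(range(frag.end - 1, frag.start - 1, -1))
    a = cfg.end_trim
    b = min(a + cfg.read_length, len(s))
    return s[a:b], coords[a:b]


def simulate_reads(genome: Mapping[str, str], truth: pd.DataFrame, cfg: SimConfig,
                   rng: np.random.Generator
                   ) -> tuple[dict[tuple[str, int], list[FastqRecord]], pd.DataFrame]:
    """Simulate bisulfite reads for every group/replicate.

    Each size-selected fragment contributes Poisson(coverage_target) reads
    per strand per sample, drawn from the 5' end of that strand. A
    template C is emitted as C when methylated (per the site's true group
    probability); an unmethylated C converts to T with probability
    conversion_efficiency. Per-base sequencing errors are substitutions to
    a uniformly random other base.
    """
    dcfg = cfg.digest_config()
    fragments = size_select(digest(genome, dcfg), dcfg)
    if not fragments:
        raise ValueError("no fragments pass size selection")
    g1, g2 = cfg.group_labels
    pmap: dict[tuple[str, int, str], tuple[float, float]] = {
        (r.contig, r.pos, r.strand): (getattr(r, f"p_{g1}"), getattr(r, f"p_{g2}"))
        for r in truth.itertuples()}

    reads: dict[tuple[str, int], list[FastqRecord]] = {
        (g, rep): [] for g in cfg.group_labels
        for rep in range(1, cfg.replicates_per_group + 1)}
    records = []
    other = {b: [x for x in "ACGT" if x != b] for b in "ACGTN"}
    counter = 0
    for frag in fragments:
        for strand in ("top", "bottom"):
            template, coords = _strand_template(frag, genome, strand, cfg)
            read_strand = "+" if strand == "top" else "-"
            c_info = []  # (template index, genome pos, p per group)
            for i, b in enumerate(template):
                if b == "C":
                    probs = pmap.get((frag.contig, coords[i], read_strand))
                    if probs is not None:
                        c_info.append((i, coords[i], probs))
            for gi, group in enumerate(cfg.group_labels):
                for rep in range(1, cfg.replicates_per_group + 1):
                    n = int(rng.poisson(cfg.coverage_target))
                    for _ in range(n):
                        counter += 1
                        chars = list(template)
                        emitted = []
                        if c_info:
                            meth_draw = rng.random(len(c_info))
                            conv_draw = rng.random(len(c_info))
                            for k, (i, gpos, probs) in enumerate(c_info):
                                if meth_draw[k] < probs[gi]:
                                    emitted.append("C")  # methylated: protected
                                elif conv_draw[k] < cfg.conversion_efficiency:
                                    chars[i] = "T"
                                    emitted.append("T")
                                else:
                                    emitted.append("C")
                        n_err = 0
                        if cfg.sequencing_error_rate > 0:
                            err_mask = rng.random(len(chars)) < cfg.sequencing_error_rate
                            for i in np.flatnonzero(err_mask):
                                chars[i] = other[chars[i]][rng.integers(3)]
                                n_err += 1
                        seq = "".join(chars)
                        read_id = f"sim{counter:08d}"
                        reads[(group, rep)].append(
                            FastqRecord(read_id, seq, "I" * len(seq)))
                        records.append({
                            "read_id": read_id, "group": group, "replicate": rep,
                            "fragment_id": frag.fragment_id, "contig": frag.contig,
                            "strand": strand,
                            "template_start": coords[0], "template_end": coords[-1],
                            "site_positions": ",".join(str(p) for _, p, _ in c_info),
                            "site_emitted": "".join(emitted),
                            "n_errors": n_err})
    read_records = pd.DataFrame(records, columns=[
        "read_id", "group", "replicate", "fragment_id", "contig", "strand",
        "template_start", "template_end", "site_positions", "site_emitted", "n_errors"])
    return reads, read_records


def simulate(cfg: SimConfig, outdir: str | Path | None = None) -> SimulationResult:
    """Run the full simulation from one seeded RNG stream."""
    rng = np.random.default_rng(cfg.seed)
    genome, genes, exons, islands = generate_genome(cfg, rng)
    truth = assign_methylation(genome, cfg, rng)
    reads, read_records = simulate_reads(genome, truth, cfg, rng)
    result = SimulationResult(cfg, genome, genes, exons, islands, truth,
                              reads, read_records)
    if outdir is not None:
        result.write(outdir)
    return result
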