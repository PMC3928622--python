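"""End-to-end pipeline orchestration with a checksum manifest.

Stages: (optional) simulate -> digest -> align -> call -> diff -> annotate.
Every produced file is recorded in manifest.json with its SHA-256, so two
runs with the same configuration and seed can be compared byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from rrbs_methkit import io as mkio
from rrbs_methkit.align import AlignConfig, Aligner
from rrbs_methkit.annotate import (FeatureModel, annotate_sites, category_distribution,
                                   detect_cpg_islands, islands_to_bed)
from rrbs_methkit.diffmeth import DiffConfig, run_comparison, summarize_comparison
from rrbs_methkit.digest import DigestConfig, ReferenceDB, build_reference, digest, size_select
from rrbs_methkit.methcall import export_tracks, pileup, pool_calls
from rrbs_methkit.simdata import SimConfig, simulate

log = logging.getLogger("rrbs_methkit")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Well-formed configuration but unusable data (CLI exit code 3)."""


@dataclass
class RunConfig:
    outdir: Path
    seed: int = 0
    simulate: dict[str, Any] | None = None
    genome: Path | None = None
    reads: dict[str, list[Path]] = field(default_factory=dict)  # group -> fastqs
    genes: Path | None = None
    exons: Path | None = None
    islands: Path | None = None
    digest: DigestConfig = field(default_factory=DigestConfig)
    align: AlignConfig = field(default_factory=AlignConfig)
    diff: DiffConfig = field(default_factory=DiffConfig)
    promoter_upstream: int = 1000
    promoter_downstream: int = 500

    @classmethod
    def from_dict(cls, raw: dict[str, Any], outdir: str | Path) -> "RunConfig":
        try:
            cfg = cls(
                outdir=Path(outdir),
                seed=int(raw.get("seed", 0)),
                simulate=raw.get("simulate"),
                genome=Path(raw["genome"]) if raw.get("genome") else None,
                reads={g: [Path(p) for p in ps]
                       for g, ps in raw.get("reads", {}).items()},
                genes=Path(raw["genes"]) if raw.get("genes") else None,
                exons=Path(raw["exons"]) if raw.get("exons") else None,
                islands=Path(raw["islands"]) if raw.get("islands") else None,
                digest=DigestConfig(**raw.get("digest", {})),
                align=AlignConfig(**raw.get("align", {})),
                diff=DiffConfig(**raw.get("diff", {})),
                promoter_upstream=int(raw.get("promoter_upstream", 1000)),
                promoter_downstream=int(raw.get("promoter_downstream", 500)),
            )
        except (TypeError, ValueError, KeyError) as exc:
            raise ConfigError(str(exc)) from exc
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.simulate is None:
            if self.genome is None:
                raise ConfigError("either a 'simulate' section or a 'genome' path is required")
            if not self.genome.exists():
                raise ConfigError(f"genome FASTA not found: {self.genome}")
            if not self.reads:
                raise ConfigError("no read files configured")
            for group, paths in self.reads.items():
                for p in paths:
                    if not p.exists():
                        raise ConfigError(f"reads for {group} not found: {p}")
            for label, p in (("genes", self.genes), ("exons", self.exons),
                             ("islands", self.islands)):
                if p is not None and not p.exists():
                    raise ConfigError(f"{label} file not found: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all stages; returns the manifest path.

    Any stage failure aborts with the stage name in the exception message;
    files already written are left in place.
    """
    out = cfg.outdir
    out.mkdir(parents=True, exist_ok=True)
    produced: list[Path] = []
    stage = "setup"
    try:
        # ---- simulate / load inputs
        if cfg.simulate is not None:
            stage = "simulate"
            sim_cfg = SimConfig(**{**cfg.simulate, "seed": cfg.seed})
            sim = simulate(sim_cfg)
            produced += sim.write(out / "sim")
            genome = sim.genome
            sample_reads = {f"{g}_rep{rep}": [(r.read_id, r.seq) for r in recs]
                            for (g, rep), recs in sorted(sim.reads.items())}
            groups = list(sim_cfg.group_labels)
            group_of = {f"{g}_rep{rep}": g for (g, rep) in sim.reads}
            genes_bed, exons_bed, islands_bed = sim.genes, sim.exons, sim.islands
        else:
            stage = "load"
            genome = mkio.read_fasta(cfg.genome)
            sample_reads = {}
            group_of = {}
            groups = list(cfg.reads)
            for group, paths in cfg.reads.items():
                for i, p in enumerate(paths, 1):
                    name = f"{group}_rep{i}"
                    sample_reads[name] = [(r.read_id, r.seq) for r in mkio.read_fastq(p)]
                    group_of[name] = group
            genes_bed = mkio.read_bed6(cfg.genes) if cfg.genes else []
            exons_bed = mkio.read_bed6(cfg.exons) if cfg.exons else []
            if cfg.islands:
                islands_bed = mkio.read_bed6(cfg.islands)
            else:
                islands_bed = [r for contig, seq in genome.items()
                               for r in islands_to_bed(contig, detect_cpg_islands(seq))]
        if len(groups) != 2:
            raise DataError(f"need exactly 2 groups, got {groups}")

        # ---- digest & reference
        stage = "digest"
        fragments = size_select(digest(genome, cfg.digest), cfg.digest)
        if not fragments:
            raise DataError("digest produced no size-selected fragments")
        db = build_reference(fragments, genome, cfg.digest)
        refdir = out / "refdb"
        db.save(refdir)
        produced += [refdir / "reference.fa", refdir / "offsets.tsv"]

        # ---- align & call per sample
        stage = "align"
        aligner = Aligner(db, cfg.align)
        per_sample_calls: dict[str, pd.DataFrame] = {}
        for sample, rd in sample_reads.items():
            table = aligner.align_many(rd)
            aln_path = out / f"aln_{sample}.tsv"
            mkio.write_tsv(aln_path, table)
            produced.append(aln_path)
            raw_by_id = dict(rd)
            kept = []
            for r in table[table["verdict"] == "unique"].itertuples():
                from rrbs_methkit.align import AlignmentHit
                kept.append((raw_by_id[r.read_id],
                             AlignmentHit(r.entry_id, int(r.offset), r.strand, 0,
                                          int(r.bs_mismatches))))
            per_sample_calls[sample] = pileup(kept, db, genome)

        stage = "call"
        group_calls: dict[str, pd.DataFrame] = {}
        group_reps: dict[str, list[pd.DataFrame]] = {g: [] for g in groups}
        for sample, calls in per_sample_calls.items():
            produced += export_tracks(calls, out / f"calls_{sample}", track_name=sample)
            group_reps[group_of[sample]].append(calls)
        for group in groups:
            pooled = pool_calls(group_reps[group])
            group_calls[group] = pooled
            produced += export_tracks(pooled, out / f"calls_{group}_pooled",
                                      track_name=f"{group}_pooled")

        # ---- differential testing
        stage = "diff"
        table = run_comparison(group_calls[groups[0]], group_calls[groups[1]], cfg.diff,
                               replicates1=group_reps[groups[0]],
                               replicates2=group_reps[groups[1]])
        diff_path = out / "differential_sites.tsv"
        mkio.write_tsv(diff_path, table)
        produced.append(diff_path)
        summary_path = out / "differential_summary.tsv"
        mkio.write_tsv(summary_path, summarize_comparison(table, cfg.diff))
        produced.append(summary_path)

        # ---- annotation
        stage = "annotate"
        model = FeatureModel.from_bed(genes_bed, exons_bed, islands_bed,
                                      cfg.promoter_upstream, cfg.promoter_downstream)
        annotated = annotate_sites(table, model)
        ann_path = out / "differential_sites_annotated.tsv"
        mkio.write_tsv(ann_path, annotated)
        produced.append(ann_path)
        sig = annotated[annotated["significant"]]
        if len(sig):
            dist_path = out / "category_distribution.tsv"
            mkio.write_tsv(dist_path, category_distribution(sig))
            produced.append(dist_path)
    except (ConfigError, DataError):
        raise
    except Exception as exc:
        raise DataError(f"stage '{stage}' failed: {exc}") from exc

    stage = "manifest"
    manifest = {
        "seed": cfg.seed,
        "files": {str(p.relative_to(out)): _sha256(p) for p in sorted(set(produced))},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest_path
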