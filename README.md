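# rrbs-methkit

A reduced-representation bisulfite sequencing (RRBS) methylome analysis
toolkit:

- **simdata** — synthetic genomes and bisulfite read libraries with known
  per-site ground truth (MspI–TaqI fragments 40–350 bp, 50-bp reads from
  both converted strands, configurable differential fraction/effect,
  conversion efficiency and sequencing error).
- **digest** — in-silico sequential TaqI (T^CGA) + MspI (C^CGG) digestion,
  size selection, and the C→T-converted fragment-end reference database
  (≤50-bp ends, both strands, with genome offset maps).
- **align** — exact ungapped three-letter alignment: reads are fully C→T
  converted and matched against the converted reference via a lossless
  pigeonhole seed index, mismatches are recounted on the unconverted
  sequences (read-T over reference-C ignored; read-C over reference-T
  counted), and a read is kept only when the second-best placement has at
  least 2 more mismatches.
- **methcall** — per-cytosine pileup: level = #C / (#C + #T), CpG/CHG/CHH
  context from the unconverted reference, strand-specific records, bedGraph
  and TSV export.
- **diffmeth** — per-site two-group testing: two-sided Fisher exact
  (minimum-likelihood tail) on pooled counts or Welch t-test on replicate
  levels, ≥5 reads required in each group, effect size, direction labels,
  BH q-values, and a published-table inverter (`reconstruct_table`).
- **annotate** — promoter/exon/intron/intergenic assignment (precedence
  promoter > exon > intron), CpG-island membership, category-distribution
  summaries, and a Gardiner-Garden–Frommer island detector fallback.
- **expression** — Pfaffl relative-expression ratios from qPCR Ct tables
  with replicate statistics.
- **pipeline / cli** — one-command orchestration with a SHA-256 manifest;
  fixed seed ⇒ byte-identical outputs.

## CLI

```sh
rrbs-methkit simulate --config sim.yaml --seed 1 --out simdir/
rrbs-methkit digest   --fasta genome.fa --min 40 --max 350 --out refdb/
rrbs-methkit align    --reads r.fastq --ref refdb/ --max-mm 3 --margin 2 --out aln.tsv
rrbs-methkit call     --aln aln.tsv --reads r.fastq --ref refdb/ --genome genome.fa --out calls
rrbs-methkit diff     --a callsA.tsv --b callsB.tsv --min-cov 5 --alpha 0.05 --out diff.tsv
rrbs-methkit annotate --sites diff.tsv --genes genes.gff3 --islands islands.bed --out ann.tsv
rrbs-methkit expr     --ct ct.tsv
rrbs-methkit run      --config run.yaml --out outdir/   # full pipeline
```

A minimal `run.yaml` for a fully simulated end-to-end run:

```yaml
seed: 1
simulate:
  genome_length: 50000
  replicates_per_group: 3
  coverage_target: 12
  dm_fraction: 0.16
  dm_effect: 0.8
```

Exit codes: 0 success, 2 configuration error, 3 data error.

## Conventions

All internal coordinates are 0-based half-open. Report TSVs use the
single-base (start, end = start + 1) convention; BED and bedGraph are
written natively 0-based half-open. Top- and bottom-strand cytosines are
always separate records.
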