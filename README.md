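# ampliseek

A desk-scale toolkit for targeted amplicon sequencing of anuran
antimicrobial-peptide (AMP) transcripts: degenerate primer design from
conserved signal-peptide coding regions, Ion-Torrent-like read processing
and greedy overlap-layout-consensus assembly, AMP homology screening,
precursor annotation (Lys-Arg cleavage, C-terminal amidation, rana-box
detection, novelty tiering, feature-based classification), and
physicochemical profiling of mature peptides. A seeded synthetic-data
generator makes every stage testable offline.

## Layout

| module | role |
|---|---|
| `ampliseek.seqcore` | sequence types, IUPAC degeneracy, translation, ORF finding, FASTA/FASTQ I/O |
| `ampliseek.primer_design` | clustering, conserved-window scan, degenerate consensus, tails, amplicon-size prediction |
| `ampliseek.homology_screen` | PWM profile scan with shuffle significance; translated Smith–Waterman search with Karlin–Altschul E-values |
| `ampliseek.amplicon_pipeline` | modified-Mott trimming, demultiplexing, greedy OLC assembly, support filter, remap + stringent re-assembly |
| `ampliseek.precursor_annotation` | precursor splitting, amidation resolution, rana-box, novelty tiers, eight-class rules |
| `ampliseek.physchem` | net charge, mean hydrophobicity (consensus scale), average molecular weight with amidation correction |
| `ampliseek.synthetic_data` | seeded gene-family and amplicon-read simulator with truth manifest |
| `ampliseek.workflow` / `ampliseek.cli` | pipeline orchestration, YAML config, CLI |

## CLI

Each stage is independently scriptable; `run` chains them all:

```bash
# generate a ground-truthed synthetic dataset
ampliseek simulate --n-loci 10 --coverage 50 --seed 1 --outdir sim/

# design a degenerate forward primer from an aligned FASTA region
ampliseek design-primers alignment.fasta --out primers.tsv

# stagewise
ampliseek trim sim/reads.fastq trimmed.fastq --adapter ATCACCGACTGCCCATAGAGAGG
ampliseek assemble trimmed.fastq contigs.fasta --min-support 3
ampliseek screen contigs.fasta db.fasta --out hits.tsv
ampliseek annotate contigs.fasta db.fasta --outdir annot/
ampliseek physchem mature.fasta --out physchem.tsv

# or the whole pipeline (demultiplex -> trim -> assemble -> screen -> annotate)
ampliseek run sim/reads.fastq db.fasta --outdir run/ --config config.yaml
```

`config.yaml` accepts the pipeline thresholds (all default to the published
values: trim limit 0.05, minimum read length 100, minimum contig support 3,
E-value alpha 0.05, identity bands 80/81–99/100, 70% coverage cutoff,
450-nt platform cap, 10-nt barcodes). Unknown keys are rejected. Exit
codes: 0 success, 2 configuration error, 3 stage failure.

## Conventions

- Coordinates are 0-based half-open; strand is explicit (signed frames).
- Net charge: `(#K + #R) − (#D + #E) + 1` for the free N-terminal amine;
  His/Cys and the C-terminus contribute nothing. A Henderson–Hasselbalch
  alternative is available (`net_charge_hh`).
- Molecular weight: average residue masses + 18.015 (water), −0.984 for a
  C-terminal amide.
- Amidation stripping (trailing G plus optional basics) is an explicit,
  flagged transformation — opt-in via `strip_amidation`, never silent.
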