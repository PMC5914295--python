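# editscope

Strand-aware A-to-G RNA-editing analysis toolkit for bulk transcriptomics:

- **Site calling** — candidate A→G (and reference-forward T→C) editing sites
  from per-sample pileups, with coverage (≥20 reads) and mean-frequency (≥5%)
  thresholds, known-variant masking, and three artifact filters (strand bias
  via Fisher exact; read-position and variant-distance bias via rank-sum
  tests).
- **Differential editing** — per-site binomial logistic regression of editing
  frequency on genotype, analysis-of-deviance (χ² LRT) significance, and
  Benjamini–Hochberg FDR control.
- **Amplicon mode** — targeted deep-resequencing editing quantification with a
  1% frequency floor.
- **Isoform quantification** — enumeration of all 2^k combinatorial editing
  haplotypes of an amplicon ("artificial chromosomes", e.g. the 32 variants of
  the 5-HT2CR exon 5 motif), read assignment by the base pattern at the k
  editable sites, transcript-group and per-site marginal frequencies, and
  one-way ANOVA across genotypes.
- **Synthetic data** — a stranded RNA-seq and amplicon read simulator with
  fully known truth (per-site per-genotype editing rates, planted SNPs,
  planted strand-skew/end-cluster artifacts, haplotype mixtures), so every
  stage is validated by parameter recovery.
- **Fixture aligner + pileup** — an internal ungapped anchor aligner for
  fixture-scale data plus a strand-resolved pileup engine; real data enters
  via a minimal SAM dialect.

## CLI

```sh
editscope simulate --config sim.yaml --outdir sim/          # reads + truth TSVs
editscope pileup   --ref ref.fa --fastq s1.fastq --out s1.tsv   # or --sam aln.sam
editscope call     --pileups s1.tsv --pileups s2.tsv ... \
                   --design design.tsv --mask dbsnp.bed --out candidates.tsv
editscope diff     --candidates candidates.tsv --design design.tsv --out diffedit.tsv
editscope isoform  --amplicon amplicon.fa --sites sites.tsv \
                   --reads s1.fq --reads s2.fq ... --design design.tsv --out isoforms.tsv
```

The design table is a TSV with header `sample_id\tgenotype\tpath`; region
strings at CLI boundaries are 1-based inclusive (`chrX:147169590-147169767` =
178 bp) while all internal coordinates are 0-based half-open.

## Layout

```
src/editscope/
  io_formats.py           FASTA/FASTQ/SAM-dialect/BED-mask/design-table I/O, regions
  synthetic_data.py       reference + RNA-seq + amplicon simulators, truth files
  pileup.py               fixture aligner, strand-resolved pileup engine
  editing_caller.py       candidate detection, masking, bias filters, amplicon mode
  differential_editing.py binomial GLM (IRLS), LRT, BH FDR
  isoform_quant.py        2^k haplotype enumeration, read assignment, groups, ANOVA
  cli.py                  click command group
tests/                    unit, property (hypothesis) and acceptance tests
scripts/acceptance.py     acceptance-target report
```
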