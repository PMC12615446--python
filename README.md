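# fusionkit

A toolkit for characterizing fusion (chimeric) transcripts from caller
output: structural annotation of fusion junctions, cross-tool consensus
merging, expression and qPCR analyses, presence/absence conservation across
genotypes, long-read validation filtering, and caller benchmarking — plus a
seeded synthetic-data generator so the whole pipeline is testable without
any external downloads.

## What it does

- **io_formats** — FASTA / GFF3 / unified fusion TSV (plus a
  `chrom:pos:strand` caller dialect) / BLAST outfmt-6 tabular / TPM matrix
  readers and writers, and the shared coordinate-bearing domain types.
  Coordinates are 1-based inclusive; `bp5` is the last transcribed base of
  the 5′ segment, `bp3` the first transcribed base of the 3′ segment.
- **junction_annotation** — per-call locality (inter/intrachromosomal),
  exon-boundary class (both/one/none, any isoform counts, strand-aware),
  donor/acceptor dinucleotides (canonical = GT-AG), short-homologous-
  sequence (SHS) detection at the breakpoints, reading-frame status, the
  200-bp junction query sequence, and mechanism summaries.
- **consensus_merge** — deduplication of calls across tools/samples into
  unique fusions and ordered gene pairs, partner-degree statistics,
  gene-fraction arithmetic, and 2-of-3 coding-potential voting.
- **expression_analysis** — parental-gene co-expression (Pearson R on
  log(TPM+1)), fusion-present vs fusion-absent fold-change classification
  (≥2-fold up / ≤0.5 down, +1 pseudocount), and 2^−ΔΔCt relative
  quantification with Welch's t-test on per-replicate ΔCt.
- **conservation** — binary presence/absence matrices of gene pairs across
  genotypes, conserved-pair tallies, Jaccard/average-linkage clustering of
  genotypes (Newick export), and ortholog-mapped cross-species conservation.
- **validation_bench** — long-read hit filtering (identity > 80%, length
  > 150 bp by default; strictness configurable), transcript-length
  estimation from the best supporting hit, and sensitivity/precision/
  F-measure benchmarking against a truth set.
- **synthetic_data** — seeded generators: genome + annotation with
  canonical intron edges, planted fusions of known mechanism/boundary/frame,
  correlated log-normal expression, threshold-straddling long-read hits,
  and replicated Ct tables.

## CLI

All stages are exposed as `fusionkit` subcommands (or
`python -m fusionkit.cli`). A full synthetic round trip:

```sh
fusionkit simulate --seed 7 --outdir demo
fusionkit annotate --genome demo/genome.fa --gff3 demo/annotation.gff3 \
    --calls demo/calls.tsv --outdir demo/ann
fusionkit mechanisms --annotated demo/ann/annotated.tsv --outdir demo/mech
fusionkit merge --calls demo/calls.tsv --outdir demo/merge
fusionkit validate --hits demo/longread_hits.tsv --outdir demo/val
fusionkit ddct --ct demo/ct.tsv --target fusion1 --reference EF1a --outdir demo/ddct
```

Other subcommands: `expression`, `conserve`, `benchmark`. Any long option
can also be supplied through a `key=value` config file (`--config`);
explicit flags win. Exit codes: 0 success, 1 data error, 2 argument error.

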