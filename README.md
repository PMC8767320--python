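# mxpipe

Analysis toolkit for a long-read (nanopore) genome of the amitochondriate
flagellate *Monocercomonoides exilis* — and for any study with the same
shape: a telomere-bearing assembly, an annotation lifted over from an older
assembly, long-read transcript evidence for UTRs, and a proteome screened
for mitochondrial hallmark proteins.

The package implements the analysis layer only. Heavy external tools
(assemblers, gene predictors, BLAST/HMMER, targeting-signal and
secondary-structure predictors) are never run; their standard-format outputs
are inputs. A seeded synthetic-data generator with ground-truth manifests
makes every stage testable offline.

## What it computes

* **genome_stats** — N50, GC (ambiguous bases excluded), telomeric-end
  classification (tandem repeat-unit runs at contig ends), per-5 kb coding
  density, and gene/intron/intergenic/UTR summary metrics. The chromosome
  number is estimated from telomere-capped contig counts as

  `point = n_both + n_one / 2`

  each both-ends-capped contig being a complete chromosome and each one-end
  contig half of one.
* **annotation_transfer** — staged, clustering-verified transfer of old gene
  models: exact clustering (equal length, 100 % identity) for the first two
  stages, near clustering (equal length, global identity >= 0.95) for later
  stages, then fusion/split detection by CDS overlap on the new coordinate
  system, with the locus-tag naming convention `PREFIX_afub` for fusions and
  `PREFIX_np1 ... pk` for splits, and conservation-checked summaries.
* **utr_landscape** — full-length 3′UTR selection by the oligo-dT boundary
  criterion, exhaustive k-mer enrichment over the last 100 bp against a
  dinucleotide-preserving shuffle null (z-scores), positional occurrence
  profiles anchored at the cleavage site, U-content profiles, and the Kozak
  position-frequency matrix (±10 bp around ATG).
* **mito_screen** — reciprocal best hits (e ≤ 0.001), dual targeting-signal
  consensus (both predictors > 0.5), tail-anchor filter (TMD within 32 aa of
  the C-terminus), β-signal scan (Po-x-G-Hy-x-Hy-x-Hy in the C-terminal
  window) with secondary-structure filters (≥ 25 % strand, ≤ 10 % helix over
  ≤ 300 aa of context, ≤ 50 % of the motif helical), and an aggregated
  evidence report. Flagged proteins are `manual_review`, never auto-accepted.
* **synthetic_data** — seeded generator for all of the above with a
  ground-truth manifest (`truth.json`).

## Worked example

```sh
mxpipe synth --seed 5 --out corpus
mxpipe report --dir corpus --out results
```

prints (log lines abridged):

```
N50 46468 bp; 2/3 telomeric contigs; chromosome estimate 3.5 (range 0-10)
transferred 109 / 124 old models (10 fused, 3 split)
88 full-length 3'UTRs; top motif AAUAAA (z=16.8); Kozak consensus TAAwAwwwAwATGwttsyaktgr
channels: rbh 50, targeting 24 (0.5%), TA 7, MBOMP 2; union 111 of 4665
```

Reading: the synthetic assembly has 2 contigs capped at both ends and 3 at
one end, so the chromosome point estimate is 2 + 3/2 = 3.5. Of 124 old gene
models, 109 transfer verbatim, ten old tags fuse into five new models, three
old models split in two, and the remaining two are contaminants. Among the
full-length 3′UTR tails the planted polyadenylation signal AAUAAA is the top
enriched hexamer at z = 16.8, and the proteome screen flags exactly the
planted 24 targeting-consensus, 7 tail-anchor and 2 β-barrel candidates, at
the published 0.5 % consensus rate.

Each subcommand (`stats`, `transfer`, `utr`, `mito`) also runs standalone on
your own FASTA/GFF3/TSV inputs; see `mxpipe <cmd> --help`.

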