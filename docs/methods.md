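# Methods

This note documents the models and procedures implemented in mxpipe, the
defaults they run with, the numerical choices behind them, and what the
synthetic-data generator does and does not emulate.

## Coordinates and sequence conventions

All coordinates are GFF3-style 1-based closed; any half-open arithmetic is
confined to function internals. Sequences are stored upper-case; RNA is
stored as T and rendered as U only in reports. Terminal stop codons are
included in CDS intervals but trimmed from protein strings, so CDS lengths
stay multiples of three while protein FASTA output looks conventional.
GC content is computed over unambiguous bases only (N excluded from
numerator and denominator), matching common assembly-statistics practice.
Gene models read from GFF3 whose CDS length is not a multiple of three are
flagged partial rather than rejected: such models occur in real annotations
and refusing them would make the readers unusable on the data they exist for.

## Assembly statistics and chromosome counting

N50 uses the dominant convention: contigs sorted descending, cumulative sum,
first length at which the sum reaches *at least* half the total. A contig
end is called telomeric when at least `telomere_min_units` (default 5)
tandem copies of the repeat unit (default TTAGGG) or its reverse complement
begin within `telomere_search_window` (default 1000 bp) of that end, with at
most 2 mismatches over the whole run. The tolerance is explicit and
configurable because no published detection rule exists to inherit; the
3′ end is scanned on the reverse complement, which makes the call exactly
symmetric under reverse-complementing a contig (a tested invariant).

The chromosome estimate treats each both-ends-capped contig as a complete
chromosome and each one-end contig as half of one:
`point = n_both + n_one/2`. The point estimate is the scientific output; the
reported range rounds it outward to multiples of ten, mirroring the loose
wording such estimates are quoted with in print.

Coding density tiles each contig with fixed windows (default 5 kb; the final
partial window keeps its true length) and reports the fraction of each
window covered by the union of CDS intervals. Summing fraction × window
length reconstructs the exact CDS-covered base count per contig (a tested
conservation law). "Gene length" is the genomic span from first to last
exon base — introns and UTRs included — because the summary table pairs it
with separate intron and UTR rows; intergenic length is the gap between
consecutive gene *spans* on a contig (the alternative, CDS spans, is
undocumented in the source material; spans were chosen and are stated here).

## Annotation transfer

The transfer engine reproduces the verification bookkeeping of a staged
liftover. External mappers are abstracted away: each stage contributes a set
of candidate gene models (as CDS sequences), and the engine decides which
old models those candidates account for.

* Stages run in the fixed order denovo_evm, ratt, gmap, pasa, manual; a tag
  resolved at one stage is never revisited.
* The first two stages use exact clustering: two sequences co-cluster iff
  they have equal length and 100 % identity (the cd-hit `-s 1 -c 1`
  behaviour). Implemented by hashing on the sequence string, which is
  trivially order-independent and is tested against a naive all-pairs
  oracle.
* Later stages use near clustering: equal length and global identity
  ≥ 0.95. Identity is matches / alignment columns of the best-scoring
  global alignment under match +1, mismatch 0, gap open −2, gap extend −1
  (Biopython PairwiseAligner). This is a deterministic, oracle-checkable
  stand-in for cd-hit's heuristic identity; the equal-length rule is
  enforced exactly. Lowering the threshold can only grow the transferred
  set (tested monotonicity).
* Fusion/split detection then runs on whatever failed to cluster, using old
  models lifted onto the new coordinate system: a new model whose CDS covers
  ≥ 50 % of the CDS of two or more old models (same contig and strand) is a
  fusion; one old model covering ≥ 50 % of the CDS of two or more new
  models is a split. The 50 % threshold is configurable; events are
  disjoint and any model implicated in both kinds raises an error rather
  than guessing.
* Naming: fusing `PREFIX_a` and `PREFIX_b` (a < b numerically) yields
  `PREFIX_afub`; splitting `PREFIX_n` into k parts yields `PREFIX_np1` …
  `pk`, numbered in plus-strand coordinate order regardless of gene strand
  (one unambiguous rule).
* Everything left is failed, carrying a reason category (contaminant,
  poor isoform, …) when the caller supplies one. The summary enforces
  conservation — every old tag appears exactly once and outcome counts sum
  to the input size — as a hard error, since violating it can only mean a
  bookkeeping bug.

Whether the original study's 95 % stages clustered nucleotide or protein
sequences is ambiguous in its description; the engine clusters whatever
sequences it is handed and the pipeline default is nucleotide CDS.

## UTR landscape

A 3′UTR is **full-length** iff at least one transcript read's polyA/oligo-dT
boundary lies within `full_length_tolerance` (default 0) bases of the
annotated UTR end *and* that read's alignment covers the whole UTR span.

Motif discovery replaces STREME/Centrimo with an exhaustive, deterministic
equivalent for short fixed k: every k-mer (default k = 6) is scored by the
number of tail sequences containing it at least once, against a null built
from `n_shuffles` (default 100) dinucleotide-preserving shuffles of every
sequence (Altschul–Erickson Eulerian-walk shuffle, seeded), summarised as
z = (obs − mean)/sd, ties broken by observed count then lexicographically.
Per-sequence first-occurrence counting (zero-or-one) matches the
site-probability reading of positional enrichment plots; an all-occurrences
mode is available. With ~4096 k-mers scored, the null's *maximum* z is an
extreme-value statistic and lands near 4–5 even for pure noise; planted
signals at realistic plant fractions score z > 10, so rank-1 recovery, not
an absolute z cutoff, is the meaningful criterion (and the one tested).

Positional profiles anchor at the cleavage site (position 0; the last UTR
base is −1) over the last 100 bp. The profile value at p is the fraction of
sequences whose motif occurrence starts at p; the profile reports the argmax
and the smallest window containing at least half of all occurrences. The
U-content profile is the per-position mean T indicator over sequences long
enough to reach that position.

The Kozak matrix uses genes with a spliced 5′UTR of at least `kozak_flank`
(default 10) bases and CDS of at least flank + 3; shorter contexts are
excluded and counted, mirroring curated-subset practice. Columns span
−10…+13 (ATG at +1…+3) and are column-stochastic. The consensus letter is
the base with frequency ≥ 0.4, else the IUPAC code of all bases ≥ 0.25
(lower case), else `n`; the upstream AT fraction is reported because an
AT-rich but motif-free upstream context is the expected signature here.

## Mitochondrial-hallmark screen

All channels consume predictor output tables; thresholds sit in
`PipelineConfig`:

* **RBH**: best hit per query = lowest e-value, ties by higher bitscore,
  then lexicographic subject id; a pair is reported iff mutual and both
  e-values ≤ 0.001 (inclusive). Symmetric under swapping the two tables
  (tested), and equivalent to a brute-force all-pairs oracle (tested on 100
  random instances).
* **Targeting consensus**: both predictors strictly > 0.5; missing scores
  count 0. The flagged percentage is reported to one decimal.
* **Tail anchor**: some TMD's last residue within 32 aa of the C-terminus,
  inclusive (`length − end ≤ 32`) — the most permissive natural reading of
  "within"; anchoring on the TMD start is configurable. A Kyte–Doolittle
  hydropathy fallback (19-residue centred window, threshold 1.6) exists so
  the pipeline runs without a predictor table; it is plumbing, clearly
  labelled in its output, and not equivalent to a real TMD predictor.
* **β-signal/MBOMP**: 8-mers matching Po-x-G-Hy-x-Hy-x-Hy with the last
  residue within 15 aa of the C-terminus (the source describes only "in the
  C-terminus"; the window makes that testable and is configurable). The
  Po/Hy classes default to Po = {D,E,H,K,N,Q,R,S,T},
  Hy = {A,F,I,L,M,V,W,Y} and are config-exposed, because the original class
  tables are cited but not restated in the study this models. The filter
  then requires, over the ≤ 300 residues immediately preceding the motif:
  strand fraction ≥ 0.25, helix fraction ≤ 0.10, and at most 4 of the 8
  motif residues helical — all boundaries inclusive (tested exactly at
  threshold and one residue beyond). For proteins shorter than 300 + 8 the
  context truncates; short candidates are a reporting concern downstream,
  not a filter.
* **Aggregation**: one row per protein with all channel flags; any flag
  yields verdict `manual_review`, none `rejected`. The screen never
  declares a mitochondrial protein on its own — the final call is manual by
  design.

## The synthetic-data generator

The generator's defaults are its standing study conditions, chosen once:
genome GC 37.2 % (introns 27.6 %, 3′UTR GC 26.1 %, AT-rich 5′UTRs at 70 %),
~1.95 introns per gene with mean length ~119 bp, mean 3′UTR 312 bp and
5′UTR 62 bp, hexamer AATAAA planted in 80 % of genes at 20–30 bp upstream
of the cleavage site with U-rich (p = 0.6) 10 bp flanks, telomere unit
TTAGGG × 12 per capped end, mean intergenic distance 1855 bp, and a
4665-protein proteome carrying 24 dual-targeting, 7 tail-anchor and 2
β-barrel positives among single-violation decoys, 50 reciprocal-best pairs
and 28 HMM hits of which 6 have database homologs. One integer seed drives
fixed per-artifact sub-streams, so identical (spec, seed) re-generation is
byte-identical while individual artifacts can be regenerated independently.

The derived "old" assembly fragments each contig at intergenic midpoints and
plants three event types, named by their outcome in the old→new transfer
direction: a *fusion* event represents one new gene as two partial old
models (split at a codon boundary near the CDS midpoint); a *split* event
merges two adjacent plus-strand genes into one old model via a fake long
intron; a *frameshift* event applies a compensated 1-bp insertion/deletion
pair ~30 bp apart inside one CDS exon, so the old CDS keeps its length
(surviving the equal-length rule) but only matches at the 95 % stage —
a plain indel would change the length and always fail. Event genes are
restricted to the plus strand for construction simplicity; the transfer
engine itself is strand-aware and tested on both strands. Contaminant genes
live on an old-only contig. β-barrel plants carry a 15-residue proline
spacer before the planted motif so it is provably the only β-signal in the
C-terminal window; decoys violate exactly one filter each, cycling over the
three secondary-structure filters.

What the generator does **not** emulate: sequencing error and raw reads
(frameshifts are the only error proxy), repeat families and transposable
elements, overlapping genes and alternative isoforms, codon-usage and
amino-acid composition bias, realistic 3′UTR length distributions (a
clipped exponential stands in), homology e-value structure beyond the
threshold neighbourhood, and any phylogenetic signal. Passing the recovery
suite therefore demonstrates that the decision layers implement their
definitions exactly on data satisfying their assumptions — not that the
thresholds themselves are optimal for real genomes.

## Problem sizes and determinism in the test suite

Unit and property tests run on a shared default corpus (120 genes, 8
contigs, 4665 proteins, seed 7). The recovery sweep runs ten corpora at 500
genes / 5000 proteins (seeds 0–9), sizes at which every planted count is
recovered exactly while the whole suite stays fast. Oracle-equivalence
sweeps use seeds 0–99. Hypothesis-based property tests are derandomised.
All randomness anywhere in the package flows through explicit seeds.
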