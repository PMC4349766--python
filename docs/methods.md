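# Methods

## Overview

`somaticsim` produces cancer-cell-population genomes by composing four
stochastic stages — germline polymorphism, tumor aneuploidy, somatic SV/CNV
placement, and clonal evolution — and then projecting every resulting
chromosome copy back onto reference coordinates to derive exact truth tables.
All internal coordinates are 0-based half-open; 1-based coordinates appear
only in VCF output. Every stage is driven by a `numpy` `Generator`, so a
single seed reproduces all outputs byte-identically.

## Genome representation

The central data structure is the *chromosome copy*: a nucleotide string
plus an ordered interval map of **pieces**, each recording which stretch of
which personal-genome haplotype (A or B) the bases came from and in which
orientation; foreign pieces map to nothing. All sequence surgery (aneuploidy
and SV events) rewrites sequence and pieces in lockstep, and the germline
stage supplies liftover maps from haplotype to reference coordinates. Truth
derivation is then mechanical: per-base parental copy counts are accumulated
by pushing every piece through the liftover, and maximal runs of constant
`(copies_A, copies_B)` become segments. A segment is LOH iff one parental
count is zero while at least one copy remains, and its expected BAF for the
allele on haplotype B is `copies_B / total`. The test suite checks this
projection against an independent brute-force per-base recount on dozens of
randomized genomes.

Because segments are exact reference projections, germline INDELs leave
sub-50 bp slivers (a base deleted on one haplotype has parental count 0
there). These are reported as-is rather than smoothed away; consumers
interested only in somatic CNV can filter on segment length.

## Germline stage

Exactly `snv_count` SNVs and `round(snv_count × indel_snv_ratio)` INDELs are
placed uniformly over non-N positions with non-overlapping reference
footprints (greedy acceptance over a sorted oversample of candidate
positions; variant kind is shuffled independently of position). Each SNV is
a transition with probability `titv/(titv+1)`; each variant is heterozygous
with probability `hhr/(hhr+1)`, het carriers split evenly between
haplotypes. INDEL lengths are geometric (p = 0.3) truncated at 49 bp;
insertions and deletions are drawn 1:1 and inserted bases are uniform.
Defaults — Ts/Tv 2.0, het/hom 1.5, INDEL/SNV 0.1 — approximate commonly
reported human whole-genome statistics and are all CLI-overridable. At
n = 10^4 the empirical ratios fall inside exact binomial 99.9% intervals of
these targets (asserted in the suite).

## Aneuploidy stage

Base ploidy n transforms the diploid copy set per chromosome: n = 1 keeps
one random parental copy; n = 2 both; n = 3 both plus one random duplicate;
even n replicates each parental copy n/2 times; odd n ≥ 5 replicates
(n−1)/2 times and adds one random extra. Ploidy is uniform across
chromosomes unless a per-chromosome override map is given. On top,
`aneuploidy_events` (default 2) whole or segmental duplications/deletions
are applied (segmental fraction 0.5; segmental sizes uniform between 10%
and 50% of the copy); a whole-chromosome loss never removes the last copy.

## SV stage

Event types: INS, DEL, INV, TDUP, balanced and unbalanced inter-chromosomal
translocation (CTX), and intra-chromosomal translocation (ITX), which is
always reinserted in inverted orientation; a non-inverting intra-chromosomal
move is deliberately not offered. Unbalanced CTX is realized as a loss: the
acceptor's terminal segment (sized by the event's drawn size) is replaced by
the donor's terminal segment, so the genome loses exactly `size` bases — an
earlier design that cut both chromosomes uniformly lost half a copy per
event on average and collapsed genomes over long simulations. Event sizes
are log-uniform between 1 kb and 1 Mb by default; the clone orchestrator
clamps the maximum to 5% of the shortest chromosome so that hundreds of
events remain placeable on small test genomes. Every event targets exactly
one randomly chosen chromosome copy (the source of allele-specific CNV and
LOH), and requested event counts are fulfilled exactly or the run errors.

Breakpoint mechanisms (default weights 0.60 / 0.35 / 0.05, reflecting that
foreign insertion is comparatively rare):

* **Non-homologous.** Breakpoints are uniform over eligible positions
  (outside N-runs, ≥ 50 bp from any existing junction — piece boundaries
  double as the junction registry, and the spacing keeps truth tables
  unambiguous). Each junction draws a micro-homology length uniformly on
  [0, 20] bp and the flanking sequence is edited to share *exactly* that
  many bases: the left side's would-be continuation is written over the
  junction's right flank, then one substitution breaks any accidental
  extension on either side. The junction-homology oracle
  (`junction_homology`) recomputes the tract from sequence plus the stored
  source contexts; placement-time records must and do agree with it.
* **Homologous.** Both breakpoints fall at the same consensus offset inside
  two compatible repeat elements (same family, each ≥ `min_shared` bp,
  default 100): same strand for DEL/TDUP, opposite strands for INV,
  elements on different chromosomes for CTX. Homology-mediated insertion
  copies the segment between a same-strand pair and pastes it at the
  matching offset of a third (forward-strand) family member. The junction
  then carries a chimeric element homologous to the family consensus over
  ≥ `min_shared` bp (verified by local alignment in the suite). Pair span
  is bounded by four times the drawn event size so realized sizes track
  requested ones and elements are not wiped out wholesale. ITX has no
  homologous geometry here and falls back to the non-homologous mechanism,
  as does any event for which no compatible pair survives on an intact
  copy. Because translocations make copies mosaics, elements are searched
  on *all* copies, not only those housed under the element's chromosome.
* **Foreign.** Insertions of uniformly random novel sequence verified to
  share no exact 30-mer with either strand of the reference (2-bit k-mer
  hashing; sequences shorter than 30 bp are novel vacuously).

A base-count ledger is asserted on every application: the model's total base
count changes by +size (INS, TDUP), −size (DEL, unbalanced CTX's lost
terminal), and 0 (INV, ITX, balanced CTX). Events must be applied at the
coordinates they were placed at; stale coordinates raise.

## Heterogeneity and purity

Under the clone-evolution model the founder's events are a verbatim prefix
of every descendant's event list; new descendant events are placed on the
parent's already rearranged coordinates (evolutionary realism) while truth
tables always report reference projections. Descendant event counts are
totals including inherited events — "a descendant with 150 events" derived
from a 50-event founder adds 100 of its own — with a flag for
additional-count semantics. The cancer-stem-cell model runs independent
founders with no shared events (duplicate seeds warn but do not error).
Deeper trees are built by iterating descendant derivation.

Read-level mixing is delegated to an external read simulator; `somaticsim`
emits the manifest (component FASTA paths and fractions, with the normal at
1 − purity) and the expected per-segment relative coverage and BAF over the
union segmentation of all clones, using the closed forms in the README.
With one clone at purity p the expected BAF moves monotonically from 0.5 at
p = 0 toward the clone's allele fraction `b/(a+b)` at p = 1
(property-tested).

## Numerical and design choices

* Micro-homology engineering substitutes at most `h + 2` bases per junction
  (h ≤ 20); with the 50 bp junction-spacing rule edits never collide. The
  substituted bases behave like junctional point mutations and do not affect
  copy-number truth.
* The synthetic reference generator plants repeat families as diverged
  copies of a random per-family consensus (default divergence 5–8%,
  mimicking younger/older transposon families) at non-overlapping uniform
  positions, and returns a catalog whose rows match the planted coordinates
  exactly. It emulates the repeat-mediated rearrangement substrate of a real
  genome but not its sequence composition (no CpG structure, no segmental
  duplications, no N-gaps unless present in the input), so passing tests
  demonstrate correctness of the simulator's bookkeeping, not realism of
  any particular genome build.
* Repeat annotation is accepted both as UCSC rmsk tab tables (0-based, with
  or without the bin column, or a minimal 6-column variant) and as
  RepeatMasker `.out` (1-based, converted on read), auto-detected from the
  header; rows on chromosomes absent from the reference are dropped with a
  logged count. Only (genoName, genoStart, genoEnd, strand, repName,
  repFamily) are consumed.
* VCF output is written directly as VCF 4.2 text (het genotypes phased to
  the carrier: 1|0 for hapA, 0|1 for hapB) and read back through pysam.
* Default problem sizes in the tests and acceptance script (2 × 500 kb
  references, 50/150/150-event clone trees, 200-event micro-homology
  batches) were chosen as the smallest scales at which every mechanism and
  interaction is exercised; all generators scale to larger genomes linearly
  in sequence length.

## Known limitations

* No mutation-signature-aware substitution contexts, population allele
  frequencies, replication-timing or fragile-site bias.
* No composite catastrophic events (chromothripsis, chromoplexy); complex
  genomes arise only from event accumulation.
* Homology-mediated insertion requires three forward-strand family members;
  otherwise it falls back to the non-homologous mechanism.
* Foreign-insertion and germline-inserted bases have no reference
  projection: they appear in FASTA and event tables but not in segments.
* Expected coverage ignores GC and mappability bias; it is the copy-number
  expectation only.
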