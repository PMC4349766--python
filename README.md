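# somaticsim

Simulated cancer genomes with fully known somatic structural variants (SVs)
and copy-number variants (CNVs), for benchmarking somatic SV/CNV callers.

Detecting somatic SVs and CNVs from tumor sequencing data is confounded by
exactly the sample properties a caller cannot control: abnormal base ploidy
(aneuploidy), sub-clonal heterogeneity, and contamination by normal cells
(purity). A benchmark needs genomes where every event, breakpoint, and
per-segment copy state is known. `somaticsim` builds such genomes:

1. **Germline stage** — simulates SNVs and small INDELs (< 50 bp) against a
   reference at configurable transition/transversion (Ts/Tv), het/hom, and
   INDEL/SNV ratios, producing a phased diploid *personal genome* (FASTA) and
   a VCF. Heterozygous loci later provide B-allele-frequency (BAF) truth.
2. **Aneuploidy stage** — sets the tumor base ploidy per chromosome
   (1n: one parental copy kept at random; 3n: one copy doubled; even n:
   genome multiplied; odd n ≥ 5: multiplied plus one extra copy) and applies
   whole/segmental chromosome duplications and deletions.
3. **SV stage** — places insertions, deletions, inversions, tandem
   duplications, and balanced/unbalanced inter- plus intra-chromosomal
   translocations under three breakpoint mechanisms: uniformly random
   breakpoints with engineered micro-homology (≤ 20 bp), breakpoints at
   homologous offsets inside compatible repeat elements of one family
   (inversions need opposite strands, deletions/duplications the same
   strand), and insertion of novel sequence sharing no 30-mer with the
   reference. Each event hits exactly one chromosome copy, which is what
   creates allele-specific copy number and loss of heterozygosity (LOH).
4. **Heterogeneity stage** — clone-evolution model (founder clone whose
   events are inherited verbatim by descendants that add their own) or
   cancer-stem-cell model (independent clones); plus the expected
   segment-level signal of any mixture: for tumor fractions `f_k`, purity
   `p = Σ f_k`, and per-clone parental copy counts `(a_k, b_k)`,

   ```
   r(s)   = [Σ_k f_k (a_k + b_k) + (1 − p)·2] / 2
   baf(s) = [Σ_k f_k b_k + (1 − p)] / [Σ_k f_k (a_k + b_k) + (1 − p)·2]
   ```

Every clone is emitted as FASTA (one record per chromosome copy) together
with a complete truth set: events table, breakpoints (BEDPE, 0-based
half-open), per-segment `(copies_A, copies_B)` with total CN, LOH flag
(`min(copies_A, copies_B) = 0` and total ≥ 1) and expected BAF, per-locus
BAF at phased heterozygous germline sites, and a mixing manifest for driving
an external read simulator (e.g. ART). Read simulation itself is out of
scope.

## Worked example

No downloads are needed: the package generates its own references.

```bash
somaticsim make-fixture --out fixture --chroms 2 --length 500000 --seed 1
somaticsim germline --reference fixture/reference.fa --out germline \
    --seed 1 --snv-count 2000
somaticsim tumor --reference fixture/reference.fa --rmsk fixture/repeats.tsv \
    --vcf germline/germline.vcf --out tumor --seed 1 \
    --n-events 50 --descendants 150,150
somaticsim mix --clones tumor --fractions 0.3,0.2,0.1 --purity 0.6 --out mix
```

which prints

```
INFO somaticsim: wrote synthetic reference (2 x 500000 bp, 28 repeats) to fixture
INFO somaticsim.germline: simulated 2000 SNVs + 200 INDELs
INFO somaticsim: wrote 2200 variants (1310 het) to germline
INFO somaticsim.clones: founder clone0: 50 SV events, 2 aneuploidy events
INFO somaticsim.truth: clone clone0: wrote 4 copies, 50 events, 61 junction rows, 142 segments
INFO somaticsim.truth: clone clone1: wrote 4 copies, 150 events, 184 junction rows, 202 segments
INFO somaticsim.truth: clone clone2: wrote 4 copies, 150 events, 196 junction rows, 250 segments
INFO somaticsim.clones: wrote mixture manifest with 4 components, 432 signal segments
```

The founder clone carries 50 SV events; each descendant inherits them and
adds 100 of its own, for 150 total (descendant counts are totals by default;
`--additional-counts` flips the semantics). The truth tables read, e.g.:

```
# tumor/clone0/breakpoints.bedpe
chr1  354294  354295  chr1  360570  360571  clone0.e0000  INV:NONHOM   0
chr2  78281   78282   chr2  64025   64026   clone0.e0001  TDUP:NONHOM  18

# mix/expected_signal.tsv
chrom  start  end  expected_coverage_ratio  expected_baf
chr1   100    342  1.05                     0.476190
```

The second BEDPE row is a tandem duplication whose junction shares an
18 bp micro-homology tract with the reference; the signal row says that at
60% purity this segment's read depth should sit 5% above normal with het
BAFs pulled to 0.476 — the quantities a CNV caller should recover.

Segment tables may contain sub-50 bp `(0,0)` or `(1,0)` slivers at germline
INDEL sites: segments are exact reference projections, and bases deleted in
the personal genome project to nothing. Filter by segment length if only
somatic CNVs are of interest.

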