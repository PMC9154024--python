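# splicigen

Splice-variant neoantigen prediction from tumor and matched-normal RNA-seq.

Tumors with few somatic mutations (acute myeloid leukemia is the canonical
example) often carry widespread aberrant splicing instead. Unannotated splice
junctions expressed in the tumor but absent from matched normal tissue can
produce junction-spanning peptides that the immune system has never seen —
candidate targets for therapeutic vaccines. `splicigen` predicts these
splice-variant neoantigens directly from aligned RNA-seq reads, without
requiring DNA sequencing, and ships a complete in-silico validation harness
so the whole pipeline can be exercised and benchmarked on a laptop with no
external downloads.

## Method

Given tumor and matched-normal alignments (BAM/SAM from a splice-aware
aligner), a genome FASTA and a GENCODE-style annotation:

1. **Differential k-mer search.** Multi-string Burrows–Wheeler indexes are
   built over both read collections (each read plus its reverse complement by
   default). A depth-first search runs in lockstep over the two indexes,
   refining both backward-search intervals with the same symbol at each step
   and pruning any branch whose tumor count falls below `T_min`. It emits the
   *minimal* tumor-specific k-mers: strings with tumor count ≥ `T_min` = 21
   and normal count ≤ `N_max` = 3 none of whose proper substrings qualify,
   capped at 90% of read length.
2. **Splice graph.** A graph is built from the tumor alignments: nodes are
   covered genomic segments partitioned at every junction boundary and
   annotated exon boundary; edges are adjacencies, splice junctions (one per
   distinct `N`-operation intron, with unique/total read support), and
   SNV/insertion/deletion edges (support ≥ 10; SNVs additionally a one-sided
   binomial test against a 1% error null at p ≤ 5·10⁻⁶). Tumor-specific
   k-mers are located in read sequences by multi-pattern matching and
   projected through each read's CIGAR onto graph paths.
3. **Junction calling and peptides.** A junction is called tumor-specific
   when it lies on a junction-spanning k-mer path, has ≥ 20 unique tumor
   reads and < 3 unique normal reads, and matches no annotated intron. For
   each called junction the in-frame variant transcript is rebuilt from an
   annotated start codon through the novel junction (junctions supported by
   < 15 k-mer-bearing reads are filtered), translated, and every 8–11mer
   window spanning the junction is kept if it occurs nowhere in the reference
   peptidome. Surviving peptides are scored per HLA allele; predicted binding
   affinity < 500 nM defines a predicted neoantigen. Binding prediction is a
   pluggable interface: an adapter for an installed netMHCpan-style binary,
   or a deterministic hash-based stub for hermetic runs.

The simulation harness mirrors the method's published validation: it selects
protein-coding genes with ≥ 8 annotated isoforms (5 per chromosome), injects
one novel junction per gene of a chosen class — exon skipping, partial exon
loss, or partial intron gain — into every transcript able to form it, writes
tumor/normal GTFs, simulates 1000 paired 100 bp reads per transcript with
truth spliced alignments, derives ground-truth junctions (> 10 uniquely
mapping reads in tumor, absent from the similarly filtered normal set), and
scores predictions by sensitivity = TP/(TP+FN) and precision = TP/(TP+FP).

## Worked example

Simulate a two-gene exon-skipping dataset, call junctions, and score them:

```
$ splicigen simulate --junction-class exon_skipping --n-genes 2 --n-chroms 1 \
      --reads-per-transcript 150 --seed 5 --out sim
$ splicigen call --tumor-bam sim/tumor.truth.sam --normal-bam sim/normal.truth.sam \
      --annotation sim/annotation.gtf --genome sim/genome.fa --out calls
$ cat calls/junctions.tsv
chrom   intron_start  intron_end  strand  class          annotated  tumor_unique_reads  normal_unique_reads
chr1    878           1258        -       exon_skipping  0          1200                0
chr1    2761          3174        +       exon_skipping  0          52                  0
$ splicigen evaluate --predicted calls/junctions.tsv \
      --truth sim/truth_junctions.tsv --out perf.json
{"tp": 2, "fp": 0, "fn": 0, "sensitivity": 1.0, "precision": 1.0}
```

Both injected junctions are recovered: each is unannotated, crossed by
abundant tumor-specific k-mer-bearing reads (1200 and 52 unique junction
reads respectively, far above the 20-read floor) and completely absent from
the matched normal, so sensitivity and precision are both 1.0. Intron
coordinates in the TSV are 1-based inclusive, the convention used by aligner
splice-junction tables.

The same pipeline is available as a library (`splicigen.run_pipeline`),
returning called junctions, variant transcripts, filtered peptides and
binding calls as Python objects.

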