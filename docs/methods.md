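# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `splicigen`.

## Differential k-mer model

The unit of tumor specificity is a nucleotide string that occurs at least
`t_min` times across the tumor read collection and at most `n_max` times in
the matched normal collection. Defaults are `t_min = 21` and `n_max = 3`,
the method's published operating point; both are plain occurrence counts
(overlapping occurrences within one read each count, duplicate reads are not
collapsed unless `deduplicate_reads` is set — with no published guidance on
duplicate handling, no deduplication is the default). K-mer length is capped
at `floor(0.9 × read length)` so that every k-mer fits inside reads with
margin for matching.

Counting is served by a multi-string BWT over {terminator, A, C, G, T} with
terminators collating below the bases and ordered by string index. The
search proceeds by leftward (backward-search) extension, in lockstep: both
indexes' intervals are refined with the same symbol, and a branch is pruned
as soon as its tumor interval is narrower than `t_min` — occurrence counts
are monotone non-increasing under extension, so pruning loses nothing.

**Minimality.** The search reports *minimal* differential strings: a
qualifying string none of whose proper substrings qualifies. By count
monotonicity it suffices that neither immediate substring (drop the first or
the last base) qualifies: any deeper qualifying substring would force one of
those to qualify too. Minimal strings maximize read-matching recall at fixed
thresholds; the non-minimal behaviour (report every qualifying string up to
the cap) remains reachable via `minimal=False`.

**Strandedness.** The default `with_revcomp` mode indexes every read
together with its reverse complement, making counts strand-symmetric, which
is correct for unstranded libraries (including the simulated ones);
`forward_only` is provided for stranded protocols.

**Construction.** Suffixes are sorted with a radix strategy tailored to
short reads: each suffix is keyed by its 2-bit-packed sequence padded with
the smallest symbol, plus a length tie-break that reproduces the
terminator-sorts-first order. Two exactness-preserving optimizations keep
desk-scale runs fast: (i) duplicate reads are collapsed before sorting and
their rows re-expanded by multiplicity afterwards — equal suffixes carry
identical preceding symbols, and their relative order never changes any
backward-search interval; (ii) an optional comparison-depth cap
(`max_query_len`) truncates sort keys; ties beyond the cap are broken
consistently by enumeration order, which preserves the LF-mapping, so
counting stays exact for every pattern up to the cap. The pipeline caps at
the k-mer length limit, the longest pattern it ever queries; standalone
indexes default to unlimited depth.

## Splice graph

Nodes are maximal covered reference runs split at every observed junction
donor/acceptor and every annotated exon boundary; coverage gaps break
adjacency edges. Junction edges are created only from `N` CIGAR operations,
never inferred from coverage, and carry unique/total read support. A read is
"uniquely mapping" when `NH == 1`, falling back to `MAPQ ≥ 50` when the NH
tag is absent (the rule and MAPQ threshold are configurable; the notion is
not pinned down further by the method's description).

Sequence-variant edges require `variant_min_support = 10` reads. SNV
candidates additionally pass a one-sided exact binomial upper-tail test of
the mismatch count against a per-base error null (`snv_error_rate = 0.01`,
threshold `p ≤ 5e-6`) at the observed depth — the simplest null consistent
with calling SNV edges from pileups. Mismatches are found by direct
comparison against the reference genome (which the graph builder requires
anyway), rather than from MD tags; insertion and deletion edges come
straight from `I`/`D` operations.

K-mer occurrences in reads are found by multi-pattern matching. Two
equivalent routes exist: a hand-rolled Aho–Corasick automaton (the general
path, also used for patterns longer than 32 nt), and a vectorised matcher
that packs read windows into 2-bit codes and tests membership against the
sorted pattern codes — used for the large simulated read sets. Both routes,
and the CIGAR projection that follows them, are cross-checked against naive
scanning in the test suite. A projection that would place matched bases
inside a soft clip is discarded; a projection crossing one or more `N`
operations spans those junctions.

## Junction calling, transcripts, peptides

A junction is called when all four conditions hold: ≥ 1 junction-spanning
tumor-specific k-mer read; tumor unique support ≥ 20; normal unique support
< 3 (strict); intron not annotated. Classification against the annotation:
*exon skipping* if both sites are annotated sites of one transcript with a
complete internal exon inside the intron; *partial exon loss* / *partial
intron gain* if exactly one site is novel and lies strictly inside an
annotated exon / intron; otherwise *other*. When isoforms disagree about
whether the novel position is exonic or intronic, the exonic reading wins.

Variant transcripts are anchored on annotated coding transcripts whose CDS
start lies upstream of the junction and whose exon chain reaches the
junction's upstream boundary; the upstream path follows the anchor's
annotated chain exactly (re-traversing the graph upstream would add
ambiguity without changing the junction-spanning windows). One candidate is
emitted per anchor; identical peptides are deduplicated later at the peptide
level. Downstream of the junction the path follows graph segments, choosing
at each boundary by preference: an edge consistent with an observed mate
span (a read pair bracketing the edge — the minimal usable reading of
paired-end guidance), else an annotated edge, else the best-supported edge.
The walk stops after `3 × max(peptide length) + 3` bases, enough to contain
every junction-spanning window; translation then truncates at the first stop
codon. Negative-strand genes are assembled in transcription order and
reverse-complemented before translation. Junctions supported by < 15
junction-spanning k-mer reads are filtered at this stage.

Peptide windows (lengths {8,9,10,11} by default) must contain at least one
residue with a base strictly upstream of the junction and one with a base at
or after it; a codon split by the junction satisfies both sides alone.
"Present in the reference peptidome" means *exact substring of any protein*
translated from the annotated coding transcripts — the conservative reading,
since any peptide occurring inside a normal protein is not tumor-specific.
Codons containing non-ACGT bases terminate translation at that point. A
peptide is a predicted binder iff its predicted affinity is strictly below
500 nM. The affinity predictor is an interface: `NetMHCpanPredictor` shells
out to an installed binary; `StubPredictor` derives a deterministic affinity
in [1, 50000] nM from a fixed-key hash of (allele, peptide) so the full
pipeline, including the strict binder rule, runs hermetically. The stub has
no immunological meaning.

## Simulation harness

`make_fixture_genome` emulates a GENCODE-annotated genome at desk scale:
genes with 8–12 exons (exon lengths multiples of 3, 24–48 bp; introns
60–200 bp; both strands), eight or more isoforms per gene generated by
skipping blocks of 1–2 internal exons and shrinking internal boundaries by
whole codons. Keeping every exon length ≡ 0 (mod 3) means codons never span
junctions, so drawing exon sequence from the 61 sense codons guarantees
every isoform's CDS is in frame and internally stop-free by construction.
Each CDS starts with ATG at the 5' end of the first exon and ends before a
stop codon that opens the terminal exon.

Junction injection follows the published procedure: per chromosome, up to 5
eligible genes (protein-coding, ≥ 8 isoforms) are selected at random; per
gene one candidate donor/acceptor combination of the requested class that
matches no annotated junction of the gene is applied to every transcript
able to form it; transcripts that cannot form it, and genes with no viable
candidate, are excluded from both tumor and normal sets (the normal set is
the unmodified reference version of exactly the retained transcripts).
Candidates are kept local — skips of 1–3 exons, truncation of the exon
adjacent to an existing intron, a novel site ≥ 6 bp inside an intron — so
injected variants resemble real splicing aberrations rather than removing
most of a transcript. Novel interior positions are uniform with a 6 bp
margin from the boundary.

Read simulation draws, per transcript, 1000 fragment positions uniformly
with lengths from N(250, 25) truncated to [read length, transcript length]
(typical Illumina values; the method's description does not fix a fragment
model), and emits 100 bp pairs with independent per-base substitution errors
at 0.1%. Every read carries its correct spliced alignment (CIGAR with `N`
across introns, NH=1, MAPQ 255), so the pipeline runs without an external
aligner; externally aligned BAMs can be substituted through the CLI. A
description elsewhere of 8000 reads per transcript is reachable by raising
`sim_reads_per_transcript`; 1000 pairs is the default.

Ground truth: junctions with ≤ 10 uniquely mapping reads are filtered in
both samples; the truth set is the filtered tumor set minus the filtered
normal set. Scoring is junction-level sensitivity and precision, per class
and overall; a false positive is attributed to the class of the nearest
truth junction on its chromosome (the attribution rule is otherwise
unspecified). Medians and means aggregate replicate runs.

**What the simulation does and does not show.** The fixture has uniform
expression, uniform fragment sampling, substitution-only errors, perfectly
spliced truth alignments, and genes far smaller than human ones. Passing
the benchmark therefore demonstrates the pipeline's logic — indexing,
differential search, projection, calling, scoring — at realistic coverage,
not robustness to alignment artifacts, expression heterogeneity, indels, or
annotation incompleteness in real data. Borderline truth artifacts (an
annotated junction straddling the 10-read filter in one sample only) appear
at very low simulated coverage and vanish at the default 1000 pairs per
transcript.

## Problem sizes and determinism

The shipped benchmark uses 20 eligible genes over 4 chromosomes, three
junction classes and three replicate seeds — about 180 injected junctions
and ~30 M indexed bases per sample per replicate; it completes in roughly 7
minutes on one CPU within 4 GB. All randomness flows from explicit seeds
through `numpy.random.default_rng`; identical seeds reproduce byte-identical
genomes, annotations, reads and results. Ties everywhere (anchor ordering,
k-mer output, file emission) are broken deterministically.

## Known limitations

- No fusion (inter-gene/inter-chromosome) edges, no novel transcription
  starts, and no quantification (TPM/PSI) of variant transcripts.
- Junction identity is strand-agnostic, matching aligner SJ tables; two
  overlapping genes on opposite strands could in principle collide.
- The mate-consistency preference is a simple bracketing predicate, isolated
  behind one function, and matters only when the splice graph branches
  downstream of a called junction.
- MHC class II, percentile ranks, immunogenicity and proteasomal-cleavage
  modelling are out of scope; only nM affinity with the strict 500 nM rule
  is implemented.
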