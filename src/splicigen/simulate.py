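"""In-silico splice-variant simulation and evaluation harness.

This module builds the benchmark the pipeline is validated against:

1. :func:`make_fixture_genome` generates a random desk-scale genome and a
   GENCODE-like annotation whose protein-coding genes carry many annotated
   isoforms (exon skipping and alternative splice-site usage), every isoform
   having a valid, internally stop-free CDS.
2. :func:`simulate_variant_annotation` injects one novel tumor-specific
   splice junction of a requested class (exon skipping, partial exon loss,
   partial intron gain) into each selected gene, producing a tumor
   annotation (modified transcripts) and a matched normal annotation (the
   reference versions of the same transcripts).
3. :func:`simulate_reads` simulates paired 100 bp reads per transcript with
   a truncated-normal fragment model and substitution errors, emitting the
   *truth* spliced alignments directly so the pipeline can be exercised
   without an external aligner.
4. :func:`derive_truth_junctions` and :func:`evaluate_predictions` implement
   the ground-truth filter (junctions with <= 10 uniquely mapping reads
   discarded; tumor-only junctions kept) and sensitivity/precision scoring.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .config import PipelineConfig
from .io import (
    AlignedRead,
    Annotation,
    Gene,
    Genome,
    Transcript,
    reverse_complement,
    write_fasta,
    write_gtf,
)

log = logging.getLogger(__name__)

JUNCTION_CLASSES = ("exon_skipping", "partial_exon_loss", "partial_intron_gain")

#: the 61 sense codons of the standard code (no TAA/TAG/TGA)
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


# ---------------------------------------------------------------------------
# Fixture genome
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _stopfree_seq(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_SENSE_CODONS), n_codons)
    return "".join(_SENSE_CODONS[i] for i in idx)


def _make_isoforms(
    rng: np.random.Generator,
    exons: list[tuple[int, int]],
    n_isoforms: int,
) -> list[list[tuple[int, int]]]:
    """Derive isoforms from a full exon chain by skipping internal exon
    blocks and shrinking internal boundaries by whole codons.

    Keeping every exon length a multiple of 3 (and shrinking only in steps
    of 3) keeps all isoform CDSs in frame and internally stop-free, since
    codons never span junctions.
    """
    n = len(exons)
    isoforms: list[list[tuple[int, int]]] = [list(exons)]
    seen = {tuple(exons)}
    attempts = 0
    while len(isoforms) < n_isoforms and attempts < 400:
        attempts += 1
        chain = [list(e) for e in exons]
        # skip a block of 1-2 internal exons
        blk = int(rng.integers(1, 3))
        i0 = int(rng.integers(1, n - 1 - (blk - 1)))
        keep = [c for k, c in enumerate(chain) if not (i0 <= k < i0 + blk)]
        # optionally shrink one internal boundary by 3 or 6 bases
        if rng.random() < 0.5 and len(keep) > 2:
            k = int(rng.integers(1, len(keep) - 1))
            delta = int(rng.choice([3, 6]))
            s, e = keep[k]
            if e - s - delta >= 9:
                if rng.random() < 0.5:
                    keep[k] = [s + delta, e]  # alternative acceptor
                else:
                    keep[k] = [s, e - delta]  # alternative donor
        tup = tuple(tuple(c) for c in keep)
        if tup not in seen:
            seen.add(tup)
            isoforms.append([tuple(c) for c in keep])
    return isoforms


def make_fixture_genome(
    n_genes: int,
    n_chroms: int = 1,
    seed: int = 0,
    cfg: Optional[PipelineConfig] = None,
    out_dir: Optional[str] = None,
) -> tuple[Genome, Annotation]:
    """Generate a random genome plus annotation at desk scale.

    ``n_genes`` genes are distributed round-robin over ``n_chroms``
    chromosomes.  Each gene has 8-12 exons (lengths a multiple of 3, coding
    sequence free of in-frame stops), at least ``cfg.sim_min_isoforms``
    annotated isoforms, an ATG start at the 5' end of the first exon and a
    stop codon at the start of the last exon (so the CDS covers every exon
    but the last).  Deterministic per seed; optionally writes
    ``genome.fa``/``annotation.gtf`` under ``out_dir``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    cfg = cfg or PipelineConfig()
    rng = np.random.default_rng(seed)
    chrom_names = [f"chr{i + 1}" for i in range(n_chroms)]
    seqs: dict[str, list[str]] = {c: [] for c in chrom_names}
    cursors: dict[str, int] = {c: 0 for c in chrom_names}
    genes: list[Gene] = []

    for gi in range(n_genes):
        chrom = chrom_names[gi % n_chroms]
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(8, 13))
        exon_lens = [3 * int(rng.integers(8, 17)) for _ in range(n_exons)]
        intron_lens = [int(rng.integers(60, 201)) for _ in range(n_exons - 1)]
        spacer = int(rng.integers(300, 801))

        # coding sequence in transcription order: ATG, stop-free body,
        # stop codon opening the last exon, stop-free 3' tail
        tx_pieces: list[str] = []
        for k, L in enumerate(exon_lens):
            if k == 0:
                body = "ATG" + _stopfree_seq(rng, L // 3 - 1)
            elif k == n_exons - 1:
                body = "TAA" + _stopfree_seq(rng, L // 3 - 1)
            else:
                body = _stopfree_seq(rng, L // 3)
            tx_pieces.append(body)
        if strand == "-":
            tx_pieces = [reverse_complement(p) for p in reversed(tx_pieces)]
            exon_lens = exon_lens[::-1]

        parts = [_random_seq(rng, spacer)]
        pos = cursors[chrom] + spacer
        gexons: list[tuple[int, int]] = []
        for k, L in enumerate(exon_lens):
            parts.append(tx_pieces[k])
            gexons.append((pos, pos + L))
            pos += L
            if k < n_exons - 1:
                parts.append(_random_seq(rng, intron_lens[k]))
                pos += intron_lens[k]
        seqs[chrom].append("".join(parts))
        cursors[chrom] = pos

        gene_id = f"G{gi + 1:03d}"
        gene = Gene(
            gene_id=gene_id, chrom=chrom, strand=strand, name=gene_id,
            biotype="protein_coding", start=gexons[0][0], end=gexons[-1][1],
        )
        chains = _make_isoforms(rng, gexons, cfg.sim_min_isoforms)
        for ti, chain in enumerate(chains):
            tid = f"{gene_id}.t{ti + 1}"
            t = Transcript(
                transcript_id=tid, gene_id=gene_id, chrom=chrom, strand=strand,
                exons=list(chain),
            )
            t.cds, t.cds_phases, t.start_codon = _cds_for_chain(chain, strand)
            gene.transcripts[tid] = t
        genes.append(gene)

    for c in chrom_names:
        seqs[c].append(_random_seq(rng, 300))
    genome = Genome.from_dict({c: "".join(p) for c, p in seqs.items()})
    annotation = Annotation(genes)
    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        write_fasta(
            {c: genome.fetch(c, 0, genome.lengths[c]) for c in genome.chroms},
            os.path.join(out_dir, "genome.fa"),
        )
        write_gtf(annotation, os.path.join(out_dir, "annotation.gtf"))
    return genome, annotation


def _cds_for_chain(
    chain: Sequence[tuple[int, int]], strand: str
) -> tuple[list[tuple[int, int]], list[int], int]:
    """CDS chain covering every exon except the terminal one (which opens
    with the stop codon in transcription order)."""
    if strand == "+":
        cds = [tuple(e) for e in chain[:-1]]
        start_codon = chain[0][0]
    else:
        cds = [tuple(e) for e in chain[1:]]
        start_codon = chain[-1][1]
    phases: list[int] = []
    acc = 0
    order = cds if strand == "+" else list(reversed(cds))
    ph = {}
    for s, e in order:
        ph[(s, e)] = (3 - acc % 3) % 3
        acc += e - s
    phases = [ph[tuple(c)] for c in cds]
    return [tuple(c) for c in cds], phases, start_codon


# ---------------------------------------------------------------------------
# Junction injection
# ---------------------------------------------------------------------------


@dataclass
class InjectedJunction:
    gene_id: str
    chrom: str
    intron_start: int  # 0-based, inclusive (first intronic base)
    intron_end: int    # 0-based, exclusive
    junction_class: str
    transcript_ids: list[str] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.intron_start, self.intron_end)


@dataclass
class SimTruth:
    junction_class: str
    junctions: list[InjectedJunction]
    tumor_annotation: Annotation
    normal_annotation: Annotation
    tumor_gtf: Optional[str] = None
    normal_gtf: Optional[str] = None

    def truth_keys(self) -> set[tuple[str, int, int]]:
        return {j.key for j in self.junctions}


def _candidate_junctions(
    gene: Gene, annotation: Annotation, junction_class: str, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Enumerate candidate (intron_start, intron_end) pairs of the class
    whose sites avoid every annotated junction of the gene."""
    out: list[tuple[int, int]] = []
    chrom = gene.chrom
    margin = 6
    for t in gene.transcripts.values():
        exons = t.exons
        n = len(exons)
        if junction_class == "exon_skipping":
            for a in range(n - 1):
                for b in range(a + 2, min(a + 5, n)):  # skip 1-3 exons
                    l, r = exons[a][1], exons[b][0]
                    if not annotation.is_annotated_intron(chrom, l, r):
                        out.append((l, r))
        elif junction_class == "partial_exon_loss":
            for a in range(n - 1):
                # annotated donor, novel acceptor truncating the next exon
                l = exons[a][1]
                s, e = exons[a + 1]
                if e - s > 2 * margin:
                    p = int(rng.integers(s + margin, e - margin))
                    out.append((l, p))
                # novel donor truncating exon a, annotated acceptor of a+1
                s, e = exons[a]
                if e - s > 2 * margin:
                    p = int(rng.integers(s + margin, e - margin))
                    out.append((p, exons[a + 1][0]))
        elif junction_class == "partial_intron_gain":
            for a in range(n - 1):
                il, ir = exons[a][1], exons[a + 1][0]
                if ir - il > 2 * margin:
                    p = int(rng.integers(il + margin, ir - margin))
                    if rng.random() < 0.5:
                        out.append((il, p))  # novel acceptor inside the intron
                    else:
                        out.append((p, ir))  # novel donor inside the intron
        else:
            raise ValueError(f"unknown junction class {junction_class!r}")
    # drop anything colliding with an annotated junction or its exact sites
    uniq = []
    seen = set()
    for l, r in out:
        if (l, r) in seen:
            continue
        seen.add((l, r))
        if annotation.is_annotated_intron(chrom, l, r):
            continue
        uniq.append((l, r))
    return uniq


def _apply_junction(
    t: Transcript, l: int, r: int, junction_class: str
) -> Optional[list[tuple[int, int]]]:
    """Apply intron (l, r) of the given class to a transcript's exon chain.

    Returns the new chain, or None when the transcript cannot form the
    junction (its exon structure lacks the required sites).
    """
    exons = t.exons
    ends = {e for _, e in exons}
    starts = {s for s, _ in exons}

    if junction_class == "exon_skipping":
        if l not in ends or r not in starts:
            return None
        inside = [ex for ex in exons if ex[0] >= l and ex[1] <= r]
        if not inside:
            return None
        # no exon may straddle the removed interval
        for s, e in exons:
            if (s < l < e) or (s < r < e):
                return None
        new = [ex for ex in exons if ex[1] <= l or ex[0] >= r]
    elif junction_class == "partial_exon_loss":
        donor_annot = l in ends
        accept_annot = r in starts
        l_in_exon = any(s < l < e for s, e in exons)
        r_in_exon = any(s < r < e for s, e in exons)
        if donor_annot and r_in_exon:
            pass
        elif accept_annot and l_in_exon:
            pass
        else:
            return None
        new = []
        for s, e in exons:
            if e <= l or s >= r:
                new.append((s, e))
            elif s < l < e:
                new.append((s, l))
            elif s < r < e:
                new.append((r, e))
            # exons fully inside (l, r) are dropped
    elif junction_class == "partial_intron_gain":
        hit = None
        for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
            if e0 == l and e0 < r < s1:
                hit = ("acceptor", (s0, e0), (s1, e1))
                break
            if s1 == r and e0 < l < s1:
                hit = ("donor", (s0, e0), (s1, e1))
                break
        if hit is None:
            return None
        new = []
        for ex in exons:
            if hit[0] == "acceptor" and ex == hit[2]:
                new.append((r, ex[1]))  # exon gains the intronic bases [r, s1)
            elif hit[0] == "donor" and ex == hit[1]:
                new.append((ex[0], l))  # exon gains [e0, l)
            else:
                new.append(ex)
    else:
        raise ValueError(junction_class)

    if len(new) < 2:
        return None
    for (s0, e0), (s1, e1) in zip(new, new[1:]):
        if s1 <= e0:
            return None
    if (l, r) not in [(e0, s1) for (_, e0), (s1, _) in zip(new, new[1:])]:
        return None
    if (l, r) in [(e, s) for (_, e), (s, _) in zip(t.exons, t.exons[1:])]:
        return None  # not novel for this transcript
    return new


def simulate_variant_annotation(
    annotation: Annotation,
    junction_class: str,
    cfg: PipelineConfig,
    seed: int = 0,
    genome: Optional[Genome] = None,
    out_dir: Optional[str] = None,
) -> SimTruth:
    """Inject one novel junction of ``junction_class`` per selected gene.

    Per chromosome, up to ``cfg.sim_genes_per_chrom`` eligible genes
    (protein-coding with >= ``cfg.sim_min_isoforms`` isoforms) are selected
    at random.  For each, a candidate donor/acceptor combination of the
    requested class that matches no annotated junction of the gene is
    chosen, and applied to every transcript able to form it; transcripts
    that cannot form it — and genes with no viable candidate — are excluded
    from both the tumor and the normal sets.
    """
    if junction_class not in JUNCTION_CLASSES:
        raise ValueError(f"unknown junction class {junction_class!r}")
    rng = np.random.default_rng(seed)
    tumor_genes: list[Gene] = []
    normal_genes: list[Gene] = []
    injected: list[InjectedJunction] = []

    any_eligible = False
    for chrom in sorted(annotation.by_chrom):
        eligible = [
            g
            for g in annotation.by_chrom[chrom]
            if g.biotype == "protein_coding"
            and len(g.transcripts) >= cfg.sim_min_isoforms
        ]
        if eligible:
            any_eligible = True
        if len(eligible) > cfg.sim_genes_per_chrom:
            pick = rng.choice(len(eligible), cfg.sim_genes_per_chrom, replace=False)
            eligible = [eligible[i] for i in sorted(pick)]
        for gene in eligible:
            cands = _candidate_junctions(gene, annotation, junction_class, rng)
            rng.shuffle(cands)
            chosen = None
            for l, r in cands:
                formed = {
                    tid: chain
                    for tid, t in sorted(gene.transcripts.items())
                    if (chain := _apply_junction(t, l, r, junction_class))
                }
                if formed:
                    chosen = (l, r, formed)
                    break
            if chosen is None:
                log.info("gene %s: no viable %s junction; excluded",
                         gene.gene_id, junction_class)
                continue
            l, r, formed = chosen
            tg = Gene(gene_id=gene.gene_id, chrom=chrom, strand=gene.strand,
                      name=gene.name, biotype=gene.biotype,
                      start=gene.start, end=gene.end)
            ng = Gene(gene_id=gene.gene_id, chrom=chrom, strand=gene.strand,
                      name=gene.name, biotype=gene.biotype,
                      start=gene.start, end=gene.end)
            for tid, chain in formed.items():
                ref = gene.transcripts[tid]
                vt = Transcript(
                    transcript_id=tid + "_var", gene_id=gene.gene_id,
                    chrom=chrom, strand=gene.strand, exons=chain,
                )
                tg.transcripts[vt.transcript_id] = vt
                nt = Transcript(
                    transcript_id=tid, gene_id=gene.gene_id, chrom=chrom,
                    strand=gene.strand, exons=list(ref.exons),
                    cds=list(ref.cds), cds_phases=list(ref.cds_phases),
                    start_codon=ref.start_codon,
                )
                ng.transcripts[tid] = nt
            tumor_genes.append(tg)
            normal_genes.append(ng)
            injected.append(
                InjectedJunction(
                    gene_id=gene.gene_id, chrom=chrom, intron_start=l,
                    intron_end=r, junction_class=junction_class,
                    transcript_ids=sorted(formed),
                )
            )
    if not any_eligible:
        raise ValueError(
            f"annotation has no eligible gene (protein-coding with >= "
            f"{cfg.sim_min_isoforms} isoforms)"
        )

    truth = SimTruth(
        junction_class=junction_class,
        junctions=injected,
        tumor_annotation=Annotation(tumor_genes),
        normal_annotation=Annotation(normal_genes),
    )
    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        truth.tumor_gtf = os.path.join(out_dir, "tumor.gtf")
        truth.normal_gtf = os.path.join(out_dir, "normal.gtf")
        write_gtf(truth.tumor_annotation, truth.tumor_gtf)
        write_gtf(truth.normal_annotation, truth.normal_gtf)
    return truth


# ---------------------------------------------------------------------------
# Read simulation with truth alignments
# ---------------------------------------------------------------------------


def simulate_reads(
    annotation: Annotation,
    genome: Genome,
    cfg: PipelineConfig,
    seed: int = 0,
    sample: str = "s",
) -> list[AlignedRead]:
    """Simulate ``cfg.sim_reads_per_transcript`` paired reads per transcript.

    Fragment lengths are drawn from N(sim_fragment_mean, sim_fragment_sd)
    truncated to [read length, transcript length]; start positions are
    uniform; substitution errors occur at ``cfg.sim_error_rate`` per base.
    The returned records are the *truth* alignments: every read carries its
    correct spliced CIGAR (N across introns), NH=1 and MAPQ 255.
    Transcripts shorter than the read length are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    rl = cfg.sim_read_len
    reads: list[AlignedRead] = []
    for t in sorted(annotation.transcripts(), key=lambda t: t.transcript_id):
        tlen = t.length()
        if tlen < rl:
            log.warning("transcript %s (%d bp) shorter than read length; skipped",
                        t.transcript_id, tlen)
            continue
        # genomic-order spliced sequence and cumulative exon offsets
        gseq = "".join(genome.fetch(t.chrom, s, e) for s, e in t.exons)
        exon_lens = [e - s for s, e in t.exons]
        cum = np.concatenate([[0], np.cumsum(exon_lens)])
        n_pairs = cfg.sim_reads_per_transcript
        frag = np.rint(
            rng.normal(cfg.sim_fragment_mean, cfg.sim_fragment_sd, n_pairs)
        ).astype(np.int64)
        frag = np.clip(frag, rl, tlen)
        starts = rng.integers(0, tlen - frag + 1)
        # transcript coordinates run genomically for '+', reversed for '-'
        if t.strand == "-":
            g_lo = tlen - (starts + frag)
        else:
            g_lo = starts
        r1_lo, r1_hi = g_lo, g_lo + rl
        r2_lo, r2_hi = g_lo + frag - rl, g_lo + frag
        if t.strand == "-":
            r1_lo, r1_hi, r2_lo, r2_hi = r2_lo, r2_hi, r1_lo, r1_hi
        # substitution errors, independent per base
        err_mask1 = rng.random((n_pairs, rl)) < cfg.sim_error_rate
        err_mask2 = rng.random((n_pairs, rl)) < cfg.sim_error_rate

        for i in range(n_pairs):
            name = f"{sample}:{t.transcript_id}:{i}"
            mate_info = []
            for mate, (lo, hi, emask) in enumerate(
                [(r1_lo[i], r1_hi[i], err_mask1[i]), (r2_lo[i], r2_hi[i], err_mask2[i])]
            ):
                pos, cigar = _spliced_cigar(t, cum, int(lo), int(hi))
                seq = gseq[int(lo) : int(hi)]
                if emask.any():
                    seq = _apply_errors(seq, emask, rng)
                mate_info.append((pos, cigar, seq))
            (p1, c1, s1), (p2, c2, s2) = mate_info
            reads.append(
                AlignedRead(
                    name=name, seq=s1, chrom=t.chrom, pos=p1, cigar=c1,
                    mapq=255, nh=1, is_paired=True, is_proper_pair=True,
                    is_reverse=False, mate_chrom=t.chrom, mate_pos=p2,
                )
            )
            reads.append(
                AlignedRead(
                    name=name, seq=s2, chrom=t.chrom, pos=p2, cigar=c2,
                    mapq=255, nh=1, is_paired=True, is_proper_pair=True,
                    is_reverse=True, mate_chrom=t.chrom, mate_pos=p1,
                )
            )
    return reads


def _spliced_cigar(
    t: Transcript, cum: np.ndarray, lo: int, hi: int
) -> tuple[int, list[tuple[str, int]]]:
    """Genomic position and CIGAR of a read covering genomic-order spliced
    coordinates [lo, hi) of transcript ``t``."""
    cigar: list[tuple[str, int]] = []
    first = bisect_right(cum, lo) - 1
    pos = t.exons[first][0] + (lo - int(cum[first]))
    x = lo
    k = first
    while x < hi:
        exon_s, exon_e = t.exons[k]
        off = x - int(cum[k])
        take = min(hi - x, (exon_e - exon_s) - off)
        cigar.append(("M", int(take)))
        x += take
        if x < hi:
            gap = t.exons[k + 1][0] - exon_e
            cigar.append(("N", int(gap)))
        k += 1
    return pos, cigar


_OTHER = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}


def _apply_errors(seq: str, mask: np.ndarray, rng: np.random.Generator) -> str:
    chars = list(seq)
    for j in np.flatnonzero(mask):
        chars[j] = _OTHER[chars[j]][int(rng.integers(0, 3))]
    return "".join(chars)


# ---------------------------------------------------------------------------
# Ground truth and scoring
# ---------------------------------------------------------------------------


def derive_truth_junctions(
    tumor_sj: Mapping[tuple[str, int, int], object],
    normal_sj: Mapping[tuple[str, int, int], object],
    cfg: PipelineConfig,
) -> set[tuple[str, int, int]]:
    """Ground-truth junction set from tumor/normal junction support.

    Junctions supported by <= ``cfg.truth_min_unique_reads`` uniquely mapping
    reads are filtered in both samples; the truth set is the filtered tumor
    set minus the filtered normal set.
    """

    def _uniq(v) -> int:
        return v[0] if isinstance(v, (tuple, list)) else int(v)

    tum = {k for k, v in tumor_sj.items() if _uniq(v) > cfg.truth_min_unique_reads}
    nor = {k for k, v in normal_sj.items() if _uniq(v) > cfg.truth_min_unique_reads}
    return tum - nor


@dataclass
class ClassPerf:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else math.nan

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else math.nan


@dataclass
class PerfReport:
    overall: ClassPerf
    per_class: dict[str, ClassPerf]

    @staticmethod
    def aggregate(reports: Sequence["PerfReport"]) -> dict[str, dict[str, float]]:
        """Median and mean sensitivity/precision across replicate reports."""
        out: dict[str, dict[str, float]] = {}
        classes = sorted({c for r in reports for c in r.per_class})
        for label in ["overall"] + classes:
            sens = [
                (r.overall if label == "overall" else r.per_class[label]).sensitivity
                for r in reports
                if label == "overall" or label in r.per_class
            ]
            prec = [
                (r.overall if label == "overall" else r.per_class[label]).precision
                for r in reports
                if label == "overall" or label in r.per_class
            ]
            out[label] = {
                "median_sensitivity": float(np.nanmedian(sens)),
                "median_precision": float(np.nanmedian(prec)),
                "mean_sensitivity": float(np.nanmean(sens)),
                "mean_precision": float(np.nanmean(prec)),
            }
        return out


def evaluate_predictions(
    predicted: Iterable[tuple[str, int, int]],
    truth: Mapping[tuple[str, int, int], str] | Iterable[tuple[str, int, int]],
    classes: Optional[Sequence[str]] = None,
) -> PerfReport:
    """Score predicted junctions against a truth set.

    ``truth`` maps junction keys to class labels (or is a bare key set, in
    which case every truth junction is labelled "other").  A false positive
    is attributed to the class of the nearest truth junction on its
    chromosome, or "other" when the chromosome carries none.
    """
    pred = set(predicted)
    if isinstance(truth, Mapping):
        truth_map = dict(truth)
    else:
        truth_map = {k: "other" for k in truth}
    truth_set = set(truth_map)
    classes = list(classes) if classes else sorted(set(truth_map.values()))

    overall = ClassPerf(
        tp=len(pred & truth_set),
        fp=len(pred - truth_set),
        fn=len(truth_set - pred),
    )
    per_class = {c: ClassPerf() for c in classes}
    for k in truth_set:
        c = truth_map[k]
        if c not in per_class:
            per_class[c] = ClassPerf()
        if k in pred:
            per_class[c].tp += 1
        else:
            per_class[c].fn += 1
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for (chrom, s, e), c in truth_map.items():
        by_chrom.setdefault(chrom, []).append(((s + e) // 2, c))
    for chrom, s, e in pred - truth_set:
        locs = by_chrom.get(chrom)
        if locs:
            mid = (s + e) // 2
            c = min(locs, key=lambda pc: abs(pc[0] - mid))[1]
        else:
            c = "other"
        if c not in per_class:
            per_class[c] = ClassPerf()
        per_class[c].fp += 1
    return PerfReport(overall=overall, per_class=per_class)
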