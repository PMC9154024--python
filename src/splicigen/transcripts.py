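"""Tumor-specific junction calling and variant-transcript inference.

A junction is *called* tumor-specific when four conditions hold: it lies on
at least one junction-spanning tumor-specific k-mer path, its tumor unique
read support meets the calling floor, its normal unique read support is
strictly below the normal ceiling, and its intron matches no annotated
intron.  Called junctions are classified against the annotation as exon
skipping, partial exon loss, partial intron gain, or other.

For each called junction, variant transcripts are rebuilt in frame: an
anchor transcript supplies the annotated start codon and the upstream exon
chain down to the junction; the novel junction is crossed; downstream
sequence follows splice-graph segments, preferring edges consistent with
observed mate spans, then annotated edges, then the best-supported edge,
until enough coding sequence exists to harbor every junction-spanning
peptide window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

from .config import PipelineConfig
from .io import Annotation, Genome, Transcript, reverse_complement
from .splice_graph import JunctionKey, JunctionSupportTable, KmerMatch, SpliceGraph

log = logging.getLogger(__name__)


class JunctionOutsideGeneError(ValueError):
    """The junction overlaps no annotated gene and cannot be classified."""


@dataclass(frozen=True)
class Junction:
    chrom: str
    intron_start: int  # 0-based inclusive (first intronic base)
    intron_end: int    # 0-based exclusive
    strand: str = "."
    tumor_unique_reads: int = 0
    normal_unique_reads: int = 0
    annotated: bool = False
    junction_class: str = "other"
    kmer_read_support: int = 0

    def __post_init__(self):
        if self.intron_end - self.intron_start < 1:
            raise ValueError("intron length must be >= 1")

    @property
    def key(self) -> JunctionKey:
        return (self.chrom, self.intron_start, self.intron_end)

    @property
    def junction_id(self) -> str:
        return f"{self.chrom}:{self.intron_start + 1}-{self.intron_end}"


def _spanning_read_counts(
    kmer_evidence: Union[Mapping[JunctionKey, int], Iterable[KmerMatch]],
) -> dict[JunctionKey, int]:
    if isinstance(kmer_evidence, Mapping):
        return dict(kmer_evidence)
    counts: dict[JunctionKey, set[str]] = {}
    for m in kmer_evidence:
        if not m.spans_junction:
            continue
        for key in m.junctions:
            counts.setdefault(key, set()).add(m.read_name)
    return {k: len(v) for k, v in counts.items()}


def call_tumor_specific_junctions(
    tumor: JunctionSupportTable,
    normal: JunctionSupportTable,
    kmer_evidence: Union[Mapping[JunctionKey, int], Iterable[KmerMatch]],
    annotation: Annotation,
    cfg: PipelineConfig,
) -> list[Junction]:
    """Junctions passing all four tumor-specificity conditions.

    (a) >= 1 spanning tumor-specific k-mer path; (b) tumor unique support
    >= ``junction_tumor_min_reads``; (c) normal unique support strictly
    below ``junction_normal_max_reads``; (d) intron not annotated.
    """
    spanning = _spanning_read_counts(kmer_evidence)
    out: list[Junction] = []
    for key in sorted(tumor):
        chrom, l, r = key
        n_span = spanning.get(key, 0)
        if n_span < 1:
            continue
        if tumor.unique_count(key) < cfg.junction_tumor_min_reads:
            continue
        if normal.unique_count(key) >= cfg.junction_normal_max_reads:
            continue
        if annotation.is_annotated_intron(chrom, l, r):
            continue
        try:
            jclass = classify_junction(key, annotation)
        except JunctionOutsideGeneError:
            jclass = "other"
        genes = annotation.genes_overlapping(chrom, l, r)
        strand = genes[0].strand if genes else "."
        out.append(
            Junction(
                chrom=chrom, intron_start=l, intron_end=r, strand=strand,
                tumor_unique_reads=tumor.unique_count(key),
                normal_unique_reads=normal.unique_count(key),
                annotated=False, junction_class=jclass,
                kmer_read_support=n_span,
            )
        )
    return out


def classify_junction(
    junction: Union[Junction, JunctionKey], annotation: Annotation
) -> str:
    """Classify a junction against annotated transcript structures.

    exon_skipping: both splice sites match annotated sites of one transcript
    and at least one complete internal exon of that transcript lies inside
    the intron.  partial_exon_loss / partial_intron_gain: exactly one site
    is novel and falls strictly inside an annotated exon / intron.
    Everything else is "other".
    """
    if isinstance(junction, Junction):
        chrom, l, r = junction.key
    else:
        chrom, l, r = junction
    genes = annotation.genes_overlapping(chrom, l, r)
    if not genes:
        raise JunctionOutsideGeneError(
            f"junction {chrom}:{l}-{r} overlaps no annotated gene"
        )

    transcripts = [t for g in genes for t in g.transcripts.values()]
    for t in transcripts:
        ends = {e for _, e in t.exons}
        starts = {s for s, _ in t.exons}
        if l in ends and r in starts:
            internal = t.exons[1:-1]
            if any(l <= s and e <= r for s, e in internal):
                return "exon_skipping"

    donor_novel = not any(l in {e for _, e in t.exons} for t in transcripts)
    acceptor_novel = not any(r in {s for s, _ in t.exons} for t in transcripts)
    if donor_novel == acceptor_novel:
        return "other"
    novel_pos = l if donor_novel else r
    in_exon = any(s < novel_pos < e for t in transcripts for s, e in t.exons)
    in_intron = any(
        e0 < novel_pos < s1
        for t in transcripts
        for (_, e0), (s1, _) in zip(t.exons, t.exons[1:])
    )
    if in_exon and not in_intron:
        return "partial_exon_loss"
    if in_intron and not in_exon:
        return "partial_intron_gain"
    if in_exon:  # ambiguous across isoforms: exon location takes precedence
        return "partial_exon_loss"
    return "other"


# ---------------------------------------------------------------------------
# Variant transcripts
# ---------------------------------------------------------------------------


@dataclass
class VariantTranscript:
    gene_id: str
    anchor_transcript_id: str
    chrom: str
    strand: str
    junction: Junction
    path: list[tuple] = field(default_factory=list)  # ('exon'|'segment', s, e) and ('junction', l, r)
    sequence: str = ""  # transcription-sense, starting at the annotated ATG
    junction_offset: int = 0  # nt from CDS start to the junction point
    kmer_read_support: int = 0
    anchor_cds_len: int = 0

    @property
    def frame_offset(self) -> int:
        return self.junction_offset % 3

    def recompute_sequence(self, genome: Genome) -> str:
        """Re-splice the stored genomic path; must equal ``sequence``."""
        pieces = [
            genome.fetch(self.chrom, item[1], item[2])
            for item in self.path
            if item[0] in ("exon", "segment")
        ]
        if self.strand == "-":
            return "".join(reverse_complement(p) for p in pieces)
        return "".join(pieces)


def _upstream_pieces_plus(
    t: Transcript, cds_start: int, l: int
) -> Optional[list[tuple[int, int]]]:
    """Exonic pieces from the start codon to junction donor ``l`` ('+')."""
    pieces: list[tuple[int, int]] = []
    reached = False
    for s, e in t.exons:
        if e <= cds_start:
            continue
        a = max(s, cds_start)
        if l <= a:
            break
        if l <= e:
            pieces.append((a, l))
            reached = True
            break
        pieces.append((a, e))
    return pieces if reached and pieces else None


def _upstream_pieces_minus(
    t: Transcript, cds_start_hi: int, r: int
) -> Optional[list[tuple[int, int]]]:
    """Exonic pieces (transcription order, '-' strand) from the start codon
    down to junction donor ``r`` (the genomic right edge of the intron)."""
    pieces: list[tuple[int, int]] = []
    reached = False
    for s, e in reversed(t.exons):
        if s >= cds_start_hi:
            continue
        b = min(e, cds_start_hi)
        if r >= b:
            break
        if r >= s:
            pieces.append((r, b))
            reached = True
            break
        pieces.append((s, b))
    return pieces if reached and pieces else None


def _mate_consistent(
    mate_spans: Optional[Sequence[tuple[str, int, int]]],
    chrom: str,
    intron: tuple[int, int],
) -> bool:
    if not mate_spans:
        return False
    l, r = intron
    for c, a, b in mate_spans:
        if c == chrom and a < l and b > r:
            return True
    return False


def _walk_downstream(
    graph: SpliceGraph,
    chrom: str,
    start_pos: int,
    strand: str,
    need: int,
    mate_spans: Optional[Sequence[tuple[str, int, int]]],
) -> list[tuple[int, int]]:
    """Collect genomic segment pieces downstream of the junction until
    ``need`` bases are gathered or the component ends.

    At each boundary the next edge is chosen by preference: mate-consistent
    junction, annotated junction, then highest unique-read support; plain
    adjacency is taken when no junction edge qualifies better.
    """
    pieces: list[tuple[int, int]] = []
    got = 0
    if strand == "+":
        node = graph.find_segment(chrom, start_pos)
        if node is None:
            return pieces
        cur = (start_pos, node[2])
        while got < need:
            pieces.append(cur)
            got += cur[1] - cur[0]
            if got >= need:
                break
            node = graph.find_segment(chrom, cur[1] - 1)
            options = []
            for v, data in graph.junction_edges_from(node):
                options.append(
                    (
                        _mate_consistent(mate_spans, chrom, data["intron"]),
                        bool(data.get("annotated")),
                        data.get("unique_reads", 0),
                        -data["intron"][1],
                        ("j", v),
                    )
                )
            adj = graph.adjacency_from(node)
            if adj is not None:
                options.append((False, True, -1, 0, ("a", adj)))
            if not options:
                break
            options.sort(reverse=True)
            _, _, _, _, (kind, nxt) = options[0]
            cur = (nxt[1], nxt[2])
    else:
        node = graph.find_segment(chrom, start_pos - 1)
        if node is None:
            return pieces
        cur = (node[1], start_pos)
        while got < need:
            pieces.append(cur)
            got += cur[1] - cur[0]
            if got >= need:
                break
            node = graph.find_segment(chrom, cur[0])
            options = []
            for u, _, data in graph.graph.in_edges(node, data=True):
                if data.get("kind") == "junction" and data["intron"][1] == node[1]:
                    options.append(
                        (
                            _mate_consistent(mate_spans, chrom, data["intron"]),
                            bool(data.get("annotated")),
                            data.get("unique_reads", 0),
                            data["intron"][0],
                            ("j", u),
                        )
                    )
                elif data.get("kind") == "adjacency" and u[2] == node[1]:
                    options.append((False, True, -1, 0, ("a", u)))
            if not options:
                break
            options.sort(reverse=True)
            _, _, _, _, (kind, nxt) = options[0]
            cur = (nxt[1], nxt[2])
    return pieces


def infer_variant_transcript(
    junction: Junction,
    graph: SpliceGraph,
    annotation: Annotation,
    genome: Genome,
    kmer_evidence: Union[Mapping[JunctionKey, int], Iterable[KmerMatch], int],
    mate_spans: Optional[Sequence[tuple[str, int, int]]],
    cfg: PipelineConfig,
) -> list[VariantTranscript]:
    """In-frame variant transcripts containing a called junction.

    One candidate per anchor transcript: an annotated protein-coding
    transcript whose CDS start lies upstream of the junction and whose exon
    chain reaches the junction's upstream boundary.  Results whose
    junction-spanning k-mer read support is below ``cfg.path_kmer_read_min``
    are discarded; a junction upstream of every start codon yields none.
    """
    if isinstance(kmer_evidence, int):
        support = kmer_evidence
    else:
        support = _spanning_read_counts(kmer_evidence).get(junction.key, 0)
    if support < cfg.path_kmer_read_min:
        log.info("junction %s: %d k-mer reads < %d; filtered",
                 junction.junction_id, support, cfg.path_kmer_read_min)
        return []

    chrom, l, r = junction.key
    need = 3 * max(cfg.peptide_lengths) + 3
    out: list[VariantTranscript] = []
    for gene in annotation.genes_overlapping(chrom, l, r):
        if gene.biotype != "protein_coding":
            continue
        for tid in sorted(gene.transcripts):
            t = gene.transcripts[tid]
            if not t.is_coding:
                continue
            if gene.strand == "+":
                cds_start = t.cds[0][0]
                if cds_start >= l:
                    continue
                up = _upstream_pieces_plus(t, cds_start, l)
                if up is None:
                    continue
                down = _walk_downstream(graph, chrom, r, "+", need, mate_spans)
            else:
                cds_start_hi = t.cds[-1][1]
                if cds_start_hi <= r:
                    continue
                up = _upstream_pieces_minus(t, cds_start_hi, r)
                if up is None:
                    continue
                down = _walk_downstream(graph, chrom, l, "-", need, mate_spans)
            if not down:
                continue
            path: list[tuple] = [("exon", s, e) for s, e in up]
            path.append(("junction", l, r))
            path.extend(("segment", s, e) for s, e in down)
            if gene.strand == "+":
                seq_up = "".join(genome.fetch(chrom, s, e) for s, e in up)
                seq_down = "".join(genome.fetch(chrom, s, e) for s, e in down)
            else:
                seq_up = "".join(
                    reverse_complement(genome.fetch(chrom, s, e)) for s, e in up
                )
                seq_down = "".join(
                    reverse_complement(genome.fetch(chrom, s, e)) for s, e in down
                )
            vt = VariantTranscript(
                gene_id=gene.gene_id, anchor_transcript_id=tid, chrom=chrom,
                strand=gene.strand, junction=junction, path=path,
                sequence=seq_up + seq_down, junction_offset=len(seq_up),
                kmer_read_support=support,
                anchor_cds_len=sum(e - s for s, e in t.cds),
            )
            out.append(vt)
    if not out:
        log.info("junction %s: no anchor transcript with an annotated start "
                 "reaching it; dropped", junction.junction_id)
    out.sort(key=lambda v: (-v.anchor_cds_len, v.anchor_transcript_id))
    return out
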