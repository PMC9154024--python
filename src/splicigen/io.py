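"""Formats, coordinate conventions and core genomic records.

Internal coordinates are 0-based half-open throughout the package.  Every
file interface converts at the boundary: GTF/GFF3 and STAR-style SJ tables
are 1-based inclusive on disk, BAM/SAM positions are 0-based via pysam.
A splice junction is canonically represented by its *intron* interval
``[donor_end, acceptor_start)`` in 0-based coordinates; junction identity is
strand-agnostic, matching aligner SJ-table behaviour.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pandas as pd
import pysam
from gffutils.feature import feature_from_line

STRANDS = ("+", "-", ".")

#: CIGAR operations that consume query sequence / reference sequence.
QUERY_OPS = set("MIS=X")
REF_OPS = set("MDN=X")


class AnnotationError(ValueError):
    """Raised when an annotation file violates structural invariants."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)  # sorted, 0-based
    cds: list[tuple[int, int]] = field(default_factory=list)
    cds_phases: list[int] = field(default_factory=list)
    start_codon: Optional[int] = None  # genomic position of first base of ATG

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def spliced_sequence(self, genome: "Genome") -> str:
        """Exonic sequence in transcription order (revcomp for '-' strand)."""
        seq = "".join(genome.fetch(self.chrom, s, e) for s, e in self.exons)
        return reverse_complement(seq) if self.strand == "-" else seq

    def cds_sequence(self, genome: "Genome") -> str:
        seq = "".join(genome.fetch(self.chrom, s, e) for s, e in self.cds)
        return reverse_complement(seq) if self.strand == "-" else seq


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    name: str = ""
    biotype: str = "protein_coding"
    transcripts: dict[str, Transcript] = field(default_factory=dict)
    start: int = 0
    end: int = 0

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


class Annotation:
    """Gene models indexed by chromosome, with junction/site lookups."""

    def __init__(self, genes: Iterable[Gene]):
        self.genes: dict[str, Gene] = {}
        self.by_chrom: dict[str, list[Gene]] = {}
        for g in genes:
            self.genes[g.gene_id] = g
            self.by_chrom.setdefault(g.chrom, []).append(g)
        for glist in self.by_chrom.values():
            glist.sort(key=lambda g: (g.start, g.end, g.gene_id))
        self._introns: set[tuple[str, int, int]] = set()
        self._donors: set[tuple[str, int]] = set()
        self._acceptors: set[tuple[str, int]] = set()
        for g in self.genes.values():
            for t in g.transcripts.values():
                for s, e in t.introns:
                    self._introns.add((g.chrom, s, e))
                    self._donors.add((g.chrom, s))
                    self._acceptors.add((g.chrom, e))
        self.validate()

    def validate(self) -> None:
        for g in self.genes.values():
            for t in g.transcripts.values():
                if t.gene_id != g.gene_id:
                    raise AnnotationError(
                        f"transcript {t.transcript_id} references gene "
                        f"{t.gene_id}, filed under {g.gene_id}"
                    )
                if not t.exons:
                    raise AnnotationError(f"transcript {t.transcript_id} has no exons")
                for (s0, e0), (s1, e1) in zip(t.exons, t.exons[1:]):
                    if s1 < e0:
                        raise AnnotationError(
                            f"transcript {t.transcript_id} has overlapping/unsorted "
                            f"exons [{s0},{e0}) and [{s1},{e1})"
                        )
                if t.cds:
                    exon_set = t.exons
                    for cs, ce in t.cds:
                        if not any(s <= cs and ce <= e for s, e in exon_set):
                            raise AnnotationError(
                                f"CDS [{cs},{ce}) of {t.transcript_id} is not "
                                "contained in its exon chain"
                            )

    def transcripts(self) -> Iterator[Transcript]:
        for g in self.genes.values():
            yield from g.transcripts.values()

    def is_annotated_intron(self, chrom: str, start: int, end: int) -> bool:
        return (chrom, start, end) in self._introns

    def is_annotated_donor_site(self, chrom: str, pos: int) -> bool:
        """True if ``pos`` is an annotated intron start (exon 3' boundary)."""
        return (chrom, pos) in self._donors

    def is_annotated_acceptor_site(self, chrom: str, pos: int) -> bool:
        """True if ``pos`` is an annotated intron end (exon 5' boundary)."""
        return (chrom, pos) in self._acceptors

    def genes_overlapping(self, chrom: str, start: int, end: int) -> list[Gene]:
        return [
            g
            for g in self.by_chrom.get(chrom, [])
            if g.start < end and start < g.end
        ]


# ---------------------------------------------------------------------------
# Sequence helpers / genome access
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class Genome:
    """Uniform 0-based access to a genome, file-backed or in-memory."""

    def __init__(self, getter, chroms: Sequence[str], lengths: Mapping[str, int]):
        self._getter = getter
        self.chroms = list(chroms)
        self.lengths = dict(lengths)

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "Genome":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        lengths = {name: len(fa[name]) for name in fa.keys()}
        return cls(lambda c, s, e: str(fa[c][s:e]), list(fa.keys()), lengths)

    @classmethod
    def from_dict(cls, seqs: Mapping[str, str]) -> "Genome":
        seqs = {c: s.upper() for c, s in seqs.items()}
        lengths = {c: len(s) for c, s in seqs.items()}
        return cls(lambda c, s, e: seqs[c][s:e], list(seqs.keys()), lengths)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self.lengths:
            raise KeyError(f"chromosome {chrom!r} absent from genome")
        return self._getter(chrom, start, end)


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------

_TX_FEATURES = {"transcript", "mRNA"}


def load_annotation(path: str | os.PathLike, dialect: str = "gtf") -> Annotation:
    """Parse a GTF or GFF3 (GENCODE dialect) file into an :class:`Annotation`.

    File coordinates (1-based inclusive) are converted to 0-based half-open.
    Transcripts are grouped under genes; CDS phase is retained.  Malformed
    attribute columns raise :class:`AnnotationError` naming the line number.
    """
    if dialect not in ("gtf", "gff3"):
        raise ValueError(f"unknown dialect {dialect!r}")
    genes: dict[str, Gene] = {}
    transcripts: dict[str, Transcript] = {}
    tx_spans: dict[str, tuple[int, int]] = {}

    def attr(f, *names):
        for n in names:
            if n in f.attributes:
                v = f.attributes[n]
                return v[0] if isinstance(v, list) else v
        return None

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") != 8:
                raise AnnotationError(
                    f"{path}: parse error at line {lineno}: expected 9 "
                    f"tab-separated columns, found {line.count(chr(9)) + 1}"
                )
            try:
                f = feature_from_line(line, dialect=None)
            except Exception as exc:  # gffutils raises assorted types
                raise AnnotationError(
                    f"{path}: parse error at line {lineno}: {exc}"
                ) from exc
            ftype = f.featuretype
            start0, end0 = f.start - 1, f.end  # 1-based inclusive -> 0-based half-open
            if ftype == "gene":
                gid = attr(f, "gene_id", "ID")
                if gid is None:
                    raise AnnotationError(
                        f"{path}: line {lineno}: gene feature lacks gene_id/ID"
                    )
                genes[gid] = Gene(
                    gene_id=gid,
                    chrom=f.seqid,
                    strand=f.strand,
                    name=attr(f, "gene_name", "Name") or gid,
                    biotype=attr(f, "gene_type", "gene_biotype", "biotype")
                    or "protein_coding",
                    start=start0,
                    end=end0,
                )
            elif ftype in _TX_FEATURES:
                tid = attr(f, "transcript_id", "ID")
                gid = attr(f, "gene_id", "Parent")
                if tid is None or gid is None:
                    raise AnnotationError(
                        f"{path}: line {lineno}: transcript lacks id or parent"
                    )
                transcripts[tid] = Transcript(
                    transcript_id=tid, gene_id=gid, chrom=f.seqid, strand=f.strand
                )
                tx_spans[tid] = (start0, end0)
            elif ftype in ("exon", "CDS", "start_codon"):
                tid = attr(f, "transcript_id", "Parent")
                if tid is None:
                    raise AnnotationError(
                        f"{path}: line {lineno}: {ftype} lacks transcript parent"
                    )
                t = transcripts.get(tid)
                if t is None:
                    # tolerate exon-before-transcript by creating a shell
                    gid = attr(f, "gene_id") or tid
                    t = Transcript(
                        transcript_id=tid, gene_id=gid, chrom=f.seqid, strand=f.strand
                    )
                    transcripts[tid] = t
                if ftype == "exon":
                    if tid in tx_spans:
                        ts, te = tx_spans[tid]
                        if start0 < ts or end0 > te:
                            raise AnnotationError(
                                f"{path}: line {lineno}: exon [{start0},{end0}) "
                                f"outside transcript span [{ts},{te}) of {tid}"
                            )
                    t.exons.append((start0, end0))
                elif ftype == "CDS":
                    t.cds.append((start0, end0))
                    try:
                        t.cds_phases.append(int(f.frame))
                    except (TypeError, ValueError):
                        t.cds_phases.append(0)
                else:  # start_codon
                    if t.start_codon is None or (
                        start0 < t.start_codon
                        if f.strand == "+"
                        else end0 > t.start_codon
                    ):
                        t.start_codon = start0 if f.strand == "+" else end0

    for t in transcripts.values():
        order = sorted(range(len(t.exons)), key=lambda i: t.exons[i])
        t.exons = [t.exons[i] for i in order]
        cds_order = sorted(range(len(t.cds)), key=lambda i: t.cds[i])
        t.cds = [t.cds[i] for i in cds_order]
        t.cds_phases = [t.cds_phases[i] for i in cds_order] if t.cds_phases else []
        if t.gene_id not in genes:
            # gene rows are optional in some dialects: synthesize
            genes[t.gene_id] = Gene(
                gene_id=t.gene_id, chrom=t.chrom, strand=t.strand,
                start=t.exons[0][0], end=t.exons[-1][1],
            )
        g = genes[t.gene_id]
        if not g.transcripts and g.end == 0:  # synthesized gene without a span
            g.start, g.end = t.exons[0][0], t.exons[-1][1]
        else:
            g.start = min(g.start, t.exons[0][0])
            g.end = max(g.end, t.exons[-1][1])
        g.transcripts[t.transcript_id] = t

    return Annotation(genes.values())


def _gtf_attrs(**kv) -> str:
    return " ".join(f'{k} "{v}";' for k, v in kv.items() if v is not None)


def write_gtf(annotation: Annotation, path: str | os.PathLike) -> None:
    """Write an annotation as GTF (1-based inclusive), deterministically ordered."""
    with open(path, "w") as fh:
        for chrom in sorted(annotation.by_chrom):
            for g in annotation.by_chrom[chrom]:
                fh.write(
                    "\t".join(
                        [
                            g.chrom, "splicigen", "gene",
                            str(g.start + 1), str(g.end), ".", g.strand, ".",
                            _gtf_attrs(gene_id=g.gene_id, gene_name=g.name,
                                       gene_type=g.biotype),
                        ]
                    )
                    + "\n"
                )
                for tid in sorted(g.transcripts):
                    t = g.transcripts[tid]
                    ts, te = t.span
                    fh.write(
                        "\t".join(
                            [g.chrom, "splicigen", "transcript", str(ts + 1),
                             str(te), ".", t.strand, ".",
                             _gtf_attrs(gene_id=g.gene_id, transcript_id=tid)]
                        )
                        + "\n"
                    )
                    for s, e in t.exons:
                        fh.write(
                            "\t".join(
                                [g.chrom, "splicigen", "exon", str(s + 1), str(e),
                                 ".", t.strand, ".",
                                 _gtf_attrs(gene_id=g.gene_id, transcript_id=tid)]
                            )
                            + "\n"
                        )
                    for (s, e), ph in zip(t.cds, t.cds_phases or [0] * len(t.cds)):
                        fh.write(
                            "\t".join(
                                [g.chrom, "splicigen", "CDS", str(s + 1), str(e),
                                 ".", t.strand, str(ph),
                                 _gtf_attrs(gene_id=g.gene_id, transcript_id=tid)]
                            )
                            + "\n"
                        )


# ---------------------------------------------------------------------------
# Alignment records
# ---------------------------------------------------------------------------


@dataclass(slots=True)
class AlignedRead:
    """A mapped primary alignment, decoupled from any file backend."""

    name: str
    seq: str
    chrom: str
    pos: int  # 0-based leftmost reference position
    cigar: list[tuple[str, int]]
    mapq: int = 255
    nh: Optional[int] = 1
    is_paired: bool = False
    is_proper_pair: bool = False
    is_reverse: bool = False
    mate_chrom: Optional[str] = None
    mate_pos: Optional[int] = None

    def query_length_from_cigar(self) -> int:
        return sum(n for op, n in self.cigar if op in QUERY_OPS)

    def reference_end(self) -> int:
        return self.pos + sum(n for op, n in self.cigar if op in REF_OPS)

    def validate(self) -> None:
        qlen = self.query_length_from_cigar()
        if qlen != len(self.seq):
            raise ValueError(
                f"read {self.name}: CIGAR consumes {qlen} query bases but "
                f"sequence has {len(self.seq)}"
            )
        if any(n < 0 for _, n in self.cigar):
            raise ValueError(f"read {self.name}: negative CIGAR length")

    def junctions(self) -> list[tuple[int, int]]:
        """Intron intervals (0-based half-open) of every N operation."""
        out = []
        ref = self.pos
        for op, n in self.cigar:
            if op == "N":
                out.append((ref, ref + n))
            if op in REF_OPS:
                ref += n
        return out


_CIGAR_CODES = "MIDNSHP=XB"


def _from_pysam(rec: pysam.AlignedSegment) -> AlignedRead:
    cigar = [(_CIGAR_CODES[op], n) for op, n in (rec.cigartuples or [])]
    try:
        nh: Optional[int] = rec.get_tag("NH")
    except KeyError:
        nh = None
    return AlignedRead(
        name=rec.query_name,
        seq=rec.query_sequence or "",
        chrom=rec.reference_name,
        pos=rec.reference_start,
        cigar=cigar,
        mapq=rec.mapping_quality,
        nh=nh,
        is_paired=rec.is_paired,
        is_proper_pair=rec.is_proper_pair,
        is_reverse=rec.is_reverse,
        mate_chrom=rec.next_reference_name if rec.is_paired else None,
        mate_pos=rec.next_reference_start if rec.is_paired and rec.next_reference_start >= 0 else None,
    )


def read_alignments(
    path: str | os.PathLike, region: Optional[GenomicInterval] = None
) -> Iterator[AlignedRead]:
    """Stream primary mapped alignments from a BAM/SAM file.

    Unmapped, secondary and supplementary records are excluded.  A region
    query requires a coordinate-sorted, indexed file.  Records whose CIGAR
    and sequence lengths disagree raise a record-level error naming the read.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode) as fh:
        if region is not None:
            if not fh.has_index():
                raise ValueError(
                    f"{path}: region query requires an indexed alignment file"
                )
            it = fh.fetch(region.chrom, region.start, region.end)
        else:
            it = fh.fetch(until_eof=True)
        for rec in it:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            read = _from_pysam(rec)
            read.validate()
            yield read


def write_sam(
    reads: Iterable[AlignedRead],
    path: str | os.PathLike,
    chrom_lengths: Mapping[str, int],
) -> None:
    """Write alignments to a (text) SAM file, sorted by coordinate."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in chrom_lengths.items()],
    }
    refs = {c: i for i, c in enumerate(chrom_lengths)}
    reads = sorted(reads, key=lambda r: (refs[r.chrom], r.pos, r.name))
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for r in reads:
            rec = pysam.AlignedSegment(fh.header)
            rec.query_name = r.name
            rec.query_sequence = r.seq
            rec.reference_id = refs[r.chrom]
            rec.reference_start = r.pos
            rec.cigartuples = [(_CIGAR_CODES.index(op), n) for op, n in r.cigar]
            rec.mapping_quality = r.mapq
            rec.flag = (0x1 if r.is_paired else 0) | (0x10 if r.is_reverse else 0) | (
                0x2 if r.is_proper_pair else 0
            )
            if r.is_paired and r.mate_pos is not None:
                rec.next_reference_id = refs.get(r.mate_chrom or r.chrom, refs[r.chrom])
                rec.next_reference_start = r.mate_pos
            rec.set_tag("NH", r.nh if r.nh is not None else 1)
            fh.write(rec)


# ---------------------------------------------------------------------------
# SJ (splice-junction) tables — STAR SJ.out.tab layout
# ---------------------------------------------------------------------------

SJ_COLUMNS = [
    "chrom", "intron_start", "intron_end", "strand", "motif",
    "annotated", "unique_reads", "multi_reads", "max_overhang",
]


def read_sj_table(path: str | os.PathLike) -> dict[tuple[str, int, int], tuple[int, int]]:
    """Read a 9-column SJ table.

    Returns a mapping from (chrom, intron_start0, intron_end0) — converted to
    0-based half-open — to (unique_read_count, total_read_count).
    """
    df = pd.read_csv(path, sep="\t", names=SJ_COLUMNS, header=None, comment="#")
    out: dict[tuple[str, int, int], tuple[int, int]] = {}
    for row in df.itertuples(index=False):
        key = (str(row.chrom), int(row.intron_start) - 1, int(row.intron_end))
        uniq = int(row.unique_reads)
        out[key] = (uniq, uniq + int(row.multi_reads))
    return out


def write_sj_table(
    counts: Mapping[tuple[str, int, int], tuple[int, int]],
    path: str | os.PathLike,
    strands: Optional[Mapping[tuple[str, int, int], str]] = None,
) -> None:
    strand_code = {"+": 1, "-": 2, ".": 0}
    rows = []
    for key in sorted(counts):
        chrom, s0, e0 = key
        uniq, total = counts[key]
        st = strand_code.get((strands or {}).get(key, "."), 0)
        rows.append([chrom, s0 + 1, e0, st, 0, 0, uniq, max(total - uniq, 0), 0])
    pd.DataFrame(rows, columns=SJ_COLUMNS).to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# Result writers
# ---------------------------------------------------------------------------


def write_results(junctions, peptides, binding_calls, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write the pipeline's outputs; byte-stable for identical inputs.

    Emits ``junctions.tsv`` (1-based inclusive intron coordinates),
    ``candidates.tsv`` (all peptide/allele binding rows) and
    ``neoantigens.fa`` (binder-only peptide FASTA whose headers encode the
    junction id, HLA allele and predicted affinity).
    """
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    jpath = os.path.join(out_dir, "junctions.tsv")
    cpath = os.path.join(out_dir, "candidates.tsv")
    fpath = os.path.join(out_dir, "neoantigens.fa")

    jrows = []
    for j in sorted(
        junctions, key=lambda j: (j.chrom, j.intron_start, j.intron_end)
    ):
        jrows.append(
            [
                j.chrom, j.intron_start + 1, j.intron_end, j.strand,
                j.junction_class, int(j.annotated),
                j.tumor_unique_reads, j.normal_unique_reads,
            ]
        )
    pd.DataFrame(
        jrows,
        columns=[
            "chrom", "intron_start", "intron_end", "strand", "class",
            "annotated", "tumor_unique_reads", "normal_unique_reads",
        ],
    ).to_csv(jpath, sep="\t", index=False)

    crows = []
    for call in binding_calls:
        p = call.peptide
        crows.append(
            [
                p.sequence, len(p.sequence), p.junction_id, p.transcript_id,
                call.allele, round(call.affinity_nM, 2), int(call.is_binder),
            ]
        )
    crows.sort()
    pd.DataFrame(
        crows,
        columns=[
            "peptide", "length", "junction_id", "transcript_id", "allele",
            "affinity_nM", "is_binder",
        ],
    ).to_csv(cpath, sep="\t", index=False)

    with open(fpath, "w") as fh:
        for row in crows:
            pep, _, jid, tid, allele, aff, binder = row
            if binder:
                fh.write(f">{jid}|{allele}|{aff}|{tid}\n{pep}\n")
    return {"junctions": jpath, "candidates": cpath, "neoantigens": fpath}
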