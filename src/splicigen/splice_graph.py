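"""Splice graphs from spliced alignments, and k-mer projection onto them.

The graph's nodes are genomic segments: maximal covered reference runs,
partitioned at every observed junction donor/acceptor boundary and at every
annotated exon boundary.  Typed edges record adjacencies (abutting
segments), splice junctions (one per distinct N-operation intron, with
unique/total read support), and sequence variants (SNV/insertion/deletion)
that clear the support threshold — SNVs additionally a one-sided binomial
test against a per-base error null.

Tumor-specific k-mers are located in read sequences by multi-pattern
matching (an Aho–Corasick automaton, plus a 2-bit packed vectorised matcher
used for large read sets) and projected through each read's CIGAR onto a
path of graph segments and edges; a projection that crosses an N operation
spans a splice junction.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .config import PipelineConfig, StrandMode, UniqueReadRule
from .io import AlignedRead, Annotation, Genome, reverse_complement
from .msbwt import TumorSpecificKmer

log = logging.getLogger(__name__)

JunctionKey = tuple[str, int, int]  # (chrom, intron_start, intron_end), 0-based


def is_unique_read(read: AlignedRead, cfg: PipelineConfig) -> bool:
    if cfg.unique_read_rule is UniqueReadRule.nh_eq_1 and read.nh is not None:
        return read.nh == 1
    return read.mapq >= cfg.mapq_unique_threshold


class JunctionSupportTable(dict):
    """Mapping junction key -> [unique_read_count, total_read_count]."""

    def add(self, key: JunctionKey, unique: bool) -> None:
        rec = self.setdefault(key, [0, 0])
        rec[1] += 1
        if unique:
            rec[0] += 1

    def unique_count(self, key: JunctionKey) -> int:
        return self.get(key, (0, 0))[0]

    def total_count(self, key: JunctionKey) -> int:
        return self.get(key, (0, 0))[1]

    def as_sj_counts(self) -> dict[JunctionKey, tuple[int, int]]:
        return {k: (v[0], v[1]) for k, v in self.items()}


def extract_junction_support(
    alignments: Iterable[AlignedRead], cfg: PipelineConfig
) -> JunctionSupportTable:
    """Count junction-spanning reads per intron for one sample.

    Every N CIGAR operation contributes one total-count increment to the
    junction whose intron equals the N span; reads that are unique under
    ``cfg.unique_read_rule`` also increment the unique count.  A read with
    several N operations increments each of its junctions.
    """
    table = JunctionSupportTable()
    for read in alignments:
        uniq = is_unique_read(read, cfg)
        for l, r in read.junctions():
            table.add((read.chrom, l, r), uniq)
    return table


def snv_edge_test(alt_count: int, depth: int, cfg: PipelineConfig) -> float:
    """One-sided upper-tail binomial probability of >= alt_count mismatches
    in ``depth`` reads under the per-base error rate ``cfg.snv_error_rate``."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not (0 <= alt_count <= depth):
        raise ValueError("alt_count must be in [0, depth]")
    return float(stats.binom.sf(alt_count - 1, depth, cfg.snv_error_rate))


# ---------------------------------------------------------------------------
# The graph
# ---------------------------------------------------------------------------


@dataclass
class SpliceGraph:
    graph: nx.MultiDiGraph
    segments: dict[str, tuple[np.ndarray, np.ndarray]]  # chrom -> (starts, ends)
    junction_support: JunctionSupportTable

    def find_segment(self, chrom: str, pos: int) -> Optional[tuple[str, int, int]]:
        """Segment node containing reference position ``pos``, if covered."""
        arrs = self.segments.get(chrom)
        if arrs is None:
            return None
        starts, ends = arrs
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return (chrom, int(starts[i]), int(ends[i]))
        return None

    def segments_in(self, chrom: str, start: int, end: int) -> list[tuple[str, int, int]]:
        arrs = self.segments.get(chrom)
        if arrs is None:
            return []
        starts, ends = arrs
        i = max(int(np.searchsorted(ends, start, side="right")), 0)
        out = []
        while i < len(starts) and starts[i] < end:
            out.append((chrom, int(starts[i]), int(ends[i])))
            i += 1
        return out

    def junction_edges_from(self, node: tuple[str, int, int]):
        """Outgoing junction edges whose intron starts at this segment's end."""
        out = []
        for _, v, data in self.graph.out_edges(node, data=True):
            if data["kind"] == "junction" and data["intron"][0] == node[2]:
                out.append((v, data))
        return out

    def adjacency_from(self, node: tuple[str, int, int]):
        for _, v, data in self.graph.out_edges(node, data=True):
            if data["kind"] == "adjacency":
                return v
        return None

    def to_jsonl(self, path) -> None:
        """Serialize nodes and edges one JSON object per line."""
        with open(path, "w") as fh:
            for chrom, s, e in sorted(self.graph.nodes):
                d = self.graph.nodes[(chrom, s, e)]
                fh.write(json.dumps(
                    {"type": "segment", "chrom": chrom, "start": s, "end": e,
                     "gene_id": d.get("gene_id")}) + "\n")
            for u, v, data in sorted(
                self.graph.edges(data=True), key=lambda t: (t[0], t[1], t[2]["kind"])
            ):
                rec = {"type": "edge", "from": list(u), "to": list(v)}
                rec.update(
                    {k: (list(val) if isinstance(val, tuple) else val)
                     for k, val in data.items()}
                )
                fh.write(json.dumps(rec) + "\n")


def build_splice_graph(
    alignments: Iterable[AlignedRead],
    annotation: Optional[Annotation],
    genome: Genome,
    cfg: PipelineConfig,
) -> SpliceGraph:
    """Construct the splice graph of one (tumor) sample.

    Segment boundaries fall at every observed junction donor/acceptor, every
    annotated exon boundary, and every coverage gap; junction edges carry
    per-intron read support; mismatch pileups against the reference become
    SNV edges when their support reaches ``cfg.variant_min_support`` and the
    binomial error-null test is at most ``cfg.snv_p_threshold``; insertions
    and deletions become edges at the support threshold alone.
    """
    cover_diff: dict[str, np.ndarray] = {}
    support = JunctionSupportTable()
    mismatch: dict[str, dict[tuple[int, str], int]] = defaultdict(lambda: defaultdict(int))
    inserts: dict[tuple[str, int, str], int] = defaultdict(int)
    deletes: dict[tuple[str, int, int], int] = defaultdict(int)
    chrom_reads = 0

    for read in alignments:
        if read.chrom not in genome.lengths:
            raise ValueError(
                f"read {read.name} aligned to {read.chrom!r}, absent from genome"
            )
        chrom_reads += 1
        diff = cover_diff.get(read.chrom)
        if diff is None:
            diff = cover_diff[read.chrom] = np.zeros(
                genome.lengths[read.chrom] + 1, dtype=np.int32
            )
        uniq = is_unique_read(read, cfg)
        ref = read.pos
        q = 0
        for op, n in read.cigar:
            if op in "M=X":
                diff[ref] += 1
                diff[ref + n] -= 1
                refseq = genome.fetch(read.chrom, ref, ref + n)
                sub = read.seq[q : q + n]
                if sub != refseq:
                    mm = mismatch[read.chrom]
                    for j in range(n):
                        if sub[j] != refseq[j] and sub[j] in "ACGT":
                            mm[(ref + j, sub[j])] += 1
                ref += n
                q += n
            elif op == "N":
                support.add((read.chrom, ref, ref + n), uniq)
                ref += n
            elif op == "D":
                deletes[(read.chrom, ref, ref + n)] += 1
                ref += n
            elif op == "I":
                inserts[(read.chrom, ref, read.seq[q : q + n])] += 1
                q += n
            elif op in "SH":
                if op == "S":
                    q += n
            else:
                raise ValueError(f"unsupported CIGAR op {op!r} in read {read.name}")

    g = nx.MultiDiGraph()
    segments: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, diff in cover_diff.items():
        coverage = np.cumsum(diff[:-1], dtype=np.int32)
        covered = coverage > 0
        # maximal covered runs
        edges_arr = np.flatnonzero(np.diff(covered.astype(np.int8)))
        run_starts = edges_arr[covered[edges_arr + 1]] + 1
        run_ends = edges_arr[~covered[edges_arr + 1]] + 1
        if covered[0]:
            run_starts = np.concatenate([[0], run_starts])
        if covered[-1]:
            run_ends = np.concatenate([run_ends, [covered.size]])

        cuts: set[int] = set()
        for (c, l, r) in support:
            if c == chrom:
                cuts.add(l)
                cuts.add(r)
        if annotation is not None:
            for gene in annotation.by_chrom.get(chrom, []):
                for t in gene.transcripts.values():
                    for s, e in t.exons:
                        cuts.add(s)
                        cuts.add(e)
        cut_arr = np.array(sorted(cuts), dtype=np.int64)

        starts_out: list[int] = []
        ends_out: list[int] = []
        for rs, re_ in zip(run_starts.tolist(), run_ends.tolist()):
            inner = cut_arr[(cut_arr > rs) & (cut_arr < re_)]
            bounds = [rs] + inner.tolist() + [re_]
            for a, b in zip(bounds, bounds[1:]):
                starts_out.append(a)
                ends_out.append(b)
        starts_np = np.array(starts_out, dtype=np.int64)
        ends_np = np.array(ends_out, dtype=np.int64)
        segments[chrom] = (starts_np, ends_np)

        prev = None
        for s, e in zip(starts_out, ends_out):
            node = (chrom, s, e)
            gene_id = None
            if annotation is not None:
                hits = annotation.genes_overlapping(chrom, s, e)
                if hits:
                    gene_id = hits[0].gene_id
            g.add_node(node, gene_id=gene_id, coverage=int(coverage[s]))
            if prev is not None and prev[2] == s:
                g.add_edge(prev, node, kind="adjacency")
            prev = node

    sg = SpliceGraph(graph=g, segments=segments, junction_support=support)

    for (chrom, l, r), (uniq, total) in support.as_sj_counts().items():
        donor = sg.find_segment(chrom, l - 1)
        acceptor = sg.find_segment(chrom, r)
        if donor is None or acceptor is None:
            continue
        g.add_edge(
            donor, acceptor, kind="junction", intron=(l, r),
            unique_reads=uniq, total_reads=total,
            annotated=annotation.is_annotated_intron(chrom, l, r)
            if annotation is not None else False,
        )

    for chrom, mm in mismatch.items():
        coverage = np.cumsum(cover_diff[chrom][:-1], dtype=np.int32)
        for (pos, alt), count in mm.items():
            if count < cfg.variant_min_support:
                continue
            depth = int(coverage[pos])
            p = snv_edge_test(count, max(depth, count), cfg)
            if p <= cfg.snv_p_threshold:
                node = sg.find_segment(chrom, pos)
                if node is not None:
                    g.add_edge(
                        node, node, kind="snv", position=pos,
                        ref=genome.fetch(chrom, pos, pos + 1), alt=alt,
                        support=count, p_value=p,
                    )
    for (chrom, pos, seq), count in inserts.items():
        if count >= cfg.variant_min_support:
            node = sg.find_segment(chrom, max(pos - 1, 0))
            if node is not None:
                g.add_edge(node, node, kind="insertion", position=pos,
                           sequence=seq, support=count)
    for (chrom, ds, de), count in deletes.items():
        if count >= cfg.variant_min_support:
            node = sg.find_segment(chrom, max(ds - 1, 0))
            if node is not None:
                g.add_edge(node, node, kind="deletion", interval=(ds, de),
                           support=count)
    log.info("splice graph: %d reads, %d segments, %d junctions",
             chrom_reads, g.number_of_nodes(), len(support))
    return sg


# ---------------------------------------------------------------------------
# Multi-pattern matching
# ---------------------------------------------------------------------------


class AhoCorasick:
    """Dict-based Aho–Corasick automaton over A/C/G/T patterns."""

    def __init__(self, patterns: Iterable[str]):
        self.goto: list[dict[str, int]] = [{}]
        self.fail: list[int] = [0]
        self.out: list[list[int]] = [[]]
        self.patterns: list[str] = []
        for p in patterns:
            self._insert(p)
        self._build_failures()

    def _insert(self, pattern: str) -> None:
        if not pattern:
            raise ValueError("empty pattern")
        state = 0
        for ch in pattern:
            nxt = self.goto[state].get(ch)
            if nxt is None:
                nxt = len(self.goto)
                self.goto.append({})
                self.fail.append(0)
                self.out.append([])
                self.goto[state][ch] = nxt
            state = nxt
        self.out[state].append(len(self.patterns))
        self.patterns.append(pattern)

    def _build_failures(self) -> None:
        from collections import deque

        queue = deque()
        for ch, s in self.goto[0].items():
            self.fail[s] = 0
            queue.append(s)
        while queue:
            r = queue.popleft()
            for ch, s in self.goto[r].items():
                queue.append(s)
                f = self.fail[r]
                while f and ch not in self.goto[f]:
                    f = self.fail[f]
                self.fail[s] = self.goto[f].get(ch, 0) if self.goto[f].get(ch, 0) != s else 0
                self.out[s] = self.out[s] + self.out[self.fail[s]]

    def iter_matches(self, text: str) -> Iterator[tuple[int, int]]:
        """Yield (pattern_index, start_offset) for every occurrence."""
        state = 0
        goto, fail, out = self.goto, self.fail, self.out
        for i, ch in enumerate(text):
            while state and ch not in goto[state]:
                state = fail[state]
            state = goto[state].get(ch, 0)
            if out[state]:
                for pi in out[state]:
                    yield pi, i + 1 - len(self.patterns[pi])


def locate_kmers_in_reads(
    kmers: Sequence[TumorSpecificKmer] | Sequence[str],
    alignments: Iterable[AlignedRead],
    strand_mode: StrandMode = StrandMode.with_revcomp,
) -> Iterator[tuple[AlignedRead, str, int]]:
    """Report every (read, k-mer, offset) occurrence across the alignments.

    Matching runs on the read sequence as stored in the alignment; under
    ``with_revcomp`` the reverse complement of each k-mer is searched too,
    and an occurrence is reported once per (k-mer, offset) even when the
    k-mer is its own reverse complement.  Overlapping occurrences and
    multiple k-mers per read are all reported.
    """
    seqs = [k.sequence if isinstance(k, TumorSpecificKmer) else k for k in kmers]
    if not seqs:
        raise ValueError("empty k-mer set")
    pattern_sources: dict[str, set[str]] = defaultdict(set)
    for s in seqs:
        pattern_sources[s].add(s)
        if strand_mode is StrandMode.with_revcomp:
            pattern_sources[reverse_complement(s)].add(s)
    ac = AhoCorasick(pattern_sources.keys())
    plist = list(pattern_sources.keys())
    for read in alignments:
        seen: set[tuple[str, int]] = set()
        for pi, off in ac.iter_matches(read.seq):
            for source in pattern_sources[plist[pi]]:
                key = (source, off)
                if key not in seen:
                    seen.add(key)
                    yield read, source, off


# ---------------------------------------------------------------------------
# CIGAR projection
# ---------------------------------------------------------------------------


@dataclass
class KmerMatch:
    kmer: str
    read_name: str
    offset: int
    path: list[tuple] = field(default_factory=list)
    spans_junction: bool = False
    ref_start: int = 0  # leftmost reference base covered by the match
    ref_end: int = 0    # one past the rightmost covered reference base

    @property
    def junctions(self) -> list[JunctionKey]:
        return [
            (item[1], item[2], item[3])
            for item in self.path
            if item[0] == "junction"
        ]


def project_match_to_path(
    offset: int,
    length: int,
    read: AlignedRead,
    graph: SpliceGraph,
) -> Optional[KmerMatch]:
    """Project a matched query span onto a path of graph segments and edges.

    Walks the CIGAR mapping query offsets [offset, offset+length) to
    reference coordinates.  The path lists traversed segments and junction /
    deletion / insertion crossings in order; ``spans_junction`` is true iff
    the span crosses at least one N operation.  Matched bases falling inside
    soft-clipped regions void the projection (returns None).
    """
    lo, hi = offset, offset + length
    ref = read.pos
    q = 0
    events: list[tuple] = []  # CIGAR-ordered spans and crossings
    for op, n in read.cigar:
        if op in "M=X":
            a = max(lo, q)
            b = min(hi, q + n)
            if a < b:
                events.append(("span", ref + (a - q), ref + (b - q)))
            ref += n
            q += n
        elif op == "N":
            if lo < q < hi:
                events.append(("junction", read.chrom, ref, ref + n))
            ref += n
        elif op == "D":
            if lo < q < hi:
                events.append(("deletion", read.chrom, ref, ref + n))
            ref += n
        elif op == "I":
            a = max(lo, q)
            b = min(hi, q + n)
            if a < b:
                events.append(("insertion", read.chrom, ref, read.seq[a:b]))
            q += n
        elif op == "S":
            if max(lo, q) < min(hi, q + n):
                return None  # matched bases inside a soft clip
            q += n
        # H consumes neither

    if not any(ev[0] == "span" for ev in events):
        return None
    path: list[tuple] = []
    for ev in events:
        if ev[0] == "span":
            _, rs, re_ = ev
            for seg in graph.segments_in(read.chrom, rs, re_):
                if path and path[-1][0] == "segment" and path[-1][3] == seg[1]:
                    path.append(("adjacency",))
                path.append(("segment",) + seg)
        else:
            path.append(ev)
    spans = any(item[0] == "junction" for item in path)
    mapped = [ev for ev in events if ev[0] == "span"]
    return KmerMatch(
        kmer=read.seq[lo:hi], read_name=read.name, offset=offset,
        path=path, spans_junction=spans,
        ref_start=mapped[0][1], ref_end=mapped[-1][2],
    )


# ---------------------------------------------------------------------------
# Vectorised junction-spanning k-mer read counting
# ---------------------------------------------------------------------------

_B2 = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _B2[ord(_b)] = _i


def count_junction_spanning_kmer_reads(
    kmers: Sequence[TumorSpecificKmer] | Sequence[str],
    alignments: Sequence[AlignedRead],
    cfg: PipelineConfig,
) -> dict[JunctionKey, int]:
    """Number of distinct reads carrying a k-mer match that spans each
    junction (>= 1 matched base on both sides of the N operation).

    This is the scaled counting path behind junction calling and the
    k-mer-read support filter; it is exactly equivalent to running
    :func:`locate_kmers_in_reads` + :func:`project_match_to_path` and
    counting distinct spanning reads per junction, but works on 2-bit packed
    windows so large read sets stay cheap.  Patterns longer than 32 nt (rare
    for minimal differential k-mers) fall back to the automaton.
    """
    seqs = sorted({k.sequence if isinstance(k, TumorSpecificKmer) else k for k in kmers})
    if not seqs:
        return {}
    patterns: set[str] = set()
    for s in seqs:
        patterns.add(s)
        if cfg.strand_mode is StrandMode.with_revcomp:
            patterns.add(reverse_complement(s))

    # junction breakpoints per read: (read_idx, query pos of first base
    # after the junction, junction key); reads without N ops are irrelevant
    jreads: list[AlignedRead] = []
    clips: list[tuple[int, int]] = []  # (left clip, right clip) per junction read
    pair_rid: list[int] = []
    pair_qpos: list[int] = []
    pair_key: list[JunctionKey] = []
    for read in alignments:
        brk = []
        q = 0
        ref = read.pos
        clip_l = clip_r = 0
        for op, n in read.cigar:
            if op in "M=X":
                q += n
                ref += n
            elif op == "N":
                brk.append((q, (read.chrom, ref, ref + n)))
                ref += n
            elif op == "D":
                ref += n
            elif op == "I":
                q += n
            elif op == "S":
                if q == 0:
                    clip_l = n
                else:
                    clip_r = n
                q += n
        if brk:
            rid = len(jreads)
            jreads.append(read)
            clips.append((clip_l, clip_r))
            for qpos, key in brk:
                pair_rid.append(rid)
                pair_qpos.append(qpos)
                pair_key.append(key)
    if not jreads:
        return {}

    max_len = max(len(r.seq) for r in jreads)
    n_reads = len(jreads)
    # pad 32 columns so 16-base window codes exist at every start position
    codes = np.full((n_reads, max_len + 32), 4, dtype=np.uint8)
    lens = np.empty(n_reads, dtype=np.int64)
    for i, r in enumerate(jreads):
        arr = _B2[np.frombuffer(r.seq.encode("ascii"), dtype=np.uint8)].copy()
        cl, cr = clips[i]
        if cl:
            arr[:cl] = 255  # soft-clipped bases void a projection
        if cr:
            arr[arr.size - cr :] = 255
        codes[i, : arr.size] = arr
        lens[i] = arr.size
    valid_base = codes[:, :max_len] <= 3

    # rolling 16-base 2-bit codes, MSB-first; invalid bases recoded as A are
    # masked out later via the validity prefix sums
    c16 = np.zeros((n_reads, max_len + 16), dtype=np.uint64)
    cc = np.where(codes <= 3, codes, 0).astype(np.uint64)
    for j in range(16):
        c16 |= cc[:, j : j + max_len + 16] << np.uint64(30 - 2 * j)

    by_len: dict[int, list[str]] = defaultdict(list)
    long_patterns: list[str] = []
    for p in patterns:
        if len(p) <= 32:
            by_len[len(p)].append(p)
        else:
            long_patterns.append(p)

    rid_arr = np.array(pair_rid, dtype=np.int64)
    qpos_arr = np.array(pair_qpos, dtype=np.int64)
    spanning = np.zeros(rid_arr.size, dtype=bool)
    stride = max_len + 1

    for L, plist in sorted(by_len.items()):
        pcodes = np.zeros(len(plist), dtype=np.uint64)
        for i, p in enumerate(plist):
            v = np.uint64(0)
            for ch in p:
                v = (v << np.uint64(2)) | np.uint64(int(_B2[ord(ch)]))
            pcodes[i] = v
        pcodes = np.unique(pcodes)
        if L <= 16:
            win = c16[:, :max_len] >> np.uint64(32 - 2 * L)
        else:
            hi = c16[:, :max_len] << np.uint64(2 * (L - 16))
            lo2 = c16[:, 16 : 16 + max_len] >> np.uint64(32 - 2 * (L - 16))
            win = hi | lo2
        win_start_ok = np.arange(max_len)[None, :] <= (lens[:, None] - L)
        # windows containing an invalid base (N or a soft-clipped base,
        # recoded as A for packing) never match: prefix-sum of invalids
        invalid = (~valid_base).astype(np.int32)
        cs = np.zeros((n_reads, max_len + 1), dtype=np.int32)
        np.cumsum(invalid, axis=1, out=cs[:, 1:])
        clean = (cs[:, L:] - cs[:, :-L]) == 0
        ok = np.zeros_like(win_start_ok)
        ok[:, : clean.shape[1]] = clean
        ok &= win_start_ok
        member = np.zeros(win.shape, dtype=bool)
        idx = np.searchsorted(pcodes, win[ok])
        idx[idx >= pcodes.size] = pcodes.size - 1
        member_vals = pcodes[idx] == win[ok]
        member[ok] = member_vals
        # match flat positions, sorted by construction (row-major)
        flat = np.flatnonzero(member.reshape(-1))
        if flat.size == 0:
            continue
        rows = flat // max_len
        cols = flat % max_len
        flatpos = rows * stride + cols
        lo_q = rid_arr * stride + np.maximum(qpos_arr - L + 1, 0)
        hi_q = rid_arr * stride + qpos_arr - 1
        a = np.searchsorted(flatpos, lo_q, side="left")
        b = np.searchsorted(flatpos, hi_q, side="right")
        spanning |= b > a

    if long_patterns:
        ac = AhoCorasick(long_patterns)
        per_read_hits: dict[int, list[tuple[int, int]]] = defaultdict(list)
        for i, r in enumerate(jreads):
            for pi, off in ac.iter_matches(r.seq):
                per_read_hits[i].append((off, off + len(ac.patterns[pi])))
        for k in range(rid_arr.size):
            if spanning[k]:
                continue
            rid = int(rid_arr[k])
            cl, cr = clips[rid]
            rlen = int(lens[rid])
            for off, end in per_read_hits.get(rid, []):
                if off >= cl and end <= rlen - cr and off < qpos_arr[k] < end:
                    spanning[k] = True
                    break

    counts: dict[JunctionKey, int] = defaultdict(int)
    for k in np.flatnonzero(spanning):
        counts[pair_key[int(k)]] += 1
    return dict(counts)
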