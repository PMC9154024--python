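import random

import pytest
from scipy import stats

from splicigen.config import PipelineConfig, StrandMode, UniqueReadRule
from splicigen.io import AlignedRead, Genome
from splicigen.splice_graph import (
    AhoCorasick,
    build_splice_graph,
    count_junction_spanning_kmer_reads,
    extract_junction_support,
    locate_kmers_in_reads,
    project_match_to_path,
    snv_edge_test,
)

from .oracles import naive_locate


def _read(name, seq, pos, cigar, nh=1, chrom="chr1", mapq=60):
    return AlignedRead(name, seq, chrom, pos, cigar, mapq=mapq, nh=nh)


# ---------------------------------------------------------------------------
# junction support
# ---------------------------------------------------------------------------


def test_junction_support_counting(cfg):
    reads = [
        _read(f"r{i}", "A" * 8, 996, [("M", 4), ("N", 100), ("M", 4)]) for i in range(3)
    ]
    table = extract_junction_support(reads, cfg)
    assert table[("chr1", 1000, 1100)] == [3, 3]
    # one extra multi-mapping read raises total but not unique
    reads.append(_read("multi", "A" * 8, 996, [("M", 4), ("N", 100), ("M", 4)], nh=2))
    table = extract_junction_support(reads, cfg)
    assert table[("chr1", 1000, 1100)] == [3, 4]


def test_read_with_two_introns_hits_two_junctions(cfg):
    r = _read("r", "A" * 9, 0, [("M", 3), ("N", 10), ("M", 3), ("N", 20), ("M", 3)])
    table = extract_junction_support([r], cfg)
    assert set(table) == {("chr1", 3, 13), ("chr1", 16, 36)}


def test_unique_rule_falls_back_to_mapq(cfg):
    r = _read("r", "A" * 8, 0, [("M", 4), ("N", 10), ("M", 4)], nh=None, mapq=10)
    assert extract_junction_support([r], cfg).unique_count(("chr1", 4, 14)) == 0
    r2 = _read("r2", "A" * 8, 0, [("M", 4), ("N", 10), ("M", 4)], nh=None, mapq=60)
    assert extract_junction_support([r2], cfg).unique_count(("chr1", 4, 14)) == 1
    mq = cfg.replace(unique_read_rule=UniqueReadRule.mapq_ge_threshold)
    r3 = _read("r3", "A" * 8, 0, [("M", 4), ("N", 10), ("M", 4)], nh=5, mapq=60)
    assert extract_junction_support([r3], mq).unique_count(("chr1", 4, 14)) == 1


def test_support_conservation_property(cfg):
    rng = random.Random(0)
    reads = []
    n_ops = 0
    for i in range(100):
        blocks = rng.randint(1, 3)
        cigar = []
        seqlen = 0
        for b in range(blocks):
            m = rng.randint(2, 6)
            cigar.append(("M", m))
            seqlen += m
            if b < blocks - 1:
                cigar.append(("N", rng.randint(5, 50)))
                n_ops += 1
        reads.append(_read(f"r{i}", "A" * seqlen, rng.randint(0, 500), cigar))
    table = extract_junction_support(reads, cfg)
    assert sum(v[1] for v in table.values()) == n_ops


# ---------------------------------------------------------------------------
# SNV edge test
# ---------------------------------------------------------------------------


def test_snv_edge_test_against_direct_summation(cfg):
    assert snv_edge_test(0, 50, cfg) == 1.0
    assert snv_edge_test(30, 30, cfg) == pytest.approx(0.01 ** 30, rel=1e-9)
    # direct binomial tail summation oracle
    e = cfg.snv_error_rate
    exact = sum(
        stats.binom.pmf(k, 20, e) for k in range(10, 21)
    )
    assert snv_edge_test(10, 20, cfg) == pytest.approx(exact, rel=1e-9)
    with pytest.raises(ValueError):
        snv_edge_test(5, 4, cfg)
    with pytest.raises(ValueError):
        snv_edge_test(1, 0, cfg)


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------


@pytest.fixture
def flat_genome():
    return Genome.from_dict({"chr1": "ACGT" * 200})


def test_two_exon_junction_graph(flat_genome, cfg):
    seq = flat_genome.fetch("chr1", 100, 200) + flat_genome.fetch("chr1", 300, 400)
    reads = [
        _read(f"r{i}", seq, 100, [("M", 100), ("N", 100), ("M", 100)])
        for i in range(25)
    ]
    sg = build_splice_graph(reads, None, flat_genome, cfg)
    nodes = sorted(sg.graph.nodes)
    assert nodes == [("chr1", 100, 200), ("chr1", 300, 400)]
    jedges = [d for _, _, d in sg.graph.edges(data=True) if d["kind"] == "junction"]
    assert len(jedges) == 1 and jedges[0]["intron"] == (200, 300)
    assert jedges[0]["unique_reads"] == 25
    # segment partition: segments are disjoint and exclude the intron
    assert sg.find_segment("chr1", 250) is None


def test_snv_support_and_p_thresholds(flat_genome, cfg):
    ref = flat_genome.fetch("chr1", 0, 30)
    alt = "T" if ref[10] != "T" else "G"
    mut = ref[:10] + alt + ref[11:]
    # 9 mismatching reads at depth 100: below variant_min_support -> no edge
    reads = [_read(f"m{i}", mut, 0, [("M", 30)]) for i in range(9)]
    reads += [_read(f"w{i}", ref, 0, [("M", 30)]) for i in range(91)]
    sg = build_splice_graph(reads, None, flat_genome, cfg)
    assert not [d for *_, d in sg.graph.edges(data=True) if d["kind"] == "snv"]
    # 50/50 at depth 100 passes both support and p <= 5e-6
    reads = [_read(f"m{i}", mut, 0, [("M", 30)]) for i in range(50)]
    reads += [_read(f"w{i}", ref, 0, [("M", 30)]) for i in range(50)]
    sg = build_splice_graph(reads, None, flat_genome, cfg)
    snvs = [d for *_, d in sg.graph.edges(data=True) if d["kind"] == "snv"]
    assert len(snvs) == 1
    assert snvs[0]["position"] == 10 and snvs[0]["alt"] == alt
    assert snvs[0]["p_value"] <= cfg.snv_p_threshold


def test_unknown_chromosome_errors(flat_genome, cfg):
    bad = _read("r", "ACGT", 0, [("M", 4)], chrom="chrMissing")
    with pytest.raises(ValueError, match="chrMissing"):
        build_splice_graph([bad], None, flat_genome, cfg)


def test_coverage_gap_breaks_adjacency(flat_genome, cfg):
    reads = [_read("a", "A" * 10, 0, [("M", 10)]),
             _read("b", "A" * 10, 20, [("M", 10)])]
    sg = build_splice_graph(reads, None, flat_genome, cfg)
    assert sorted(sg.graph.nodes) == [("chr1", 0, 10), ("chr1", 20, 30)]
    assert not [d for *_, d in sg.graph.edges(data=True) if d["kind"] == "adjacency"]


# ---------------------------------------------------------------------------
# k-mer location
# ---------------------------------------------------------------------------


def test_locate_kmer_examples(cfg):
    read = _read("r", "AACGTT", 0, [("M", 6)])
    got = sorted(
        (k, off) for _, k, off in locate_kmers_in_reads(
            ["AAC", "CGT"], [read], StrandMode.forward_only)
    )
    assert got == [("AAC", 0), ("CGT", 2)]
    # absent k-mer
    assert list(locate_kmers_in_reads(["GGGG"], [read], StrandMode.forward_only)) == []
    # two occurrences in one read
    r2 = _read("r2", "ACGACG", 0, [("M", 6)])
    got = [(k, off) for _, k, off in locate_kmers_in_reads(
        ["ACG"], [r2], StrandMode.forward_only)]
    assert sorted(got) == [("ACG", 0), ("ACG", 3)]


def test_locate_matches_naive_oracle_with_revcomp():
    rng = random.Random(123)
    for _ in range(20):
        reads = [
            _read(f"r{i}", "".join(rng.choice("ACGT") for _ in range(rng.randint(8, 30))),
                  0, None)
            for i in range(rng.randint(1, 10))
        ]
        for r in reads:
            r.cigar = [("M", len(r.seq))]
        kmers = list({
            "".join(rng.choice("ACGT") for _ in range(rng.randint(2, 5)))
            for _ in range(rng.randint(1, 6))
        })
        got = sorted(
            (r.name, k, off)
            for r, k, off in locate_kmers_in_reads(kmers, reads, StrandMode.with_revcomp)
        )
        exp = sorted(
            (r.name, k, off)
            for r in reads
            for k, off in naive_locate(kmers, r.seq, with_revcomp=True)
        )
        assert got == exp


def test_aho_corasick_overlapping_patterns():
    ac = AhoCorasick(["AB".replace("B", "C"), "C", "ACA"])
    hits = sorted(ac.iter_matches("ACACC"))
    found = sorted((ac.patterns[pi], off) for pi, off in hits)
    assert found == [("AC", 0), ("AC", 2), ("ACA", 0), ("C", 1), ("C", 3), ("C", 4)]


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------


@pytest.fixture
def spliced_graph(flat_genome, cfg):
    seq = flat_genome.fetch("chr1", 10, 14) + flat_genome.fetch("chr1", 114, 118)
    reads = [_read(f"r{i}", seq, 10, [("M", 4), ("N", 100), ("M", 4)]) for i in range(5)]
    return build_splice_graph(reads, None, flat_genome, cfg)


def test_projection_across_junction(spliced_graph):
    read = _read("q", "X" * 8, 10, [("M", 4), ("N", 100), ("M", 4)])
    read.seq = "ACGTACGT"
    m = project_match_to_path(2, 4, read, spliced_graph)
    assert m is not None and m.spans_junction
    assert m.junctions == [("chr1", 14, 114)]
    segs = [item for item in m.path if item[0] == "segment"]
    assert [(s[2], s[3]) for s in segs] == [(10, 14), (114, 118)]


def test_projection_within_single_segment(spliced_graph):
    read = _read("q", "ACGTACGT", 10, [("M", 4), ("N", 100), ("M", 4)])
    m = project_match_to_path(0, 4, read, spliced_graph)
    assert m is not None and not m.spans_junction
    assert [i for i in m.path if i[0] == "junction"] == []


def test_projection_in_soft_clip_discarded(spliced_graph):
    read = _read("q", "ACGTACGT", 10, [("S", 2), ("M", 6)])
    assert project_match_to_path(0, 2, read, spliced_graph) is None
    assert project_match_to_path(1, 3, read, spliced_graph) is None
    assert project_match_to_path(2, 3, read, spliced_graph) is not None


def test_projection_length_consistency(flat_genome, cfg):
    """Reference span of a projected path equals query span plus intron and
    deletion lengths minus insertion lengths."""
    rng = random.Random(6)
    for _ in range(50):
        cigar = []
        qlen = 0
        ref_extra = 0
        cigar.append(("M", rng.randint(3, 8)))
        qlen += cigar[-1][1]
        for _ in range(rng.randint(0, 2)):
            kind = rng.choice("NDI")
            n = rng.randint(2, 40)
            if kind == "I":
                cigar.append(("I", min(n, 3)))
                qlen += cigar[-1][1]
            else:
                cigar.append((kind, n))
            m = rng.randint(3, 8)
            cigar.append(("M", m))
            qlen += m
        read = _read("q", "".join(rng.choice("ACGT") for _ in range(qlen)), 50, cigar)
        sg = build_splice_graph([read], None, flat_genome, cfg)
        lo = rng.randint(0, qlen - 2)
        ln = rng.randint(1, qlen - lo)
        m = project_match_to_path(lo, ln, read, sg)
        if m is None:
            continue
        introns = sum(i[3] - i[2] for i in m.path if i[0] in ("junction", "deletion"))
        ins = sum(len(i[3]) for i in m.path if i[0] == "insertion")
        assert m.ref_end - m.ref_start == ln - ins + introns


# ---------------------------------------------------------------------------
# vectorised junction-spanning counter vs exact projection
# ---------------------------------------------------------------------------


def test_fast_counter_matches_projection_route(flat_genome, cfg):
    rng = random.Random(42)
    genome_seq = flat_genome.fetch("chr1", 0, 800)
    reads = []
    for i in range(120):
        a = rng.randint(0, 300)
        m1 = rng.randint(4, 20)
        gap = rng.randint(20, 120)
        m2 = rng.randint(4, 20)
        seq = genome_seq[a : a + m1] + genome_seq[a + m1 + gap : a + m1 + gap + m2]
        reads.append(_read(f"r{i}", seq, a, [("M", m1), ("N", gap), ("M", m2)]))
    kmer_pool = sorted({r.seq[max(0, len(r.seq) // 2 - 4) : len(r.seq) // 2 + 4]
                        for r in reads[:40] if len(r.seq) >= 8})
    kmers = [k for k in kmer_pool if len(k) >= 4][:25]

    fast = count_junction_spanning_kmer_reads(kmers, reads, cfg)

    sg = build_splice_graph(reads, None, flat_genome, cfg)
    slow: dict = {}
    for read, kmer, off in locate_kmers_in_reads(kmers, reads, cfg.strand_mode):
        m = project_match_to_path(off, len(kmer), read, sg)
        if m is not None and m.spans_junction:
            for key in m.junctions:
                slow.setdefault(key, set()).add(read.name)
    slow_counts = {k: len(v) for k, v in slow.items()}
    assert fast == slow_counts
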