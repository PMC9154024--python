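import random

import numpy as np
import pytest

from splicigen.config import PipelineConfig, StrandMode
from splicigen.msbwt import (
    BwtIndex,
    build_bwt,
    count_pattern,
    find_tumor_specific_kmers,
)

from .oracles import brute_force_tumor_specific, naive_count, revcomp

SYM = "$ACGT"


def _rand_reads(rng, n, lo=4, hi=25):
    return ["".join(rng.choice("ACGT") for _ in range(rng.randint(lo, hi)))
            for _ in range(n)]


def test_single_string_bwt_matches_rotation_sort():
    # all rotations of "ACG$" sorted with terminator first -> last column G$AC
    idx = build_bwt(["ACG"])
    assert "".join(SYM[c] for c in idx.bwt) == "G$AC"
    assert idx.n_strings == 1
    assert np.all(np.diff(idx.C) >= 0)


def test_counting_examples():
    idx = build_bwt(["ACGTACGT"])
    assert count_pattern(idx, "ACG") == 2  # overlapping occurrences count
    idx2 = build_bwt(["ACGT", "CGTA"])
    assert count_pattern(idx2, "CGT") == 2
    assert count_pattern(idx2, "TTT") == 0
    assert count_pattern(idx2, "ACGTACGTT") == 0  # longer than every string
    assert count_pattern(idx2, "ACGN") == 0  # out-of-alphabet cannot occur
    with pytest.raises(ValueError):
        count_pattern(idx2, "")


def test_construction_contracts():
    with pytest.raises(ValueError):
        build_bwt([])
    with pytest.raises(ValueError):
        build_bwt(["ACN"])
    with pytest.raises(ValueError):
        build_bwt(["ACG", ""])


def test_counting_oracle_randomized():
    rng = random.Random(20240)
    for _ in range(30):
        reads = _rand_reads(rng, rng.randint(1, 50))
        mode = rng.choice([StrandMode.forward_only, StrandMode.with_revcomp])
        idx = build_bwt(reads, mode)
        pool = reads if mode is StrandMode.forward_only else reads + [revcomp(r) for r in reads]
        assert idx.C[1] == idx.n_strings  # one terminator per string
        for _ in range(40):
            pat = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 7)))
            assert idx.count(pat) == naive_count(pool, pat)


def test_duplicate_strings_count_with_multiplicity():
    idx = build_bwt(["ACGT"] * 7 + ["ACGA"] * 3)
    assert idx.count("ACG") == 10
    assert idx.count("ACGT") == 7
    assert idx.n_strings == 10


def test_depth_capped_index_exact_up_to_cap():
    rng = random.Random(5)
    reads = _rand_reads(rng, 40, 30, 40)
    capped = build_bwt(reads, max_query_len=12)
    for _ in range(200):
        r = rng.choice(reads)
        L = rng.randint(1, 12)
        i = rng.randint(0, len(r) - L)
        pat = r[i : i + L]
        assert capped.count(pat) == naive_count(reads, pat)


def test_serialization_round_trip(tmp_path):
    idx = build_bwt(["ACGTACGT", "TTTTAAAA"], StrandMode.with_revcomp)
    p = tmp_path / "x.bwt"
    idx.save(p)
    idx2 = BwtIndex.load(p)
    assert np.array_equal(idx.bwt, idx2.bwt)
    assert idx2.strand_mode is StrandMode.with_revcomp
    with pytest.raises(ValueError, match="not a BWT index"):
        bad = tmp_path / "bad.bwt"
        bad.write_bytes(b"nonsense")
        BwtIndex.load(bad)


# ---------------------------------------------------------------------------
# differential k-mer search
# ---------------------------------------------------------------------------


def _kmers_as_tuples(kmers):
    return [(k.sequence, k.tumor_count, k.normal_count) for k in kmers]


def test_lockstep_dfs_worked_example():
    tumor = build_bwt(["ACGTACGT"] * 25)
    normal = build_bwt(["ACGTTCGT"] * 25)
    cfg = PipelineConfig(t_min=21, n_max=3, strand_mode=StrandMode.forward_only)
    got = find_tumor_specific_kmers(tumor, normal, read_len=8, cfg=cfg)
    assert _kmers_as_tuples(got) == [("TA", 25, 0)]


def test_identical_read_sets_yield_nothing():
    reads = ["ACGTACGTAA"] * 30
    cfg = PipelineConfig(t_min=21, n_max=3, strand_mode=StrandMode.forward_only)
    assert find_tumor_specific_kmers(build_bwt(reads), build_bwt(reads), 10, cfg) == []


def test_tumor_threshold_boundary():
    # "ACGT" repeats no substring, so every substring count equals the copy
    # number: 20 copies sit just under t_min=21, 21 copies just over
    cfg = PipelineConfig(t_min=21, n_max=3, strand_mode=StrandMode.forward_only)
    normal = build_bwt(["TTTTTTTT"] * 20)
    tumor20 = build_bwt(["ACGT"] * 20)
    assert find_tumor_specific_kmers(tumor20, normal, 8, cfg) == []
    tumor21 = build_bwt(["ACGT"] * 21)
    assert find_tumor_specific_kmers(tumor21, normal, 8, cfg) != []


def test_dfs_equals_brute_force_randomized():
    rng = random.Random(77)
    for trial in range(25):
        tum = _rand_reads(rng, rng.randint(3, 50), 4, 20)
        nor = _rand_reads(rng, rng.randint(3, 50), 4, 20)
        t_min, n_max = rng.randint(2, 8), rng.randint(0, 3)
        mode = StrandMode.forward_only if trial % 2 else StrandMode.with_revcomp
        cfg = PipelineConfig(t_min=t_min, n_max=n_max, strand_mode=mode)
        rl = max(len(r) for r in tum)
        got = find_tumor_specific_kmers(
            build_bwt(tum, mode), build_bwt(nor, mode), rl, cfg
        )
        exp = brute_force_tumor_specific(
            tum, nor, t_min, n_max, cfg.max_kmer_len(rl),
            with_revcomp=(mode is StrandMode.with_revcomp),
        )
        assert _kmers_as_tuples(got) == exp, f"trial {trial}"


def test_non_minimal_mode_is_superset_containing_minimal():
    rng = random.Random(3)
    tum = _rand_reads(rng, 30, 6, 16)
    nor = _rand_reads(rng, 30, 6, 16)
    cfg = PipelineConfig(t_min=3, n_max=1, strand_mode=StrandMode.forward_only)
    rl = max(len(r) for r in tum)
    ti, ni = build_bwt(tum), build_bwt(nor)
    minimal = find_tumor_specific_kmers(ti, ni, rl, cfg, minimal=True)
    every = find_tumor_specific_kmers(ti, ni, rl, cfg, minimal=False)
    min_seqs = {k.sequence for k in minimal}
    all_seqs = {k.sequence for k in every}
    assert min_seqs <= all_seqs
    for s in all_seqs:
        assert any(m in s for m in min_seqs)


def test_dfs_determinism():
    rng = random.Random(9)
    tum = _rand_reads(rng, 40, 8, 20)
    nor = _rand_reads(rng, 40, 8, 20)
    cfg = PipelineConfig(t_min=4, n_max=2)
    rl = max(len(r) for r in tum)
    a = find_tumor_specific_kmers(build_bwt(tum, cfg.strand_mode),
                                  build_bwt(nor, cfg.strand_mode), rl, cfg)
    b = find_tumor_specific_kmers(build_bwt(tum, cfg.strand_mode),
                                  build_bwt(nor, cfg.strand_mode), rl, cfg)
    assert _kmers_as_tuples(a) == _kmers_as_tuples(b)
    assert [k.sequence for k in a] == sorted(k.sequence for k in a)


def test_dfs_rejects_mismatched_modes_and_bad_config():
    t = build_bwt(["ACGT"], StrandMode.forward_only)
    n = build_bwt(["ACGT"], StrandMode.with_revcomp)
    cfg = PipelineConfig()
    with pytest.raises(ValueError, match="strand mode"):
        find_tumor_specific_kmers(t, n, 4, cfg)
    with pytest.raises(ValueError, match="read_len"):
        find_tumor_specific_kmers(t, build_bwt(["ACGT"]), 1, cfg)
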