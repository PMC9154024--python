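"""Multi-string Burrows–Wheeler indexes over read collections.

The index is the BWT of the collection {s_1 $_1, ..., s_m $_m} where the
terminators sort below every base and among themselves by string index.  It
supports exact occurrence counting of any pattern across all indexed strings
via backward search, and a lockstep depth-first search over a tumor and a
matched-normal index that enumerates *tumor-specific k-mers*: strings
abundant in the tumor read collection (count >= t_min) but rare or absent in
the normal collection (count <= n_max).

Construction sorts all suffixes with a radix strategy suited to short reads:
each suffix is keyed by its 2-bit-packed sequence (padded with the smallest
symbol beyond its end) plus its length, which reproduces the
terminator-sorts-first order exactly.  Everything is NumPy-vectorised; the
lockstep DFS advances a whole frontier of BWT intervals per level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .config import PipelineConfig, StrandMode
from .io import reverse_complement

_BASES = "ACGT"
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode_bases(s: str) -> np.ndarray:
    """Map an A/C/G/T string to codes 0..3; raises on other symbols."""
    arr = _CODE[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() > 3:
        bad = chr(np.frombuffer(s.encode("ascii"), dtype=np.uint8)[arr > 3][0])
        raise ValueError(f"symbol {bad!r} outside alphabet {{A,C,G,T}}")
    return arr


@dataclass(frozen=True)
class BwtInterval:
    """A half-open row range in the sorted suffix order.

    The interval width equals the occurrence count of the represented string.
    """

    low: int
    high: int
    length: int

    @property
    def count(self) -> int:
        return self.high - self.low


@dataclass(frozen=True)
class TumorSpecificKmer:
    sequence: str
    tumor_count: int
    normal_count: int


class BwtIndex:
    """Multi-string BWT with rank support for backward-search counting."""

    MAGIC = b"SGBWT"
    VERSION = 1

    def __init__(
        self,
        bwt: np.ndarray,
        n_strings: int,
        strand_mode: StrandMode = StrandMode.forward_only,
    ):
        # symbol space: 0 = terminator, 1..4 = A,C,G,T
        self.bwt = np.ascontiguousarray(bwt, dtype=np.uint8)
        self.n_strings = int(n_strings)
        self.strand_mode = StrandMode(strand_mode)
        self.n_symbols = int(self.bwt.size)
        counts = np.bincount(self.bwt, minlength=5).astype(np.int64)
        if counts[0] != self.n_strings:
            raise ValueError(
                f"terminator count {counts[0]} != number of strings {self.n_strings}"
            )
        # C[s] = number of symbols strictly smaller than s (s in 0..5)
        self.C = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        # occ[c][i] = occurrences of base c (code 0..3) in bwt[:i]
        self._occ = np.empty((4, self.n_symbols + 1), dtype=np.int32)
        for c in range(4):
            self._occ[c, 0] = 0
            np.cumsum(self.bwt == c + 1, dtype=np.int32, out=self._occ[c, 1:])

    # -- primitive queries ------------------------------------------------

    def rank(self, base_code: int, i: int) -> int:
        """Occurrences of base ``base_code`` (0..3) in bwt[:i]."""
        return int(self._occ[base_code, i])

    def root(self) -> BwtInterval:
        return BwtInterval(0, self.n_symbols, 0)

    def extend_left(self, iv: BwtInterval, base_code: int) -> BwtInterval:
        lo = self.C[base_code + 1] + self._occ[base_code, iv.low]
        hi = self.C[base_code + 1] + self._occ[base_code, iv.high]
        return BwtInterval(int(lo), int(hi), iv.length + 1)

    def count(self, pattern: str) -> int:
        """Total occurrences of ``pattern`` across all indexed strings."""
        if not pattern:
            raise ValueError("empty pattern")
        codes = _CODE[np.frombuffer(pattern.encode("ascii"), dtype=np.uint8)]
        if codes.max() > 3:
            return 0  # symbols outside the alphabet cannot occur
        iv = self.root()
        for c in codes[::-1]:
            iv = self.extend_left(iv, int(c))
            if iv.count == 0:
                return 0
        return iv.count

    # -- serialization ----------------------------------------------------

    def save(self, path) -> None:
        """Serialize to a binary file: magic, version byte, then npz payload."""
        with open(path, "wb") as fh:
            fh.write(self.MAGIC + bytes([self.VERSION]))
            np.savez(
                fh,
                bwt=self.bwt,
                n_strings=np.int64(self.n_strings),
                strand_mode=np.bytes_(self.strand_mode.value.encode()),
            )

    @classmethod
    def load(cls, path) -> "BwtIndex":
        with open(path, "rb") as fh:
            magic = fh.read(len(cls.MAGIC))
            if magic != cls.MAGIC:
                raise ValueError(f"{path}: not a BWT index file")
            version = fh.read(1)[0]
            if version != cls.VERSION:
                raise ValueError(f"{path}: unsupported index version {version}")
            data = np.load(fh)
            return cls(
                data["bwt"],
                int(data["n_strings"]),
                StrandMode(bytes(data["strand_mode"]).decode()),
            )


def count_pattern(index: BwtIndex, pattern: str) -> int:
    return index.count(pattern)


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------


def build_bwt(
    strings: Sequence[str] | Iterable[str],
    strand_mode: StrandMode = StrandMode.forward_only,
    max_query_len: int | None = None,
) -> BwtIndex:
    """Build the multi-string BWT of a read collection.

    Under ``with_revcomp`` each string's reverse complement is appended as an
    additional indexed string, making counts strand-symmetric.  Construction
    is deterministic given input order.

    Duplicate strings are collapsed internally and their rows re-expanded by
    multiplicity after sorting; equal suffixes have identical preceding
    symbols and their relative order never changes any pattern count, so the
    resulting index counts exactly as if every copy were sorted separately.
    This makes construction cost scale with the *distinct* sequence content,
    which at deep coverage is far smaller than the raw base count.

    ``max_query_len`` optionally caps the suffix comparison depth.  Counting
    is then exact for every pattern up to that length (ties beyond the depth
    are broken consistently, which preserves the backward-search interval
    arithmetic); leave it ``None`` for exactness at all pattern lengths.
    """
    strings = list(strings)
    if not strings:
        raise ValueError("cannot build a BWT over an empty string collection")
    strand_mode = StrandMode(strand_mode)
    if strand_mode is StrandMode.with_revcomp:
        strings = strings + [reverse_complement(s) for s in strings]
    m = len(strings)

    # collapse duplicate strings, keeping first-occurrence order
    uniq_index: dict[str, int] = {}
    uidx = np.empty(m, dtype=np.int64)
    uniq: list[str] = []
    for i, s in enumerate(strings):
        if not s:
            raise ValueError(f"string {i} is empty")
        j = uniq_index.get(s)
        if j is None:
            j = len(uniq)
            uniq_index[s] = j
            uniq.append(s)
        uidx[i] = j
    mult = np.bincount(uidx, minlength=len(uniq)).astype(np.int64)

    try:
        flat = encode_bases("".join(uniq))
    except ValueError as exc:
        for i, s in enumerate(strings):
            if any(ch not in "ACGTacgt" for ch in s):
                raise ValueError(f"string {i} ({s!r}): {exc}") from exc
        raise
    mu = len(uniq)
    lengths = np.fromiter((len(s) for s in uniq), dtype=np.int64, count=mu)
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    maxlen = int(lengths.max())
    depth = maxlen if max_query_len is None else min(maxlen, int(max_query_len))
    n_words = max((depth + 31) // 32, 1)

    # pack unique reads into 2-bit words, MSB-first, spare zero word for shifts
    row_idx = np.repeat(np.arange(mu), lengths)
    col_idx = np.arange(flat.size) - np.repeat(starts, lengths)
    total_words = (maxlen + 31) // 32
    codes2d = np.zeros((mu, 32 * (total_words + 1)), dtype=np.uint8)
    codes2d[row_idx, col_idx] = flat
    packed = np.zeros((mu, total_words + 1), dtype=np.uint64)
    for j in range(total_words):
        block = codes2d[:, 32 * j : 32 * (j + 1)].astype(np.uint64)
        w = np.zeros(mu, dtype=np.uint64)
        for b in range(32):
            w |= block[:, b] << np.uint64(62 - 2 * b)
        packed[:, j] = w
    del codes2d

    # one entry per proper suffix of each unique string; terminator-only
    # suffixes occupy the first m rows of the final index in string order
    rid = row_idx
    off = col_idx
    suf_len = lengths[rid] - off

    keys = []
    for j in range(n_words):
        p = off + 32 * j
        valid = p < lengths[rid]
        k = np.where(valid, p >> 5, 0)
        sh = ((p & 31) * 2).astype(np.uint64)
        left = packed[rid, k] << sh
        # (x >> 1) >> (63 - sh) equals x >> (64 - sh) and is 0 when sh == 0
        right = (packed[rid, k + 1] >> np.uint64(1)) >> (np.uint64(63) - sh)
        w = np.where(valid, left | right, np.uint64(0))
        keys.append(w)
    # length tie-break makes a prefix sort before its extensions (the padded
    # keys tie in that case); np.lexsort's last key is primary
    len_key = suf_len.astype(np.uint16 if maxlen < 65536 else np.int64)
    order = np.lexsort(tuple([len_key] + keys[::-1]))
    del keys

    last = flat[starts + lengths - 1]
    srid = rid[order]
    prev = np.where(
        off[order] > 0, flat[starts[srid] + off[order] - 1] + 1, 0
    ).astype(np.uint8)
    body = np.repeat(prev, mult[srid])
    head = (last + 1)[uidx].astype(np.uint8)  # one row per string's terminator
    return BwtIndex(np.concatenate([head, body]), m, strand_mode)


# ---------------------------------------------------------------------------
# Lockstep differential k-mer search
# ---------------------------------------------------------------------------


def _reconstruct(levels, level: int, node: int) -> str:
    """Rebuild a string from the (symbol, parent) chain; symbols were
    prepended, so the chain reads left to right."""
    out = []
    while level >= 0:
        sym, parent = levels[level]
        out.append(_BASES[sym[node]])
        node = parent[node]
        level -= 1
    return "".join(out)


def _normal_count_of(index: BwtIndex, codes: Sequence[int]) -> int:
    iv = index.root()
    for c in reversed(codes):
        iv = index.extend_left(iv, c)
        if iv.count == 0:
            return 0
    return iv.count


def find_tumor_specific_kmers(
    tumor: BwtIndex,
    normal: BwtIndex,
    read_len: int,
    cfg: PipelineConfig,
    minimal: bool = True,
) -> list[TumorSpecificKmer]:
    """Enumerate tumor-specific k-mers by lockstep DFS over both indexes.

    A string qualifies when tumor count >= ``cfg.t_min`` and normal count
    <= ``cfg.n_max``; length is capped at ``floor(kmer_len_frac * read_len)``.
    With ``minimal=True`` (default) only *minimal* qualifying strings are
    returned — those with no qualifying proper substring; count monotonicity
    makes it sufficient that neither immediate substring (drop first or last
    base) qualifies.  With ``minimal=False`` every qualifying string up to
    the cap is returned.  Branches whose tumor count falls below ``t_min``
    are pruned; by monotonicity this loses nothing.  Output is sorted
    lexicographically and is deterministic.
    """
    if cfg.t_min < 1:
        raise ValueError("t_min must be >= 1")
    if read_len < 2:
        raise ValueError("read_len must be >= 2")
    if tumor.strand_mode is not normal.strand_mode:
        raise ValueError("tumor and normal indexes built under different strand modes")
    max_len = cfg.max_kmer_len(read_len)
    if max_len < 1:
        return []

    t_min, n_max = cfg.t_min, cfg.n_max
    # level arrays: per level, (sym codes, parent index into previous level)
    levels: list[tuple[np.ndarray, np.ndarray]] = []
    emitted: list[tuple[int, int, int, int]] = []  # (level, node, t_count, n_count)

    # level 0: the four single-base strings
    sym0 = np.arange(4, dtype=np.int8)
    par0 = np.full(4, -1, dtype=np.int64)
    tlo = tumor.C[1:5].astype(np.int64)
    thi = tumor.C[2:6].astype(np.int64)
    nlo = normal.C[1:5].astype(np.int64)
    nhi = normal.C[2:6].astype(np.int64)

    keep = (thi - tlo) >= t_min
    levels.append((sym0, par0))
    qual = keep & ((nhi - nlo) <= n_max)
    for node in np.flatnonzero(qual):
        emitted.append((0, int(node), int(thi[node] - tlo[node]), int(nhi[node] - nlo[node])))
    if minimal:
        frontier = np.flatnonzero(keep & ~qual)
    else:
        frontier = np.flatnonzero(keep)
    f_tlo, f_thi = tlo[frontier], thi[frontier]
    f_nlo, f_nhi = nlo[frontier], nhi[frontier]
    f_nodes = frontier

    level = 0
    while f_nodes.size and level + 1 < max_len:
        new_sym = []
        new_par = []
        new_tlo, new_thi, new_nlo, new_nhi = [], [], [], []
        parent_tcount = f_thi - f_tlo
        for c in range(4):
            c_tlo = tumor.C[c + 1] + tumor._occ[c, f_tlo]
            c_thi = tumor.C[c + 1] + tumor._occ[c, f_thi]
            tcount = c_thi - c_tlo
            # count monotonicity: an extension can never occur more often
            assert (tcount <= parent_tcount).all()
            keep = tcount >= t_min
            if not keep.any():
                continue
            c_nlo = normal.C[c + 1] + normal._occ[c, f_nlo[keep]]
            c_nhi = normal.C[c + 1] + normal._occ[c, f_nhi[keep]]
            new_sym.append(np.full(int(keep.sum()), c, dtype=np.int8))
            new_par.append(f_nodes[keep])
            new_tlo.append(c_tlo[keep])
            new_thi.append(c_thi[keep])
            new_nlo.append(c_nlo)
            new_nhi.append(c_nhi)
        if not new_sym:
            break
        sym = np.concatenate(new_sym)
        par = np.concatenate(new_par)
        tlo = np.concatenate(new_tlo)
        thi = np.concatenate(new_thi)
        nlo = np.concatenate(new_nlo)
        nhi = np.concatenate(new_nhi)
        levels.append((sym, par))
        level += 1

        qual = (nhi - nlo) <= n_max
        for node in np.flatnonzero(qual):
            emitted.append(
                (level, int(node), int(thi[node] - tlo[node]), int(nhi[node] - nlo[node]))
            )
        if minimal:
            ext = ~qual
        else:
            ext = np.ones(sym.size, dtype=bool)
        f_nodes = np.flatnonzero(ext)
        f_tlo, f_thi = tlo[f_nodes], thi[f_nodes]
        f_nlo, f_nhi = nlo[f_nodes], nhi[f_nodes]

    out: list[TumorSpecificKmer] = []
    for lv, node, tc, nc in emitted:
        seq = _reconstruct(levels, lv, node)
        if minimal and len(seq) >= 2:
            # minimality also requires that the (L-1)-prefix (drop the last,
            # i.e. rightmost, base) does not qualify; its tumor count is
            # >= t_min by monotonicity, so only the normal count decides.
            codes = [_BASES.index(ch) for ch in seq[:-1]]
            if _normal_count_of(normal, codes) <= n_max:
                continue
        out.append(TumorSpecificKmer(seq, tc, nc))
    out.sort(key=lambda k: k.sequence)
    return out
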