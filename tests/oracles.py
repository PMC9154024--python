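"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive — direct scans and exhaustive
enumeration — and shares no code with the package's data structures.
"""

from collections import Counter

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def naive_count(strings, pattern):
    """Occurrences of pattern across strings, counting overlaps."""
    n = 0
    for s in strings:
        for i in range(len(s) - len(pattern) + 1):
            if s[i : i + len(pattern)] == pattern:
                n += 1
    return n


def substring_counts(reads, max_len):
    c = Counter()
    for r in reads:
        for i in range(len(r)):
            for j in range(i + 1, min(len(r), i + max_len) + 1):
                c[r[i:j]] += 1
    return c


def brute_force_tumor_specific(tumor_reads, normal_reads, t_min, n_max, max_len,
                               with_revcomp=False):
    """Exhaustive differential k-mer enumeration with the minimality rule:
    a qualifying string is minimal iff no qualifying proper substring exists
    (checked directly against the full qualifying set)."""
    tum = list(tumor_reads) + ([revcomp(r) for r in tumor_reads] if with_revcomp else [])
    nor = list(normal_reads) + ([revcomp(r) for r in normal_reads] if with_revcomp else [])
    tc = substring_counts(tum, max_len)
    nc = substring_counts(nor, max_len)
    qual = {s for s, n in tc.items() if n >= t_min and nc.get(s, 0) <= n_max}
    minimal = []
    for s in qual:
        has_sub = False
        for i in range(len(s)):
            for j in range(i + 1, len(s) + 1):
                if (j - i) < len(s) and s[i:j] in qual:
                    has_sub = True
                    break
            if has_sub:
                break
        if not has_sub:
            minimal.append((s, tc[s], nc.get(s, 0)))
    return sorted(minimal)


def naive_locate(kmers, seq, with_revcomp=True):
    """All (kmer, offset) occurrences; a k-mer matches at an offset when the
    window equals it or (optionally) its reverse complement."""
    out = set()
    for k in kmers:
        targets = {k, revcomp(k)} if with_revcomp else {k}
        for i in range(len(seq) - len(k) + 1):
            if seq[i : i + len(k)] in targets:
                out.add((k, i))
    return sorted(out)
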