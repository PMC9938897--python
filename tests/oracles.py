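"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by exhaustive enumeration / textbook
dynamic programming, sharing no code paths with the package implementation.
"""

from __future__ import annotations

_COMP = str.maketrans("ACGTN", "TGCAN")
_STOPS = ("TAA", "TAG", "TGA")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_orfs(seq: str, min_aa: int = 50,
               starts: tuple[str, ...] = ("ATG", "TTG", "GTG")) -> set[tuple[int, int, str]]:
    """Six-frame enumeration: per (frame, stop codon) the 5'-most start after
    the previous stop, as (start, end, strand) genome intervals including the
    stop codon."""
    found = set()
    n = len(seq)
    for strand, s in (("+", seq), ("-", rc(seq))):
        for frame in range(3):
            prev_stop = frame - 3
            for i in range(frame, n - 2, 3):
                if s[i : i + 3] in _STOPS:
                    cands = [j for j in range(prev_stop + 3, i, 3) if s[j : j + 3] in starts]
                    if cands:
                        st = cands[0]
                        if (i - st) // 3 >= min_aa:
                            if strand == "+":
                                found.add((st, i + 3, "+"))
                            else:
                                found.add((n - (i + 3), n - st, "-"))
                    prev_stop = i
    return found


def sw_affine_brute(a: str, b: str, matrix, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Textbook Gotoh local alignment; a gap of length L costs open + L*extend."""
    n, m = len(a), len(b)
    neg = float("-inf")
    h = [[0.0] * (m + 1) for _ in range(n + 1)]
    e = [[neg] * (m + 1) for _ in range(n + 1)]
    f = [[neg] * (m + 1) for _ in range(n + 1)]
    first = gap_open + gap_extend
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e[i][j] = max(h[i][j - 1] - first, e[i][j - 1] - gap_extend)
            f[i][j] = max(h[i - 1][j] - first, f[i - 1][j] - gap_extend)
            sub = matrix[a[i - 1]][b[j - 1]]
            h[i][j] = max(0.0, h[i - 1][j - 1] + sub, e[i][j], f[i][j])
            best = max(best, h[i][j])
    return int(best)


_IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT", "S": "CG",
    "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT", "H": "ACT",
    "V": "ACG", "N": "ACGT",
}


def brute_iupac_hits(consensus: str, seq: str, both_strands: bool = True,
                     max_mismatch: int = 0) -> set[tuple[int, str]]:
    """Window-by-window comparison; (offset, strand) pairs, palindromes
    deduplicated to '+'."""
    by_set = {frozenset(v): k for k, v in _IUPAC_SETS.items()}

    def pattern_rc(p: str) -> str:
        return "".join(by_set[frozenset(b.translate(_COMP) for b in _IUPAC_SETS[c])]
                       for c in reversed(p))

    def mm(p: str, w: str) -> int:
        total = 0
        for pc, wc in zip(p, w):
            if wc == "N":
                total += 1
            elif not set(_IUPAC_SETS.get(wc, wc)) <= set(_IUPAC_SETS[pc]):
                total += 1
        return total

    w = len(consensus)
    pats = [("+", consensus)]
    if both_strands:
        pats.append(("-", pattern_rc(consensus)))
    palindromic = consensus == pattern_rc(consensus)
    hits = set()
    for strand, pat in pats:
        for i in range(len(seq) - w + 1):
            if mm(pat, seq[i : i + w]) <= max_mismatch:
                if palindromic and (i, "+") in hits:
                    continue
                hits.add((i, strand))
    return hits
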