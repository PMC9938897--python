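"""Degenerate palindromic motif derivation, IUPAC/PWM scanning, sigma-70 element calling.

The central operation mirrors how the CvkR operator was defined: positions of
a protected promoter sequence that agree with its own reverse complement are
kept, disagreeing positions are masked to N, producing a degenerate motif
that is palindromic by construction (for the CvkR site,
ATAACATTATGTGTT -> ANNACATNATGTNNT).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .seqio import GenomeRecord, Interval, TssRecord, reverse_complement

log = logging.getLogger("castkit")

IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": frozenset("ACGT"),
}
IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

MINUS10_CONSENSUS = "TATAAT"
MINUS35_CONSENSUS = "TTGACA"
# conservation weights: the strongly conserved positions (T-A....T of the -10,
# T-T-G of the -35) dominate the hexamer score so that weakly matching but
# documented boxes (e.g. TTGTAT) beat chance background matches
MINUS10_WEIGHTS = (1.0, 1.0, 0.5, 0.5, 0.5, 1.0)
MINUS35_WEIGHTS = (1.0, 1.0, 1.0, 0.5, 0.5, 0.5)


def iupac_reverse_complement(consensus: str) -> str:
    return "".join(IUPAC_COMPLEMENT[c] for c in reversed(consensus))


@dataclass(frozen=True)
class DegenerateMotif:
    """An IUPAC consensus of fixed width."""

    consensus: str

    def __post_init__(self):
        if not self.consensus or set(self.consensus) - set(IUPAC):
            raise ValueError(f"invalid IUPAC consensus {self.consensus!r}")

    @property
    def width(self) -> int:
        return len(self.consensus)

    @property
    def palindromic(self) -> bool:
        return self.consensus == iupac_reverse_complement(self.consensus)


@dataclass(frozen=True)
class MotifHit:
    loc: Interval
    strand: str
    matched_seq: str
    mismatches: int


@dataclass(frozen=True)
class Pwm:
    """Position count matrix with pseudocount smoothing and per-column information content."""

    counts: np.ndarray  # width x 4, column order A C G T
    pseudocount: float
    background: np.ndarray  # length-4 probabilities

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @property
    def probs(self) -> np.ndarray:
        c = self.counts + self.pseudocount
        return c / c.sum(axis=1, keepdims=True)

    @property
    def info_content(self) -> np.ndarray:
        """Per-column bits: sum_b p log2(p / q); equals 2 + sum p log2 p at uniform q."""
        p = self.probs
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log2(p / self.background), 0.0)
        return terms.sum(axis=1)


def derive_palindromic_consensus(site: str) -> DegenerateMotif:
    """Mask positions of ``site`` that disagree with its reverse complement to N.

    Odd widths are allowed; the centre column is compared with itself (never
    self-complementary, hence always N).  The result is palindromic by
    construction.
    """
    site = site.upper()
    if len(site) < 4 or set(site) - set("ACGT"):
        raise ValueError("site must be >= 4 nt over {A,C,G,T}")
    rc = reverse_complement(site)
    consensus = "".join(b if b == rc[i] else "N" for i, b in enumerate(site))
    return DegenerateMotif(consensus)


def _window_mismatches(pattern: str, window: str, n_as_wildcard_in_seq: bool) -> int:
    mm = 0
    for p, s in zip(pattern, window):
        if s == "N":
            # conservative: an unknown sequence base counts as a mismatch
            if not n_as_wildcard_in_seq:
                mm += 1
        elif not IUPAC.get(s, frozenset(s)) <= IUPAC[p]:
            # a (possibly ambiguous) sequence code matches when its base set
            # is contained in the motif position's allowed set
            mm += 1
    return mm


def iupac_scan(motif: DegenerateMotif, seq: str, both_strands: bool = True,
               max_mismatch: int = 0, contig: str = "seq",
               n_as_wildcard_in_seq: bool = False) -> list[MotifHit]:
    """All windows matching the motif under IUPAC semantics with <= max_mismatch mismatches.

    Degeneracy lives in the motif only; an N in the *sequence* counts as a
    mismatch unless ``n_as_wildcard_in_seq``.  For palindromic motifs, plus
    and minus hits at the same window are deduplicated to the plus-strand
    representative.
    """
    seq = seq.upper()
    w = motif.width
    if w > len(seq):
        return []
    patterns = [("+", motif.consensus)]
    if both_strands:
        patterns.append(("-", iupac_reverse_complement(motif.consensus)))
    hits: dict[tuple[int, str], MotifHit] = {}
    for strand, pattern in patterns:
        for i in range(len(seq) - w + 1):
            window = seq[i : i + w]
            mm = _window_mismatches(pattern, window, n_as_wildcard_in_seq)
            if mm <= max_mismatch:
                key = (i, strand)
                if motif.palindromic and (i, "+") in hits:
                    continue  # palindrome: keep the + representative
                hits[key] = MotifHit(Interval(contig, i, i + w, strand), strand, window, mm)
    return sorted(hits.values(), key=lambda h: (h.loc.start, h.strand))


def pwm_from_sites(sites: list[str], pseudocount: float = 0.0,
                   background: np.ndarray | None = None) -> Pwm:
    """Accumulate aligned equal-width sites into a count matrix."""
    if not sites:
        raise ValueError("no sites given")
    w = len(sites[0])
    if any(len(s) != w for s in sites):
        raise ValueError("sites must all have the same width")
    order = "ACGT"
    counts = np.zeros((w, 4))
    for s in sites:
        s = s.upper()
        for i, b in enumerate(s):
            if b not in order:
                raise ValueError(f"non-ACGT base {b!r} in site {s!r}")
            counts[i, order.index(b)] += 1
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    if not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("background must sum to 1")
    return Pwm(counts, pseudocount, bg)


def write_meme(pwm: Pwm, name: str, path) -> None:
    """Minimal MEME-format PWM export."""
    p = pwm.probs
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write(f"MOTIF {name}\n")
        fh.write(f"letter-probability matrix: alength= 4 w= {pwm.width}\n")
        for row in p:
            fh.write(" " + "  ".join(f"{x:.6f}" for x in row) + "\n")


def extract_promoter(tss: TssRecord, genome: GenomeRecord, upstream: int = 80,
                     downstream: int = 0) -> str:
    """Strand-aware promoter fragment 5'->3' including the TSS nucleotide."""
    n = len(genome.seq)
    if not (0 <= tss.pos0 < n):
        raise ValueError(f"TSS position {tss.pos} outside contig {genome.id} ({n} nt)")
    if tss.strand == "+":
        lo, hi = tss.pos0 - upstream, tss.pos0 + downstream + 1
    else:
        lo, hi = tss.pos0 - downstream, tss.pos0 + upstream + 1
    if lo < 0 or hi > n:
        log.warning("promoter window for TSS %s:%d clipped at contig bounds", tss.contig, tss.pos)
        lo, hi = max(lo, 0), min(hi, n)
    fragment = genome.seq[lo:hi]
    return fragment if tss.strand == "+" else reverse_complement(fragment)


def _weighted_identity(a: str, consensus: str, weights: tuple[float, ...]) -> float:
    return sum(w for x, y, w in zip(a, consensus, weights) if x == y)


def find_sigma_elements(promoter: str, tss_offset: int,
                        minus10_gap: tuple[int, int] = (4, 9),
                        spacer_range: tuple[int, int] = (15, 22),
                        long_spacer_at: int = 19) -> dict:
    """Best-scoring -10/-35 hexamer pair upstream of the TSS.

    ``tss_offset`` is the index of the TSS nucleotide within ``promoter``
    (5'->3').  The -10 box must end 4-9 nt upstream of the TSS and the
    -10/-35 spacer must be 15-22 nt.  Spacers >= 19 nt set a long-spacer flag
    (the MerR-context heuristic).  Scoring is conservation-weighted identity
    to TATAAT/TTGACA (0-9 total); energy models are out of scope.
    """
    promoter = promoter.upper()
    min_needed = 6 + spacer_range[1] + 6 + minus10_gap[1]
    if tss_offset < min_needed:
        raise ValueError(f"promoter must cover >= {min_needed} nt upstream of the TSS")
    best = None
    for gap in range(minus10_gap[0], minus10_gap[1] + 1):
        m10_end = tss_offset - gap
        m10_start = m10_end - 6
        m10 = promoter[m10_start:m10_end]
        for spacer in range(spacer_range[0], spacer_range[1] + 1):
            m35_end = m10_start - spacer
            m35_start = m35_end - 6
            if m35_start < 0:
                continue
            m35 = promoter[m35_start:m35_end]
            score = (_weighted_identity(m10, MINUS10_CONSENSUS, MINUS10_WEIGHTS)
                     + _weighted_identity(m35, MINUS35_CONSENSUS, MINUS35_WEIGHTS))
            key = (score, -gap, -spacer)  # ties: smaller gap, then smaller spacer
            if best is None or key > best[0]:
                best = (key, {
                    "minus10": ((m10_start, m10_end), m10),
                    "minus35": ((m35_start, m35_end), m35),
                    "spacer_len": spacer,
                    "tss_gap": gap,
                    "score": score,
                    "long_spacer": spacer >= long_spacer_at,
                    "low_confidence": score < 5.0,
                })
    return best[1]
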