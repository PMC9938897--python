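"""CRISPR repeat-spacer array detection, anchor module (R* + anchor spacer +
protospacer + GTN PAM) recovery, and tracrRNA localisation.

Array detection is k-mer-seeded periodic-repeat detection: exact k-mers
recurring at array-like periods seed candidate unit sets, which are extended
column-wise into maximal similar repeats and summarised by a column-majority
consensus.  The anchor module is the truncated repeat (R*, ~12 nt of the
repeat's conserved segment) next to a truncated ~17-nt spacer inside the
transposon, matching a protospacer just outside the left end with an
upstream GTN PAM read toward the left end.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .orfcat import Orf
from .seqio import GenomeRecord, Interval, TssRecord, reverse_complement

log = logging.getLogger("castkit")


@dataclass(frozen=True)
class ArrayParams:
    min_repeats: int = 3
    repeat_len_range: tuple[int, int] = (20, 50)
    spacer_len_range: tuple[int, int] = (20, 60)
    seed_k: int = 13
    period_range: tuple[int, int] = (40, 110)
    min_repeat_identity: float = 0.8
    # a column is part of the repeat while its majority base reaches this fraction
    min_column_fraction: float = 0.75


@dataclass(frozen=True)
class AnchorParams:
    r_star_len: int = 12
    r_star_min_matches: int = 9          # >= 75% identity over >= 10 nt of a 12-nt segment
    spacer_len_range: tuple[int, int] = (15, 19)
    spacer_len_prior: int = 17
    max_protospacer_mismatches: int = 1
    outside_window: int = 200
    min_array_separation: int = 20       # R* must be clearly separated from the array
    pam_le_expected_range: tuple[int, int] = (46, 82)  # soft check only (147-nt outliers exist)


@dataclass(frozen=True)
class CrisprArray:
    loc: Interval
    repeats: tuple[Interval, ...]
    spacers: tuple[Interval, ...]
    consensus_repeat: str
    orientation: str = "unknown"  # '+', '-', or 'unknown'


@dataclass(frozen=True)
class AnchorModule:
    r_star: Interval
    anchor_spacer: Interval
    protospacer: Interval
    pam: str                      # read toward the left end; matches GTN
    pam_to_le_distance: int
    mismatches: int = 0
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class TracrLocus:
    loc: Interval
    tss: TssRecord | None
    distance_from_cas12k_stop: int | None
    predicted: bool = False
    flags: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# array detection


def _column(seq: str, unit_starts: list[int], offset: int) -> list[str]:
    return [seq[p + offset] for p in unit_starts if 0 <= p + offset < len(seq)]


def _column_ok(col: list[str], n_units: int, min_frac: float) -> bool:
    if len(col) < n_units:
        return False
    top = Counter(col).most_common(1)[0][1]
    return top / len(col) >= min_frac


def _consensus_base(col: list[str]) -> str:
    counts = Counter(col)
    best = max(counts.items(), key=lambda kv: (kv[1], -ord(kv[0])))
    return best[0]


def _expand_chain(seq: str, anchors: list[int], k: int, cfg: ArrayParams) -> tuple[int, int] | None:
    """Extend the aligned k-mer anchors column-wise into maximal repeat offsets.

    Returns (left_offset, right_offset) relative to the anchor positions such
    that the repeat occupies [p + left, p + right) for each anchor p.
    """
    n = len(anchors)
    max_len = cfg.repeat_len_range[1]
    left = 0
    while (k - left) < max_len:
        col = _column(seq, anchors, left - 1)
        if not _column_ok(col, n, cfg.min_column_fraction):
            break
        left -= 1
    right = k
    while (right - left) < max_len:
        col = _column(seq, anchors, right)
        if not _column_ok(col, n, cfg.min_column_fraction):
            break
        right += 1
    if right - left < cfg.repeat_len_range[0]:
        return None
    return left, right


def _chain_positions(positions: list[int], period: tuple[int, int]) -> list[list[int]]:
    chains, chain = [], [positions[0]]
    for p in positions[1:]:
        d = p - chain[-1]
        if period[0] <= d <= period[1]:
            chain.append(p)
        elif d > period[1]:
            chains.append(chain)
            chain = [p]
        # d < period_min: same-unit duplicate k-mer; ignore
    chains.append(chain)
    return chains


def detect_arrays(genome: GenomeRecord, cfg: ArrayParams | None = None) -> list[CrisprArray]:
    """Detect repeat-spacer arrays; non-overlapping, deterministic order."""
    cfg = cfg or ArrayParams()
    seq = genome.seq
    k = cfg.seed_k
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i : i + k]].append(i)

    candidates: list[CrisprArray] = []
    seen_units: set[tuple[int, ...]] = set()
    for kmer, positions in index.items():
        if len(positions) < cfg.min_repeats or "N" in kmer:
            continue
        for chain in _chain_positions(positions, cfg.period_range):
            if len(chain) < cfg.min_repeats:
                continue
            span = _expand_chain(seq, chain, k, cfg)
            if span is None:
                continue
            left, right = span
            starts = tuple(p + left for p in chain)
            if starts in seen_units:
                continue
            seen_units.add(starts)
            array = _build_array(genome, list(starts), right - left, cfg)
            if array is not None:
                candidates.append(array)

    # dedupe overlapping candidates: prefer more repeats, then longer span
    candidates.sort(key=lambda a: (-len(a.repeats), -(len(a.loc)), a.loc.start))
    kept: list[CrisprArray] = []
    for cand in candidates:
        if all(cand.loc.end <= other.loc.start or cand.loc.start >= other.loc.end
               for other in kept):
            kept.append(cand)
    return sorted(kept, key=lambda a: a.loc.start)


def _identity_fraction(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / max(len(a), 1)


def _build_array(genome: GenomeRecord, starts: list[int], rep_len: int,
                 cfg: ArrayParams) -> CrisprArray | None:
    seq = genome.seq
    # drop terminal units violating the spacer-length constraint
    while len(starts) >= cfg.min_repeats:
        gaps = [starts[i + 1] - (starts[i] + rep_len) for i in range(len(starts) - 1)]
        lo, hi = cfg.spacer_len_range
        if gaps and not (lo <= gaps[0] <= hi):
            starts = starts[1:]
        elif gaps and not (lo <= gaps[-1] <= hi):
            starts = starts[:-1]
        else:
            break
    if len(starts) < cfg.min_repeats:
        return None
    units = [seq[p : p + rep_len] for p in starts]
    consensus = "".join(_consensus_base([u[i] for u in units]) for i in range(rep_len))
    if any(_identity_fraction(u, consensus) < cfg.min_repeat_identity for u in units):
        return None
    if not (cfg.repeat_len_range[0] <= rep_len <= cfg.repeat_len_range[1]):
        return None
    contig = genome.id
    repeats = tuple(Interval(contig, p, p + rep_len) for p in starts)
    spacers = tuple(Interval(contig, repeats[i].end, repeats[i + 1].start)
                    for i in range(len(repeats) - 1))
    loc = Interval(contig, repeats[0].start, repeats[-1].end)
    return CrisprArray(loc, repeats, spacers, consensus)


# ---------------------------------------------------------------------------
# orientation


def orient_array(array: CrisprArray, genome: GenomeRecord,
                 context: dict | None = None) -> str:
    """Assign reading orientation: toward the left end when context gives one.

    With an ``le`` position in ``context`` the array reads toward the LE
    ('-' when the LE lies left of the array in genome coordinates).  Without
    context, the more-conserved repeat half (3' conservation) is used; fully
    uniform repeats are 'unknown'.
    """
    if context and "le" in context and context["le"] is not None:
        return "-" if context["le"] <= array.loc.start else "+"
    # 3'-conservation fallback: compare identity of the two repeat halves
    half = len(array.consensus_repeat) // 2
    units = [genome.seq[r.start : r.end] for r in array.repeats]
    left_id = sum(_identity_fraction(u[:half], array.consensus_repeat[:half]) for u in units)
    right_id = sum(_identity_fraction(u[half:], array.consensus_repeat[half:]) for u in units)
    if abs(left_id - right_id) < 1e-9:
        return "unknown"
    # the conserved segment is the 3' end of the repeat in reading direction
    return "-" if left_id > right_id else "+"


def with_orientation(array: CrisprArray, orientation: str) -> CrisprArray:
    return CrisprArray(array.loc, array.repeats, array.spacers,
                       array.consensus_repeat, orientation)


# ---------------------------------------------------------------------------
# anchor module


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def find_anchor(genome: GenomeRecord, array: CrisprArray, le: int,
                cfg: AnchorParams | None = None) -> AnchorModule | None:
    """Locate R* + anchor spacer between array and LE, and the matching
    protospacer + GTN PAM just outside the left end.

    The LE may be an exact boundary or a hypothesis; the protospacer is
    sought in a window of ``outside_window`` nt outside the LE.  The PAM is
    read toward the left end.  A PAM-LE distance outside the observed 46-82 nt
    band is reported as a warning, not rejected.
    """
    cfg = cfg or AnchorParams()
    seq, contig = genome.seq, genome.id
    left_side = le <= array.loc.start  # LE left of array in genome coordinates

    if left_side:
        region = (max(le, 0), array.loc.start - cfg.min_array_separation)
        segment = array.consensus_repeat[: cfg.r_star_len]
    else:
        region = (array.loc.end + cfg.min_array_separation, min(le, len(seq)))
        segment = array.consensus_repeat[-cfg.r_star_len :]
    if region[1] - region[0] < cfg.r_star_len:
        return None

    # best R* = best match of the repeat's conserved segment in the region
    best_rs = None
    for i in range(region[0], region[1] - cfg.r_star_len + 1):
        window = seq[i : i + cfg.r_star_len]
        matches = cfg.r_star_len - _mismatches(segment, window)
        if matches >= cfg.r_star_min_matches and (best_rs is None or matches > best_rs[0]):
            best_rs = (matches, i)
    if best_rs is None:
        return None
    rs_start = best_rs[1]
    r_star = Interval(contig, rs_start, rs_start + cfg.r_star_len)

    if left_side:
        outside = (max(le - cfg.outside_window, 0), le)
    else:
        outside = (le, min(le + cfg.outside_window, len(seq)))

    candidates = []
    for length in range(cfg.spacer_len_range[0], cfg.spacer_len_range[1] + 1):
        if left_side:
            sp = Interval(contig, rs_start - length, rs_start)
        else:
            sp = Interval(contig, r_star.end, r_star.end + length)
        if sp.start < 0 or sp.end > len(seq):
            continue
        spacer_seq = seq[sp.start : sp.end]
        for m0 in range(outside[0], outside[1] - length + 1):
            mm = _mismatches(spacer_seq, seq[m0 : m0 + length])
            if mm > cfg.max_protospacer_mismatches:
                continue
            # PAM is upstream of the protospacer read toward the LE
            if left_side:
                pam_iv = (m0 + length, m0 + length + 3)
                pam = reverse_complement(seq[pam_iv[0] : pam_iv[1]])
                dist = le - pam_iv[1]
            else:
                pam_iv = (m0 - 3, m0)
                pam = seq[pam_iv[0] : pam_iv[1]]
                dist = pam_iv[0] - le
            if len(pam) < 3 or pam[0] != "G" or pam[1] != "T" or dist < 0:
                continue
            candidates.append((mm, abs(length - cfg.spacer_len_prior), dist,
                               sp, Interval(contig, m0, m0 + length), pam))
    if not candidates:
        return None
    mm, _, dist, sp, proto, pam = min(candidates, key=lambda c: c[:3])
    warnings = []
    lo, hi = cfg.pam_le_expected_range
    if not (lo <= dist <= hi):
        warnings.append(f"PAM-LE distance {dist} outside observed {lo}-{hi} nt band")
        log.warning("anchor module: %s", warnings[-1])
    return AnchorModule(r_star, sp, proto, pam, dist, mm, tuple(warnings))


# ---------------------------------------------------------------------------
# tracrRNA


def locate_tracr(genome: GenomeRecord, cas12k: Orf, tss_list: list[TssRecord],
                 array: CrisprArray | None,
                 window: tuple[int, int] = (10, 100)) -> TracrLocus:
    """tracrRNA locus from a TSS shortly downstream of the cas12k stop codon.

    Distance convention: the first nucleotide after the stop codon is
    position 1; a TSS at position D gives distance D.  Without a qualifying
    TSS, the locus is predicted as the interval from the cas12k stop to the
    array edge.
    """
    contig = genome.id
    flags: list[str] = []
    minus = cas12k.loc.strand == "-"
    stop_edge = cas12k.loc.start if minus else cas12k.loc.end  # plus-coord boundary at the stop

    best: tuple[int, TssRecord] | None = None
    for t in tss_list:
        if t.contig != contig or t.strand != cas12k.loc.strand:
            continue
        d = (stop_edge - t.pos0) if minus else (t.pos0 - stop_edge + 1)
        if window[0] <= d <= window[1] and (best is None or d < best[0]):
            best = (d, t)

    if array is not None:
        array_edge = array.loc.end if minus else array.loc.start
        downstream_ok = (array.loc.end <= stop_edge) if minus else (array.loc.start >= stop_edge)
        if not downstream_ok:
            flags.append("array does not lie downstream of the cas12k stop")
    else:
        array_edge = None
        flags.append("no array available; tracr span open-ended")

    if best is not None:
        d, tss = best
        if minus:
            end = tss.pos0 + 1
            start = array_edge if array_edge is not None else max(end - 500, 0)
            loc = Interval(contig, start, end, "-")
        else:
            start = tss.pos0
            end = array_edge if array_edge is not None else min(start + 500, len(genome.seq))
            loc = Interval(contig, start, end, "+")
        return TracrLocus(loc, tss, d, False, tuple(flags))

    if best is None and any(t.contig == contig for t in tss_list):
        flags.append("no same-strand TSS within the downstream window; predicted locus used")
        log.warning("tracr: %s", flags[-1])
    if minus:
        start = array_edge if array_edge is not None else max(stop_edge - 500, 0)
        loc = Interval(contig, start, stop_edge, "-")
    else:
        end = array_edge if array_edge is not None else min(stop_edge + 500, len(genome.seq))
        loc = Interval(contig, stop_edge, end, "+")
    return TracrLocus(loc, None, None, True, tuple(flags))
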