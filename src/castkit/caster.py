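"""Assembly of detected components into validated CAST systems.

A system is anchored on cas12k.  Assembly is permissive -- components are
attached wherever they are found -- while validation is explicit: violations
of the canonical architecture (tnsB-tnsC-tniQ order reading away from the
right end, divergent upstream regulator, array oriented toward the left end)
are appended to ``flags`` rather than causing rejection.  Transposon end
detection is a terminal-inverted-repeat heuristic with an explicit
confidence field.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from . import __version__
from .crisprdet import (AnchorModule, AnchorParams, ArrayParams, CrisprArray,
                        TracrLocus, detect_arrays, find_anchor, locate_tracr,
                        orient_array, with_orientation)
from .homsearch import (DEFAULT_EVALUE_THRESHOLD, AlignmentHit, ScoringParams,
                        is_homolog)
from .orfcat import DEFAULT_MIN_AA, Orf, StartCorrection, correct_start_from_tss, find_orfs
from .refdata import (CORE_GENES, REGULATOR_FAMILIES, REGULATOR_LENGTH_RANGES,
                      TRNA_TOKEN, load_reference_sets)
from .seqio import (Feature, GenomeRecord, Interval, TssRecord, make_feature,
                    reverse_complement)

log = logging.getLogger("castkit")

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RegulatorCall:
    orf: Orf
    family: str
    best_hit: AlignmentHit
    length_ok: bool
    distance_to_cas12k: int


@dataclass(frozen=True)
class Ends:
    le: int
    re: int
    confidence: str          # "high" (TIR pair found) or "low" (flanking evidence)
    tir_len: int | None = None


@dataclass
class CastSystem:
    contig: str
    le: int | None
    re: int | None
    trna: Interval | None
    array: CrisprArray | None
    anchor: AnchorModule | None
    tracr: TracrLocus | None
    cas12k: Orf
    tnsB: Orf | None
    tnsC: Orf | None
    tniQ: Orf | None
    regulator: RegulatorCall | None
    regulator_type: str      # CvkR / Arc_1 / Arc_2 / unknown / none
    cargo: list[Orf] = field(default_factory=list)
    ends_confidence: str = "low"
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# regulator classification


def classify_regulator(candidates: list[Orf], cas12k: Orf,
                       refsets: dict[str, list[tuple[str, str]]] | None = None,
                       threshold: float = DEFAULT_EVALUE_THRESHOLD,
                       max_distance: int = 3000,
                       params: ScoringParams | None = None) -> RegulatorCall | None:
    """Call the regulator family among ORFs divergently upstream of cas12k.

    Candidates must be on the opposite strand with their proximal end within
    ``max_distance`` nt of the cas12k start.  The family is the best-e-value
    hit at the threshold against the three bundled regulator reference sets;
    with several qualifying ORFs the highest-scoring one is kept.
    """
    refsets = refsets or load_reference_sets()
    minus = cas12k.loc.strand == "-"
    qualifying = []
    for orf in candidates:
        if orf.loc.strand == cas12k.loc.strand or orf.loc.contig != cas12k.loc.contig:
            continue
        gap = (orf.loc.start - cas12k.loc.end) if minus else (cas12k.loc.start - orf.loc.end)
        # small negative gaps tolerated: divergent genes may overlap before
        # leaderless start correction
        if not (-60 <= gap <= max_distance):
            continue
        best: tuple[AlignmentHit, str] | None = None
        for family in REGULATOR_FAMILIES:
            hit = is_homolog(orf.protein, refsets[family], threshold, params)
            if hit is not None and (best is None or hit.evalue < best[0].evalue):
                best = (hit, family)
        if best is not None:
            qualifying.append((best[0], best[1], orf, max(gap, 0)))
    if not qualifying:
        return None
    qualifying.sort(key=lambda q: (q[0].evalue, -q[0].raw_score))
    for extra in qualifying[1:]:
        log.warning("additional regulator candidate at %s ignored", extra[2].loc)
    hit, family, orf, dist = qualifying[0]
    lo, hi = REGULATOR_LENGTH_RANGES[family]
    return RegulatorCall(orf, family, hit, lo <= len(orf.protein) <= hi, dist)


# ---------------------------------------------------------------------------
# transposon ends


def _longest_ir_match(left: str, right_rc: str, seed_k: int = 10,
                      min_len: int = 15, min_identity: float = 0.8):
    """Longest inverted-repeat match between two windows (seed + extend,
    single-mismatch bridging, trimmed back to exact-match ends)."""
    index: dict[str, list[int]] = {}
    for j in range(len(right_rc) - seed_k + 1):
        index.setdefault(right_rc[j : j + seed_k], []).append(j)
    best = None
    for i in range(len(left) - seed_k + 1):
        for j in index.get(left[i : i + seed_k], ()):
            lo_i, lo_j = i, j
            while lo_i > 0 and lo_j > 0 and left[lo_i - 1] == right_rc[lo_j - 1]:
                lo_i, lo_j = lo_i - 1, lo_j - 1
            hi_i, hi_j = i + seed_k, j + seed_k
            while hi_i < len(left) and hi_j < len(right_rc) and left[hi_i] == right_rc[hi_j]:
                hi_i, hi_j = hi_i + 1, hi_j + 1
            # bridge isolated mismatches while downstream matches resume
            while (hi_i + 1 < len(left) and hi_j + 1 < len(right_rc)
                   and left[hi_i + 1] == right_rc[hi_j + 1]):
                hi_i, hi_j = hi_i + 1, hi_j + 1
                while hi_i < len(left) and hi_j < len(right_rc) and left[hi_i] == right_rc[hi_j]:
                    hi_i, hi_j = hi_i + 1, hi_j + 1
            # trim to exact ends
            while hi_i > lo_i and left[hi_i - 1] != right_rc[hi_j - 1]:
                hi_i, hi_j = hi_i - 1, hi_j - 1
            length = hi_i - lo_i
            if length < min_len:
                continue
            ident = sum(left[lo_i + x] == right_rc[lo_j + x] for x in range(length)) / length
            if ident < min_identity:
                continue
            cand = (length, -lo_i, (lo_i, hi_i, lo_j, hi_j))
            if best is None or cand[:2] > best[:2]:
                best = cand
    return None if best is None else best[2]


def detect_ends(genome: GenomeRecord, trna: Interval | None, anchor: AnchorModule | None,
                tnsB: Orf | None, array: CrisprArray | None,
                window: int = 500, tir_range: tuple[int, int] = (15, 40)) -> Ends:
    """LE/RE detection: paired terminal inverted repeats around the locus,
    falling back to flanking evidence (protospacer / tnsB) at low confidence."""
    seq = genome.seq
    left_edge = None
    if anchor is not None:
        left_edge = min(anchor.r_star.start, anchor.anchor_spacer.start)
    elif array is not None:
        left_edge = array.loc.start
    elif trna is not None:
        left_edge = trna.end + window // 2
    right_edge = tnsB.loc.end if tnsB is not None else None
    if left_edge is None or right_edge is None:
        raise ValueError("end detection needs evidence on both sides "
                         "(array/anchor/tRNA and tnsB)")
    lw0 = max(left_edge - window, 0)
    lwin = seq[lw0:left_edge]
    rw1 = min(right_edge + window, len(seq))
    rwin = seq[right_edge:rw1]
    match = _longest_ir_match(lwin, reverse_complement(rwin), min_len=tir_range[0])
    if match is not None and (match[1] - match[0]) <= tir_range[1]:
        lo_i, hi_i, lo_j, hi_j = match
        le = lw0 + lo_i
        # right_rc index j maps to genome position rw1 - 1 - j
        re = rw1 - lo_j
        return Ends(le, re, "high", hi_i - lo_i)
    # fallback: protospacer/tnsB flanks
    if anchor is not None:
        le = anchor.protospacer.end + 3  # just inside the PAM
    elif trna is not None:
        le = trna.end
    else:
        le = max(left_edge - 100, 0)
    log.warning("no TIR pair found; low-confidence ends reported")
    return Ends(le, right_edge, "low", None)


# ---------------------------------------------------------------------------
# tRNA token finder (placeholder scanner for the bundled tRNA token)


def find_trna(genome: GenomeRecord, min_identity: float = 0.65) -> Interval | None:
    token, n = TRNA_TOKEN, len(TRNA_TOKEN)
    best = None
    for strand, text in (("+", genome.seq), ("-", reverse_complement(genome.seq))):
        for i in range(len(text) - n + 1):
            ident = sum(text[i + x] == token[x] for x in range(n)) / n
            if ident >= min_identity and (best is None or ident > best[0]):
                if strand == "+":
                    iv = Interval(genome.id, i, i + n, "+")
                else:
                    iv = Interval(genome.id, len(text) - i - n, len(text) - i, "-")
                best = (ident, iv)
    return None if best is None else best[1]


# ---------------------------------------------------------------------------
# assembly


def assemble_system(genome: GenomeRecord, parts: dict) -> CastSystem:
    """Assemble detected parts into a CastSystem; validation goes to flags."""
    cas12k: Orf | None = parts.get("cas12k")
    if cas12k is None:
        raise ValueError("a CAST system is anchored on cas12k; none detected")
    flags: list[str] = []
    ends: Ends | None = parts.get("ends")
    le = ends.le if ends else None
    re_ = ends.re if ends else None
    if le is not None and re_ is not None and le >= re_:
        le, re_ = re_, le
        flags.append("ends were swapped to normalize LE < RE")

    tnsB, tnsC, tniQ = parts.get("tnsB"), parts.get("tnsC"), parts.get("tniQ")
    if re_ is not None and all(o is not None for o in (tnsB, tnsC, tniQ)):
        def d_to_re(o: Orf) -> int:
            return min(abs(re_ - o.loc.start), abs(re_ - o.loc.end))
        if not (d_to_re(tnsB) < d_to_re(tnsC) < d_to_re(tniQ)):
            flags.append("transposase order violated (expected tnsB-tnsC-tniQ from the RE)")
        away = "-" if (le is not None and le < re_ and tnsB.loc.start > cas12k.loc.start) else "+"
        if any(o.loc.strand != away for o in (tnsB, tnsC, tniQ)):
            flags.append("transposase genes do not all face away from the RE")
    else:
        missing = [n for n, o in (("tnsB", tnsB), ("tnsC", tnsC), ("tniQ", tniQ)) if o is None]
        if missing:
            flags.append(f"missing transposase genes: {','.join(missing)}")

    array: CrisprArray | None = parts.get("array")
    if array is not None and le is not None:
        array = with_orientation(array, orient_array(array, genome, {"le": le}))
        if array.orientation == "+" and le < array.loc.start:
            flags.append("array not oriented toward the LE")

    regulator: RegulatorCall | None = parts.get("regulator")
    reg_type = regulator.family if regulator else "none"

    tracr: TracrLocus | None = parts.get("tracr")
    if tracr is not None:
        flags.extend(tracr.flags)
    anchor: AnchorModule | None = parts.get("anchor")
    if anchor is not None:
        flags.extend(anchor.warnings)

    cargo = []
    if tniQ is not None:
        inner = sorted([cas12k.loc.end, cas12k.loc.start, tniQ.loc.start, tniQ.loc.end])
        lo, hi = inner[1], inner[2]
        assigned = {id(o) for o in (cas12k, tnsB, tnsC, tniQ) if o is not None}
        if regulator:
            assigned.add(id(regulator.orf))
        cargo = [o for o in parts.get("orfs", [])
                 if id(o) not in assigned and o.loc.start >= lo and o.loc.end <= hi]

    return CastSystem(
        contig=genome.id, le=le, re=re_, trna=parts.get("trna"), array=array,
        anchor=anchor, tracr=tracr, cas12k=cas12k, tnsB=tnsB, tnsC=tnsC, tniQ=tniQ,
        regulator=regulator, regulator_type=reg_type, cargo=cargo,
        ends_confidence=(ends.confidence if ends else "low"), flags=flags,
    )


# ---------------------------------------------------------------------------
# pipeline


@dataclass(frozen=True)
class AnnotateConfig:
    min_aa: int = DEFAULT_MIN_AA
    evalue_threshold: float = DEFAULT_EVALUE_THRESHOLD
    tss_tolerance_nt: int = 0
    array: ArrayParams = field(default_factory=ArrayParams)
    anchor: AnchorParams = field(default_factory=AnchorParams)
    scoring: ScoringParams = field(default_factory=ScoringParams)


def annotate(genome: GenomeRecord, tss_list: list[TssRecord] | None = None,
             cfg: AnnotateConfig | None = None) -> list[CastSystem]:
    """Run the full detection pipeline on one genome.

    Stages: six-frame ORF catalogue -> homology classification of core genes
    -> TSS-based leaderless start correction -> array detection/orientation
    -> tracrRNA -> TIR end detection -> anchor module -> regulator
    classification -> permissive assembly with validation flags.
    """
    cfg = cfg or AnnotateConfig()
    tss_list = tss_list or []
    refsets = load_reference_sets()
    orfs = find_orfs(genome, cfg.min_aa)

    core: dict[str, tuple[Orf, AlignmentHit] | None] = {g: None for g in CORE_GENES}
    for orf in orfs:
        for gene in CORE_GENES:
            hit = is_homolog(orf.protein, refsets[gene], cfg.evalue_threshold, cfg.scoring)
            if hit is not None and (core[gene] is None or hit.evalue < core[gene][1].evalue):
                core[gene] = (orf, hit)

    if core["Cas12k"] is None:
        raise ValueError("no cas12k homolog detected; cannot anchor a CAST system")

    def corrected(orf: Orf | None) -> Orf | None:
        if orf is None:
            return None
        return correct_start_from_tss(orf, tss_list, cfg.tss_tolerance_nt).corrected

    cas12k = corrected(core["Cas12k"][0])
    tnsB = corrected(core["TnsB"][0]) if core["TnsB"] else None
    tnsC = corrected(core["TnsC"][0]) if core["TnsC"] else None
    tniQ = corrected(core["TniQ"][0]) if core["TniQ"] else None

    arrays = detect_arrays(genome, cfg.array)
    array = None
    if arrays:
        array = min(arrays, key=lambda a: min(abs(a.loc.start - cas12k.loc.start),
                                              abs(a.loc.end - cas12k.loc.end)))
    tracr = locate_tracr(genome, cas12k, tss_list, array)
    trna = find_trna(genome)

    anchor = None
    ends = None
    if tnsB is not None and (array is not None or anchor is not None or trna is not None):
        try:
            ends = detect_ends(genome, trna, None, tnsB, array)
        except ValueError as exc:
            log.warning("end detection failed: %s", exc)
    if array is not None and ends is not None:
        anchor = find_anchor(genome, array, ends.le, cfg.anchor)
        if anchor is not None and ends.confidence == "low":
            ends = detect_ends(genome, trna, anchor, tnsB, array)

    corrected_orfs = [correct_start_from_tss(o, tss_list, cfg.tss_tolerance_nt).corrected
                      for o in orfs]
    regulator = classify_regulator(corrected_orfs, cas12k, refsets,
                                   cfg.evalue_threshold, params=cfg.scoring)

    system = assemble_system(genome, {
        "cas12k": cas12k, "tnsB": tnsB, "tnsC": tnsC, "tniQ": tniQ,
        "array": array, "tracr": tracr, "anchor": anchor, "ends": ends,
        "trna": trna, "regulator": regulator, "orfs": corrected_orfs,
    })
    return [system]


# ---------------------------------------------------------------------------
# reports


def _iv(iv: Interval | None) -> dict | None:
    if iv is None:
        return None
    return {"contig": iv.contig, "start": iv.start, "end": iv.end, "strand": iv.strand}


def _orf(orf: Orf | None) -> dict | None:
    if orf is None:
        return None
    return {"loc": _iv(orf.loc), "start_codon": orf.start_codon, "aa_len": len(orf.protein)}


def report(systems: list[CastSystem], meta: dict | None = None) -> dict:
    """Versioned JSON-able report; coordinates 0-based half-open; deterministic."""
    out_systems = []
    for s in systems:
        anchor = None
        if s.anchor:
            anchor = {"r_star": _iv(s.anchor.r_star),
                      "anchor_spacer": _iv(s.anchor.anchor_spacer),
                      "protospacer": _iv(s.anchor.protospacer),
                      "pam": s.anchor.pam,
                      "pam_to_le_distance": s.anchor.pam_to_le_distance,
                      "mismatches": s.anchor.mismatches}
        array = None
        if s.array:
            array = {"loc": _iv(s.array.loc), "n_repeats": len(s.array.repeats),
                     "repeats": [_iv(r) for r in s.array.repeats],
                     "consensus_repeat": s.array.consensus_repeat,
                     "orientation": s.array.orientation}
        tracr = None
        if s.tracr:
            tracr = {"loc": _iv(s.tracr.loc),
                     "tss_pos": s.tracr.tss.pos if s.tracr.tss else None,
                     "distance_from_cas12k_stop": s.tracr.distance_from_cas12k_stop,
                     "predicted": s.tracr.predicted}
        regulator = None
        if s.regulator:
            regulator = {"orf": _orf(s.regulator.orf), "family": s.regulator.family,
                         "length_ok": s.regulator.length_ok,
                         "distance_to_cas12k": s.regulator.distance_to_cas12k,
                         "evalue": s.regulator.best_hit.evalue}
        out_systems.append({
            "contig": s.contig, "le": s.le, "re": s.re,
            "ends_confidence": s.ends_confidence,
            "trna": _iv(s.trna), "array": array, "anchor": anchor, "tracr": tracr,
            "cas12k": _orf(s.cas12k), "tnsB": _orf(s.tnsB), "tnsC": _orf(s.tnsC),
            "tniQ": _orf(s.tniQ), "regulator": regulator,
            "regulator_type": s.regulator_type,
            "cargo": [_orf(o) for o in s.cargo], "flags": list(s.flags),
        })
    doc = {"schema_version": SCHEMA_VERSION, "coordinates": "0-based half-open",
           "castkit_version": __version__, "systems": out_systems}
    if meta:
        doc["run"] = meta
    return doc


def report_json(systems: list[CastSystem], meta: dict | None = None) -> str:
    return json.dumps(report(systems, meta), sort_keys=True, indent=2)


def system_features(system: CastSystem) -> list[Feature]:
    """GFF3 feature dump of one assembled system."""
    feats: list[Feature] = []

    def add(iv: Interval | None, ftype: str, **attrs):
        if iv is not None:
            feats.append(make_feature(iv, ftype, **attrs))

    add(system.trna, "tRNA")
    if system.array:
        add(system.array.loc, "CRISPR_array", orientation=system.array.orientation)
        for r in system.array.repeats:
            add(r, "direct_repeat")
        for sp in system.array.spacers:
            add(sp, "CRISPR_spacer")
    if system.anchor:
        add(system.anchor.r_star, "truncated_repeat")
        add(system.anchor.anchor_spacer, "anchor_spacer")
        add(system.anchor.protospacer, "protospacer", pam=system.anchor.pam)
    if system.tracr:
        add(system.tracr.loc, "tracrRNA", predicted=str(system.tracr.predicted).lower())
    for name, orf in (("cas12k", system.cas12k), ("tnsB", system.tnsB),
                      ("tnsC", system.tnsC), ("tniQ", system.tniQ)):
        if orf:
            add(orf.loc, "CDS", gene=name)
    if system.regulator:
        add(system.regulator.orf.loc, "CDS", gene="regulator",
            family=system.regulator.family)
    for i, orf in enumerate(system.cargo, 1):
        add(orf.loc, "CDS", gene=f"cargo{i}")
    return feats
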