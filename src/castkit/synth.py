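"""Ground-truth synthetic genome generator emulating the canonical type V-K
CAST locus architecture.

A generated contig carries, left to right on the LE->RE axis: a tRNA token
containing the anchor protospacer with its GTN PAM (PAM-to-LE distance drawn
from the observed 46-82 nt band), the left-end terminal inverted repeat, the
anchor spacer (17 nt) next to the truncated repeat R* (12 nt), the CRISPR
array (37-nt repeats, reverse orientation), the tracrRNA region whose TSS
lies 35 nt downstream of the cas12k stop and 413 nt upstream of the first
repeat, the divergent leaderless cvkR/cas12k pair (82 nt between corrected
start codons), cargo genes, tniQ-tnsC-tnsB reading away from the right end,
and the right-end TIR -- all embedded in random background at cyanobacterial
GC content.

Planted boundaries are made *well defined*: the random bases flanking each
repeat unit and TIR are resampled so that no flanking alignment column
reaches the detector's column-identity threshold, which makes the planted
interval the unique maximal extension.  Protein-coding placeholders are
seeded, diverged copies of the bundled synthetic reference proteins so that
the homology stage recognises them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .refdata import TRNA_TOKEN, load_reference_sets, REGULATOR_FAMILIES
from .seqio import (Feature, GenomeRecord, Interval, TssRecord, make_feature,
                    reverse_complement)

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_STARTS = {"ATG", "TTG", "GTG"}
_MINUS_STOP_TRIPLETS = {"TTA", "CTA", "TCA"}  # plus-strand text whose revcomp is a stop

# codon choices per residue (bacterial table 11)
_TABLE = unambiguous_dna_by_id[11]
_CODONS: dict[str, list[str]] = {}
for codon, aa in sorted(_TABLE.forward_table.items()):
    _CODONS.setdefault(aa, []).append(codon)
_CODONS["M"] = ["ATG"]

# Divergent-gap template (82 nt between the corrected cas12k and cvkR start
# codons).  Fixed positions carry the cas12k -10/-35 boxes (21-nt spacer), the
# planted CvkR operator instance, the plus-strand stop bounding the cvkR
# leader and the minus-strand stop bounding the cas12k leader; '.' positions
# are random subject to the reading-frame constraints encoded in
# _fill_divergent_gap.
_CVKR_SITE = "ATAACATTATGTGTT"
_GAP_LEN = 82


@dataclass(frozen=True)
class CastParams:
    """Generator parameters; defaults are the canonical architecture quantities."""

    repeat_len: int = 37
    n_repeats: int = 4
    spacer_len: int = 35
    anchor_spacer_len: int = 17
    r_star_len: int = 12
    pam_to_le: int | None = None                 # None: draw uniform from range
    pam_to_le_range: tuple[int, int] = (46, 82)
    tracr_tss_offset: int = 35
    tss_to_array: int = 413
    divergent_gap: int = _GAP_LEN
    regulator_family: str = "CvkR"               # CvkR, Arc_1, Arc_2 or "none"
    regulator_len_aa: int | None = None          # None: family-conditional draw
    cargo_n: int = 2
    tir_len: int = 25
    background_len: int = 12000
    gc: float = 0.41
    mutation_rate: float = 0.0
    protein_divergence: float = 0.10
    plant_motif: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("repeat_len", "n_repeats", "spacer_len", "anchor_spacer_len",
                     "r_star_len", "tracr_tss_offset", "tss_to_array", "tir_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.regulator_family not in REGULATOR_FAMILIES + ("none",):
            raise ValueError(f"unknown regulator family {self.regulator_family!r}")
        if self.pam_to_le is not None and self.pam_to_le < 0:
            raise ValueError("pam_to_le must be >= 0")
        if self.tss_to_array <= self.tracr_tss_offset:
            raise ValueError("tss_to_array must exceed tracr_tss_offset "
                             "(the tracr locus lies between TSS and array)")
        if self.divergent_gap != _GAP_LEN:
            raise ValueError("divergent_gap is fixed at 82 nt by the promoter template")
        if not 0 <= self.mutation_rate < 0.1:
            raise ValueError("mutation_rate must be in [0, 0.1)")
        if self.background_len < 400:
            raise ValueError("background_len must be >= 400")


@dataclass
class TruthSet:
    """Every planted element plus the TSS map, as the detector should recover them."""

    features: list[Feature]
    tss_table: list[TssRecord]
    meta: dict = field(default_factory=dict)


def _rand_seq(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return list(rng.choice(_BASES, size=n, p=p))


def _rand_codon(rng: np.random.Generator, avoid: set[str]) -> str:
    while True:
        codon = "".join(rng.choice(_BASES, size=3))
        if codon not in avoid:
            return codon


def _mutate_protein(rng: np.random.Generator, protein: str, divergence: float) -> str:
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    s = list(protein)
    n_mut = int(round(divergence * (len(s) - 1)))
    idx = rng.choice(np.arange(1, len(s)), size=n_mut, replace=False)
    for i in idx:
        choices = [a for a in aa if a != s[i]]
        s[i] = choices[rng.integers(len(choices))]
    return "".join(s)


def _encode_protein(rng: np.random.Generator, protein: str) -> str:
    """Reverse-translate with random synonymous codons plus a stop."""
    cds = "".join(_CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in protein)
    return cds + ["TAA", "TAG", "TGA"][rng.integers(3)]


def _fill_divergent_gap(rng: np.random.Generator, site: str) -> str:
    """The 82-nt gap between the corrected cas12k (left, minus strand) and
    cvkR (right, plus strand) start codons.

    Layout (gap index 0 at the cas12k gene end): cas12k -10 box at [6,12)
    (minus text TATATT), plus-strand stop TAA at [10,13) bounding the cvkR
    leader, operator instance at [14,29), -35 box at [33,39) (minus text
    TTGTAT; 21-nt -10/-35 spacer containing the operator), minus-strand stop
    at [39,42) bounding the cas12k leader at 13 codons.  The cvkR leader is
    20 codons (annotated start = the ATG inside the operator instance).
    Free positions are drawn subject to both reading frames staying open.
    """
    g = ["."] * _GAP_LEN
    g[6:12] = "AATATA"           # revcomp(TATATT): cas12k -10
    g[12] = "A"                  # completes plus-strand stop TAA at [10,13)
    g[13] = "T"
    g[14:29] = site              # operator instance (15 nt)
    g[29:31] = "TG"              # with g[28]='T': plus codon TTG at [28,31)
    g[33:39] = "ATACAA"          # revcomp(TTGTAT): cas12k -35
    g[39:42] = "TTA"             # minus-strand stop bounding the cas12k leader
    # free minus-strand leader codons at [0,3) and [3,6): must not be stops
    for lo in (0, 3):
        g[lo : lo + 3] = _rand_codon(rng, _MINUS_STOP_TRIPLETS)
    # g[31],g[32]: plus codon [31,34) is (g31,g32,'A'); avoid TAA/TGA
    while True:
        pair = "".join(rng.choice(_BASES, size=2))
        if pair not in ("TA", "TG"):
            g[31], g[32] = pair[0], pair[1]
            break
    g[42] = "CT"[rng.integers(2)]        # plus codon [40,43) = 'TA'+x: avoid stop
    for lo in range(43, _GAP_LEN, 3):    # remaining plus-frame codons: non-stop
        g[lo : lo + 3] = _rand_codon(rng, _STOPS)
    assert "." not in g
    return "".join(g)


def _fill_tnsb_promoter(rng: np.random.Generator, length: int, site: str,
                        gc: float, plant: bool) -> tuple[str, int]:
    """Gap between the tnsB gene end and the RE TIR, carrying the tnsB promoter.

    Returns (plus text, TSS offset within the gap).  The tnsB TSS sits 30 nt
    into the gap (minus strand); the -10/-35 pair has a 17-nt spacer and the
    operator instance overlaps the TSS, mirroring the P_tnsB arrangement.
    """
    h = _rand_seq(rng, length, gc)
    h[0:3] = "TTA"               # minus-strand stop guarding the tnsB start
    if plant:
        h[21:36] = site          # operator overlapping the TSS at offset 29
    h[36:42] = "ATTATA"          # revcomp(TATAAT): -10, 6 nt upstream of TSS
    h[59:65] = "TGTCAA"          # revcomp(TTGACA): -35, 17-nt spacer
    return "".join(h), 29


class _Assembler:
    def __init__(self, contig: str):
        self.contig = contig
        self.chars: list[str] = []
        self.features: list[Feature] = []

    @property
    def pos(self) -> int:
        return len(self.chars)

    def add(self, text: str | list[str]) -> int:
        start = self.pos
        self.chars.extend(text)
        return start

    def feature(self, start: int, end: int, strand: str, ftype: str, **attrs) -> Interval:
        iv = Interval(self.contig, start, end, strand)
        self.features.append(make_feature(iv, ftype, source="castkit-synth", **attrs))
        return iv


def generate_cast_genome(params: CastParams | None = None) -> tuple[GenomeRecord, TruthSet]:
    """Emit one synthetic CAST genome plus its ground truth; same seed, same bytes."""
    p = params or CastParams()
    rng = np.random.default_rng(p.seed)
    contig = f"synthetic_cast_{p.seed}"
    refs = load_reference_sets()
    asm = _Assembler(contig)
    tss_table: list[TssRecord] = []
    meta: dict = {"params": asdict(p)}

    pam_to_le = p.pam_to_le if p.pam_to_le is not None else int(
        rng.integers(p.pam_to_le_range[0], p.pam_to_le_range[1] + 1))
    pam = "GT" + "ACGT"[rng.integers(4)]
    anchor_spacer_seq = "".join(_rand_seq(rng, p.anchor_spacer_len, p.gc))
    repeat = "".join(_rand_seq(rng, p.repeat_len, p.gc))
    tir = "".join(_rand_seq(rng, p.tir_len, p.gc))
    site = _CVKR_SITE

    # --- left flank with tRNA token; protospacer+PAM written in afterwards
    flank = max(p.background_len // 2, 200)
    asm.add(_rand_seq(rng, flank - len(TRNA_TOKEN), p.gc))
    trna_start = asm.add(TRNA_TOKEN)
    trna = asm.feature(trna_start, asm.pos, "+", "tRNA", note="canonical placeholder token")
    le = asm.pos

    le_tir_start = asm.add(tir)
    asm.feature(le_tir_start, asm.pos, "+", "terminal_inverted_repeat", side="LE")
    asm.add(_rand_seq(rng, 20, p.gc))                      # LE-to-anchor gap
    sp_start = asm.add(anchor_spacer_seq)
    anchor_spacer = asm.feature(sp_start, asm.pos, "-", "anchor_spacer")
    rs_start = asm.add(repeat[: p.r_star_len])             # truncated repeat R*
    r_star = asm.feature(rs_start, asm.pos, "-", "truncated_repeat", name="R*")
    asm.add(_rand_seq(rng, 60, p.gc))                      # clear separation from the array

    # --- CRISPR array: n repeats, n-1 random spacers (reverse orientation)
    unit_starts = []
    array_spacers = []
    for i in range(p.n_repeats):
        unit_starts.append(asm.add(repeat))
        if i < p.n_repeats - 1:
            s0 = asm.add(_rand_seq(rng, p.spacer_len, p.gc))
            array_spacers.append((s0, s0 + p.spacer_len))
    array_start, array_end = unit_starts[0], asm.pos
    array_iv = asm.feature(array_start, array_end, "-", "CRISPR_array",
                           n_repeats=str(p.n_repeats))
    for u in unit_starts:
        asm.feature(u, u + p.repeat_len, "-", "direct_repeat")
    for s0, s1 in array_spacers:
        asm.feature(s0, s1, "-", "CRISPR_spacer")

    # --- tracr region: TSS tss_to_array-1 nt right of the array, cas12k
    #     tracr_tss_offset further right (both distances use the convention
    #     "first nucleotide past the boundary = position 1")
    asm.add(_rand_seq(rng, p.tss_to_array - 1, p.gc))
    tracr_tss_pos0 = asm.pos  # the TSS nucleotide itself is the next base
    tss_table.append(TssRecord(contig, tracr_tss_pos0 + 1, "-", "tracrRNA"))
    asm.add(_rand_seq(rng, p.tracr_tss_offset, p.gc))
    tracr_iv = asm.feature(array_end, tracr_tss_pos0 + 1, "-", "tracrRNA")

    # --- cas12k (minus strand, leaderless, 13-codon annotated 5' extension)
    cas_ref = refs["Cas12k"][0][1]
    cas_protein = _mutate_protein(rng, cas_ref, p.protein_divergence)
    g0 = asm.add(reverse_complement(_encode_protein(rng, cas_protein)))
    g1 = asm.pos
    cas12k_iv = asm.feature(g0, g1, "-", "CDS", gene="cas12k")
    tss_table.append(TssRecord(contig, g1, "-", "cas12k"))  # 1-based pos of plus g1-1

    # --- divergent gap (promoter boxes, operator, both leaders)
    gap = _fill_divergent_gap(rng, site)
    gap_start = asm.add(gap)
    cas12k_annot = Interval(contig, g0, gap_start + 39, "-")  # +13 codons
    asm.feature(cas12k_annot.start, cas12k_annot.end, "-", "CDS_annotated", gene="cas12k")
    if p.plant_motif:
        asm.feature(gap_start + 14, gap_start + 29, "+", "CvkR_binding_site",
                    promoter="cas12k")
    meta["cas12k"] = {"corrected": cas12k_iv, "annotated": cas12k_annot,
                      "aa_len": len(cas_protein), "leader_codons": 13}
    meta["tracr"] = {"tss_pos0": tracr_tss_pos0, "distance": p.tracr_tss_offset,
                     "tss_to_array": p.tss_to_array, "loc": tracr_iv}

    # --- regulator (plus strand, divergent, leaderless; 20-codon annotated leader)
    c0 = asm.pos
    regulator = None
    if p.regulator_family != "none":
        fam = p.regulator_family
        lo, hi = (139, 185) if fam == "CvkR" else (53, 72)
        reg_len = p.regulator_len_aa or int(rng.integers(lo, hi + 1))
        reg_ref = refs[fam][0][1][:reg_len]
        reg_protein = _mutate_protein(rng, reg_ref, p.protein_divergence)
        asm.add(_encode_protein(rng, reg_protein))
        reg_iv = asm.feature(c0, asm.pos, "+", "CDS", gene="regulator", family=fam)
        reg_annot = Interval(contig, gap_start + 22, asm.pos, "+")
        asm.feature(reg_annot.start, reg_annot.end, "+", "CDS_annotated", gene="regulator")
        tss_table.append(TssRecord(contig, c0 + 1, "+", "regulator"))
        regulator = {"corrected": reg_iv, "annotated": reg_annot, "family": fam,
                     "aa_len": len(reg_protein), "leader_codons": 20,
                     "distance_to_cas12k": c0 - g1}
    meta["regulator"] = regulator

    # --- cargo genes between the regulator and tniQ
    asm.add(_rand_seq(rng, 60, p.gc))
    cargo = []
    for i in range(p.cargo_n):
        prot = "M" + "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"),
                                        size=int(rng.integers(100, 180))))
        strand = "+-"[rng.integers(2)]
        if strand == "+":
            asm.add("TAA")       # upstream stop guard
            s0 = asm.add(_encode_protein(rng, prot))
            cargo.append(asm.feature(s0, asm.pos, "+", "CDS", gene=f"cargo{i + 1}"))
        else:
            s0 = asm.add(reverse_complement(_encode_protein(rng, prot)))
            cargo.append(asm.feature(s0, asm.pos, "-", "CDS", gene=f"cargo{i + 1}"))
            asm.add("TTA")       # upstream (minus) stop guard
        asm.add(_rand_seq(rng, 40, p.gc))
    meta["cargo"] = cargo

    # --- tniQ, tnsC, tnsB (minus strand; tnsB closest to the RE)
    tns = {}
    for gene in ("TniQ", "TnsC", "TnsB"):
        prot = _mutate_protein(rng, refs[gene][0][1], p.protein_divergence)
        s0 = asm.add(reverse_complement(_encode_protein(rng, prot)))
        tns[gene.lower()] = asm.feature(s0, asm.pos, "-", "CDS", gene=gene.lower())
        if gene != "TnsB":
            asm.add("TTA")       # upstream stop guard lives in the intergenic gap
            asm.add(_rand_seq(rng, 40, p.gc))
    meta.update(tns)

    # --- tnsB promoter gap, then RE TIR and right flank
    h, tss_off = _fill_tnsb_promoter(rng, 120, site, p.gc, p.plant_motif)
    h_start = asm.add(h)
    tss_table.append(TssRecord(contig, h_start + tss_off + 1, "-", "tnsB"))
    if p.plant_motif:
        asm.feature(h_start + 21, h_start + 36, "+", "CvkR_binding_site", promoter="tnsB")
    re_tir_start = asm.add(reverse_complement(tir))
    re_end = asm.pos
    asm.feature(re_tir_start, re_end, "+", "terminal_inverted_repeat", side="RE")
    asm.add(_rand_seq(rng, max(p.background_len - flank, 200), p.gc))

    seq = asm.chars

    # --- protospacer + PAM outside the LE (PAM read toward the LE)
    pam_end = le - pam_to_le
    proto_start = pam_end - 3 - p.anchor_spacer_len
    seq[proto_start : proto_start + p.anchor_spacer_len] = anchor_spacer_seq
    seq[pam_end - 3 : pam_end] = reverse_complement(pam)
    proto_iv = asm.feature(proto_start, proto_start + p.anchor_spacer_len, "-",
                           "anchor_protospacer")
    asm.feature(pam_end - 3, pam_end, "-", "PAM", sequence=pam)
    meta["anchor"] = {"r_star": r_star, "anchor_spacer": anchor_spacer,
                      "protospacer": proto_iv, "pam": pam, "pam_to_le": pam_to_le}
    meta["le"], meta["re"] = le, re_end
    meta["trna"] = trna
    meta["array"] = {"loc": array_iv, "repeat_starts": unit_starts,
                     "repeat_len": p.repeat_len, "consensus": repeat}

    _apply_boundary_guards(rng, seq, unit_starts, p.repeat_len, le, le + p.tir_len,
                           re_tir_start, re_end)

    genome = GenomeRecord(contig, "".join(seq))
    truth = TruthSet(asm.features, tss_table, meta)
    if p.mutation_rate > 0:
        genome = mutate_genome(genome, p.mutation_rate, int(rng.integers(2**31)))
    return genome, truth


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _apply_boundary_guards(rng, seq: list[str], unit_starts: list[int], rep_len: int,
                           le: int, le_tir_end: int, re_tir_start: int, re_end: int) -> None:
    """Resample free bases adjacent to planted boundaries so the planted
    intervals are the unique maximal extensions (truth well-definedness)."""
    n = len(unit_starts)
    max_top = max(int(np.ceil(0.75 * n)) - 1, 1)
    for offset in (-1, rep_len):
        cols = [u + offset for u in unit_starts]
        free = [c for c in cols if _is_free_array_flank(c, unit_starts, rep_len)]
        guard = 0
        while guard < 100:
            bases = [seq[c] for c in cols]
            top = max(bases.count(b) for b in "ACGT")
            if top <= max_top:
                break
            c = free[rng.integers(len(free))]
            seq[c] = "ACGT"[rng.integers(4)]
            guard += 1
    # TIR guards: flanking bases must not extend the inverted-repeat match
    for a, b in (((le - 1), re_end), (le_tir_end, re_tir_start - 1)):
        while seq[b] == _COMPLEMENT[seq[a]]:
            # one side of each pair is free random fill; prefer the right side
            seq[b] = "ACGT"[rng.integers(4)]


def _is_free_array_flank(pos: int, unit_starts: list[int], rep_len: int) -> bool:
    return all(not (u <= pos < u + rep_len) for u in unit_starts)


def mutate_genome(genome: GenomeRecord, rate: float, seed: int) -> GenomeRecord:
    """I.i.d. point substitutions at the given per-site rate (no indels)."""
    if not 0 <= rate < 0.1:
        raise ValueError("rate must be in [0, 0.1)")
    if rate == 0:
        return genome
    rng = np.random.default_rng(seed)
    seq = list(genome.seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != seq[i]]
        seq[i] = choices[rng.integers(3)]
    return GenomeRecord(genome.id, "".join(seq), genome.circular)
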