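"""ORF cataloguing, TSS-based leaderless start correction, protein mass utility.

ORFs are called on both strands with the alternative bacterial start codons
ATG, TTG and GTG.  Per stop codon and reading frame the primary ORF uses the
5'-most allowed start (longest product); internal in-frame starts are kept so
that :func:`correct_start_from_tss` can re-initiate at one of them when a
mapped transcription start site coincides with its first nucleotide -- the
signature of a leaderless mRNA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio.Seq import Seq
from Bio.SeqUtils import molecular_weight

from .seqio import GenomeRecord, Interval, TssRecord, reverse_complement

log = logging.getLogger("castkit")

START_CODONS = ("ATG", "TTG", "GTG")
STOP_CODONS = ("TAA", "TAG", "TGA")
DEFAULT_MIN_AA = 50


@dataclass(frozen=True)
class Orf:
    """A located open reading frame.

    ``loc`` spans start codon through stop codon (half-open).  ``protein``
    follows the initiator-Met convention: the first residue is reported as M
    regardless of whether the start codon is ATG, TTG or GTG.  ``alt_starts``
    lists internal in-frame alternative starts as (offset_codons, codon).
    """

    loc: Interval
    start_codon: str
    protein: str
    frame_len_codons: int
    alt_starts: tuple[tuple[int, str], ...] = ()

    def __post_init__(self):
        if len(self.protein) != len(self.loc) // 3 - 1:
            raise ValueError("protein length inconsistent with interval")

    def first_codon_pos0(self) -> int:
        """0-based genomic position of the first nucleotide of the start codon."""
        return self.loc.start if self.loc.strand == "+" else self.loc.end - 1

    def start_pos0_of_codon(self, offset_codons: int) -> int:
        """0-based genomic position of the first nucleotide of codon ``offset_codons`` (0-based)."""
        if self.loc.strand == "+":
            return self.loc.start + 3 * offset_codons
        return self.loc.end - 1 - 3 * offset_codons


@dataclass(frozen=True)
class StartCorrection:
    original: Orf
    corrected: Orf
    tss: TssRecord | None
    offset_codons: int
    leaderless: bool


def _translate(cds: str) -> str:
    protein = str(Seq(cds).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    return "M" + protein[1:]


def _scan_strand(seq: str, contig: str, strand: str, min_aa: int, starts: tuple[str, ...],
                 genome_len: int) -> list[Orf]:
    """Scan the three frames of one strand (seq is already the reading-strand text)."""
    orfs = []
    n = len(seq)
    for frame in range(3):
        starts_in_segment: list[int] = []
        i = frame
        while i + 3 <= n:
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                if starts_in_segment:
                    s0 = starts_in_segment[0]
                    aa_len = (i - s0) // 3
                    if aa_len >= min_aa:
                        cds = seq[s0 : i + 3]
                        if strand == "+":
                            loc = Interval(contig, s0, i + 3, "+")
                        else:
                            loc = Interval(contig, genome_len - (i + 3), genome_len - s0, "-")
                        alt = tuple(((p - s0) // 3, seq[p : p + 3])
                                    for p in starts_in_segment[1:])
                        orfs.append(Orf(loc, seq[s0 : s0 + 3], _translate(cds), aa_len + 1, alt))
                starts_in_segment = []
            elif codon in starts:
                starts_in_segment.append(i)
            i += 3
        # segments truncated at the contig end (no stop codon) are not reported
    return orfs


def find_orfs(genome: GenomeRecord, min_aa: int = DEFAULT_MIN_AA,
              starts: tuple[str, ...] = START_CODONS) -> list[Orf]:
    """Six-frame ORF scan; one primary ORF per (stop codon, frame), longest product first.

    Deterministic order: (start, end, strand).
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    if not set(starts) <= set(START_CODONS):
        raise ValueError(f"starts must be a subset of {START_CODONS}")
    n = len(genome.seq)
    orfs = _scan_strand(genome.seq, genome.id, "+", min_aa, starts, n)
    orfs += _scan_strand(reverse_complement(genome.seq), genome.id, "-", min_aa, starts, n)
    return sorted(orfs, key=lambda o: (o.loc.start, o.loc.end, o.loc.strand))


def correct_start_from_tss(orf: Orf, tss_list: list[TssRecord],
                           tolerance_nt: int = 0) -> StartCorrection:
    """Re-initiate an ORF at an in-frame start whose first nucleotide matches a TSS.

    If a same-contig, same-strand TSS coincides (within ``tolerance_nt``,
    default exact) with the first nucleotide of an in-frame start codon at or
    downstream of the annotated start, the ORF is corrected to begin there and
    flagged leaderless.  The 5'-most qualifying start wins (longest corrected
    product).  Otherwise the ORF is returned unchanged.
    """
    candidates = [(0, orf.start_codon)] + list(orf.alt_starts)
    relevant = [t for t in tss_list if t.contig == orf.loc.contig and t.strand == orf.loc.strand]
    for t in relevant:
        # a TSS downstream of the stop codon can never correct this ORF
        past = (t.pos0 >= orf.loc.end) if orf.loc.strand == "+" else (t.pos0 < orf.loc.start)
        if past:
            log.debug("TSS %s:%d(%s) lies downstream of ORF stop; ignored",
                      t.contig, t.pos, t.strand)
    best: tuple[int, str] | None = None
    for offset, codon in sorted(candidates):
        pos0 = orf.start_pos0_of_codon(offset)
        if any(abs(t.pos0 - pos0) <= tolerance_nt for t in relevant):
            best = (offset, codon)
            break  # 5'-most qualifying start
    if best is None or best[0] < 0:
        return StartCorrection(orf, orf, None, 0, False)
    offset, codon = best
    tss = min((t for t in relevant
               if abs(t.pos0 - orf.start_pos0_of_codon(offset)) <= tolerance_nt),
              key=lambda t: abs(t.pos0 - orf.start_pos0_of_codon(offset)))
    if offset == 0:
        return StartCorrection(orf, orf, tss, 0, True)
    if orf.loc.strand == "+":
        loc = Interval(orf.loc.contig, orf.loc.start + 3 * offset, orf.loc.end, "+")
    else:
        loc = Interval(orf.loc.contig, orf.loc.start, orf.loc.end - 3 * offset, "-")
    protein = "M" + orf.protein[offset + 1 :]
    alt = tuple((o - offset, c) for o, c in orf.alt_starts if o > offset)
    corrected = Orf(loc, codon, protein, orf.frame_len_codons - offset, alt)
    return StartCorrection(orf, corrected, tss, offset, True)


def protein_mass(protein: str, kda: bool = True) -> float:
    """Average (isotope-averaged) molecular mass of a protein; kDa to 2 decimals."""
    if not protein:
        raise ValueError("empty protein sequence")
    if set(protein) - set("ACDEFGHIKLMNPQRSTVWY"):
        bad = sorted(set(protein) - set("ACDEFGHIKLMNPQRSTVWY"))
        raise ValueError(f"unknown residue characters: {bad}")
    mass_da = molecular_weight(protein, seq_type="protein")
    return round(mass_da / 1000.0, 2) if kda else mass_da


def corrections_table(corrections: list[StartCorrection]) -> str:
    """TSV export: orf id, original aa len, corrected aa len, tss pos, leaderless flag."""
    lines = ["#orf\toriginal_aa\tcorrected_aa\ttss_pos\tleaderless"]
    for c in corrections:
        o = c.original
        orf_id = f"{o.loc.contig}:{o.loc.start}-{o.loc.end}:{o.loc.strand}"
        tss = c.tss.pos if c.tss else "."
        lines.append(f"{orf_id}\t{len(o.protein)}\t{len(c.corrected.protein)}\t{tss}\t"
                     f"{str(c.leaderless).lower()}")
    return "\n".join(lines) + "\n"
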