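"""Pairwise local protein alignment with Karlin-Altschul-style score statistics.

Used to detect Cas12k, TnsB/TnsC/TniQ and regulator (CvkR/Arc) homologs by
similarity to bundled reference sets, with the classification threshold
expressed as a BLAST-like e-value (default cutoff 1e-20).  Alignment is
optimal Smith-Waterman under affine gap costs (a gap of length L costs
gap_open + L * gap_extend, BLAST convention); no heuristic seeding is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# Gapped BLOSUM62 (open 11 / extend 1) calibration constants.
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041
DEFAULT_EVALUE_THRESHOLD = 1e-20


@dataclass(frozen=True)
class ScoringParams:
    """Substitution matrix, affine gap penalties and e-value calibration constants."""

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = DEFAULT_LAMBDA
    K: float = DEFAULT_K

    def __post_init__(self):
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")

    @property
    def matrix(self):
        return _load_matrix(self.matrix_name)


@lru_cache(maxsize=4)
def _load_matrix(name: str):
    return substitution_matrices.load(name)


@lru_cache(maxsize=8)
def _aligner(matrix_name: str, gap_open: int, gap_extend: int) -> PairwiseAligner:
    aligner = PairwiseAligner(mode="local")
    aligner.substitution_matrix = _load_matrix(matrix_name)
    # BLAST convention: a gap of length L costs open + L * extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    target_id: str
    raw_score: int
    bit_score: float
    evalue: float
    query_span: tuple[int, int] = (0, 0)
    target_span: tuple[int, int] = (0, 0)


def _check_protein(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name} sequence is empty")
    bad = set(seq) - set(AA_ALPHABET)
    if bad:
        raise ValueError(f"{name} contains residues outside the 20-letter alphabet: {sorted(bad)}")


def sw_score(a: str, b: str, params: ScoringParams | None = None) -> int:
    """Optimal Smith-Waterman score (affine gaps); floored at zero."""
    params = params or ScoringParams()
    _check_protein(a, "query")
    _check_protein(b, "target")
    score = _aligner(params.matrix_name, params.gap_open, params.gap_extend).score(a, b)
    return max(int(round(score)), 0)


def local_align(a: str, b: str, params: ScoringParams | None = None,
                query_id: str = "query", target_id: str = "target") -> AlignmentHit:
    """Optimal local alignment of two proteins with traceback spans.

    Ties between co-optimal alignments are broken deterministically (the
    aligner's first reported traceback).  An all-negative comparison yields a
    zero score with empty spans.
    """
    params = params or ScoringParams()
    score = sw_score(a, b, params)
    if score == 0:
        return AlignmentHit(query_id, target_id, 0, bit_score(0, params), math.inf)
    aln = _aligner(params.matrix_name, params.gap_open, params.gap_extend).align(a, b)[0]
    qblocks, tblocks = aln.aligned
    qspan = (int(qblocks[0][0]), int(qblocks[-1][1]))
    tspan = (int(tblocks[0][0]), int(tblocks[-1][1]))
    e = evalue(score, len(a), len(b), params)
    return AlignmentHit(query_id, target_id, score, bit_score(score, params), e, qspan, tspan)


def bit_score(raw_score: int, params: ScoringParams | None = None) -> float:
    params = params or ScoringParams()
    return (params.lam * raw_score - math.log(params.K)) / math.log(2)


def evalue(raw_score: int, m: int, n: int, params: ScoringParams | None = None) -> float:
    """Expected number of chance hits: E = K * m * n * exp(-lambda * S)."""
    params = params or ScoringParams()
    if m < 1 or n < 1:
        raise ValueError("sequence/database lengths must be >= 1")
    return params.K * m * n * math.exp(-params.lam * raw_score)


def is_homolog(query: str, refs: list[tuple[str, str]],
               threshold: float = DEFAULT_EVALUE_THRESHOLD,
               params: ScoringParams | None = None,
               query_id: str = "query") -> AlignmentHit | None:
    """Best reference hit if its e-value passes the threshold, else None.

    The database length n is the total number of residues in the reference
    set.  Deterministic: ties on raw score go to the earlier reference.
    """
    if not refs:
        raise ValueError("reference set is empty")
    params = params or ScoringParams()
    n_db = sum(len(seq) for _, seq in refs)
    best_id, best_seq, best_score = None, None, -1
    for ref_id, ref_seq in refs:
        s = sw_score(query, ref_seq, params)
        if s > best_score:
            best_id, best_seq, best_score = ref_id, ref_seq, s
    e = evalue(best_score, len(query), n_db, params)
    if e > threshold:
        return None
    hit = local_align(query, best_seq, params, query_id=query_id, target_id=best_id)
    # the reported e-value uses the database length, not the single target
    return AlignmentHit(hit.query_id, hit.target_id, hit.raw_score, hit.bit_score,
                        e, hit.query_span, hit.target_span)


def hits_table(hits: list[AlignmentHit]) -> str:
    """BLAST-tabular-like TSV: query, target, raw, bits, evalue, spans."""
    lines = ["#query\ttarget\traw_score\tbit_score\tevalue\tquery_span\ttarget_span"]
    for h in hits:
        lines.append(f"{h.query_id}\t{h.target_id}\t{h.raw_score}\t{h.bit_score:.1f}\t"
                     f"{h.evalue:.3g}\t{h.query_span[0]}-{h.query_span[1]}\t"
                     f"{h.target_span[0]}-{h.target_span[1]}")
    return "\n".join(lines) + "\n"
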