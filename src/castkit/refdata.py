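"""Bundled reference sequence sets for homology-based classification.

The shipped protein reference FASTA is a deterministic SYNTHETIC stand-in for
curated CAST protein families: each family (Cas12k, TnsB, TnsC, TniQ, CvkR,
Arc_1, Arc_2) is a seeded random base sequence of realistic length plus
diverged variants.  They exercise the similarity/e-value machinery and anchor
the synthetic-genome generator; they are not biological sequences.

The tRNA token below plays the same role on the nucleotide side: a fixed
72-nt placeholder with tRNA-like length that the generator plants and the
annotator recognises; no covariance-model realism is claimed.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

from .seqio import read_protein_fasta

FAMILIES = ("Cas12k", "TnsB", "TnsC", "TniQ", "CvkR", "Arc_1", "Arc_2")
CORE_GENES = ("Cas12k", "TnsB", "TnsC", "TniQ")
REGULATOR_FAMILIES = ("CvkR", "Arc_1", "Arc_2")

# Observed length bands (aa) used for the regulator length_ok check.
REGULATOR_LENGTH_RANGES = {"CvkR": (139, 185), "Arc_1": (53, 72), "Arc_2": (53, 72)}

# Fixed 72-nt tRNA-like placeholder (cloverleaf realism not claimed).
TRNA_TOKEN = (
    "GGGCCCGTAGCTCAGTTGGTAGAGCGCCTGCTTTGCAAGCAGGAGGTCGCGGGTTCGAATCCCGTCGGGTCC"
)


@lru_cache(maxsize=1)
def load_reference_sets() -> dict[str, list[tuple[str, str]]]:
    """Family name -> list of (record id, protein sequence)."""
    path = resources.files("castkit") / "data" / "synthetic_refs.faa"
    with resources.as_file(path) as p:
        records = read_protein_fasta(p)
    sets: dict[str, list[tuple[str, str]]] = {f: [] for f in FAMILIES}
    for rec_id, seq in records:
        family = rec_id.split("|", 1)[0]
        if family not in sets:
            raise ValueError(f"unknown family prefix in reference id {rec_id!r}")
        sets[family].append((rec_id, seq))
    for family, members in sets.items():
        if not members:
            raise ValueError(f"reference set for {family} is empty")
    return sets
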