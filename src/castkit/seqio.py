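"""Readers and writers for external formats, and the single source of coordinate conventions.

All coordinates are 0-based half-open internally.  Every exported format that
uses 1-based inclusive coordinates (GFF3, TSS tables) goes through
:func:`to_one_based` / :func:`from_one_based` so there is exactly one place
where the conversion happens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger("castkit")

_DNA = set("ACGTN")
_IUPAC_EXTRA = set("RYSWKMBDHV")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return str(Seq(seq).reverse_complement())


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive (GFF3 columns 4/5)."""
    return start + 1, end


def from_one_based(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start1 - 1, end1


@dataclass(frozen=True)
class GenomeRecord:
    """A named nucleotide sequence with a circularity flag."""

    id: str
    seq: str
    circular: bool = False

    def __post_init__(self):
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid sequence id {self.id!r}")
        seq = self.seq.upper()
        if set(seq) - _DNA:
            bad = set(seq) - _DNA
            if bad - _IUPAC_EXTRA:
                raise ValueError(f"non-nucleotide characters in {self.id}: {sorted(bad - _IUPAC_EXTRA)}")
            log.warning("mapping ambiguity characters %s to N in %s", sorted(bad), self.id)
            seq = "".join(c if c in _DNA else "N" for c in seq)
        object.__setattr__(self, "seq", seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval with strand."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def shift(self, offset: int) -> "Interval":
        return Interval(self.contig, self.start + offset, self.end + offset, self.strand)


@dataclass(frozen=True)
class TssRecord:
    """A transcription start site: 1-based position of the first transcribed nucleotide."""

    contig: str
    pos: int
    strand: str
    label: str = ""

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"TSS positions are 1-based; got {self.pos}")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def pos0(self) -> int:
        """0-based position of the TSS nucleotide."""
        return self.pos - 1


@dataclass(frozen=True)
class Feature:
    """A typed, attributed interval; the unit of GFF3 import/export."""

    interval: Interval
    type: str
    attributes: tuple[tuple[str, str], ...] = field(default_factory=tuple)
    source: str = "castkit"

    def attr(self, key: str, default: str | None = None) -> str | None:
        for k, v in self.attributes:
            if k == key:
                return v
        return default


def make_feature(interval: Interval, ftype: str, source: str = "castkit", **attrs: str) -> Feature:
    return Feature(interval, ftype, tuple(sorted((k, str(v)) for k, v in attrs.items())), source)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a nucleotide FASTA into GenomeRecords (order preserved, ids unique)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"empty or invalid FASTA file: {path}")
    out, seen = [], set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        out.append(GenomeRecord(rec.id, str(rec.seq)))
    return out


def read_protein_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a protein FASTA as (id, sequence) pairs, order preserved."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"empty or invalid FASTA file: {path}")
    return [(rec.id, str(rec.seq).upper()) for rec in records]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def _esc(value: str) -> str:
    return value.replace("%", "%25").replace(";", "%3B").replace("=", "%3D").replace(",", "%2C")


def _unesc(value: str) -> str:
    return value.replace("%2C", ",").replace("%3D", "=").replace("%3B", ";").replace("%25", "%")


def write_gff3(features: Iterable[Feature], path: str | Path,
               contig_lengths: dict[str, int] | None = None) -> None:
    """Write features as GFF3 (1-based inclusive coordinates, tab-separated)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for feat in features:
            iv = feat.interval
            if contig_lengths is not None:
                clen = contig_lengths.get(iv.contig)
                if clen is not None and iv.end > clen:
                    raise ValueError(f"feature {feat.type} at [{iv.start},{iv.end}) exceeds "
                                     f"length {clen} of contig {iv.contig}")
            start1, end1 = to_one_based(iv.start, iv.end)
            attrs = ";".join(f"{_esc(k)}={_esc(v)}" for k, v in feat.attributes) or "."
            fh.write("\t".join([iv.contig, feat.source, feat.type, str(start1), str(end1),
                                ".", iv.strand, ".", attrs]) + "\n")


def read_gff3(path: str | Path) -> list[Feature]:
    features = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated columns")
            contig, source, ftype, start1, end1, _score, strand, _phase, attrs = cols
            start, end = from_one_based(int(start1), int(end1))
            attributes = tuple(
                (_unesc(kv.split("=", 1)[0]), _unesc(kv.split("=", 1)[1]))
                for kv in attrs.split(";") if kv and kv != "."
            )
            features.append(Feature(Interval(contig, start, end, strand), ftype, attributes, source))
    return features


# ---------------------------------------------------------------------------
# TSS tables


def read_tss_table(path: str | Path, contig_lengths: dict[str, int] | None = None) -> list[TssRecord]:
    """Read a TSV of (contig, 1-based pos, strand[, label]); '#' lines are comments."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: expected at least 3 columns")
            contig, pos_s, strand = cols[0], cols[1], cols[2]
            label = cols[3] if len(cols) > 3 else ""
            try:
                pos = int(pos_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer position {pos_s!r}") from None
            if strand not in "+-":
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            if pos < 1:
                raise ValueError(f"{path}:{lineno}: positions are 1-based; got {pos}")
            if contig_lengths is not None:
                clen = contig_lengths.get(contig)
                if clen is not None and pos > clen:
                    raise ValueError(f"{path}:{lineno}: position {pos} beyond contig {contig} ({clen} nt)")
            out.append(TssRecord(contig, pos, strand, label))
    return out


def write_tss_table(records: Iterable[TssRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#contig\tpos\tstrand\tlabel\n")
        for r in records:
            fh.write(f"{r.contig}\t{r.pos}\t{r.strand}\t{r.label}\n")
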