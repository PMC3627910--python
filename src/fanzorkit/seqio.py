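"""Sequence and coordinate data model plus FASTA/GFF3/TSV plumbing.

Coordinates are 0-based half-open everywhere inside the package; the single
place the 1-based inclusive convention appears is GFF3 output. The plus strand
is always the orientation of the input sequence: minus-strand structures are
reported with plus-strand coordinates and ``strand='-'``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUC_ALPHABET = frozenset("ACGTN")
PROT_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

FEATURE_VOCABULARY = frozenset({"tir", "hairpin", "atir", "tsd", "element", "motif_hit"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaParseError(ValueError):
    """Raised for malformed FASTA records or disallowed characters."""


@dataclass(frozen=True)
class NucSequence:
    """A named nucleotide sequence over {A,C,G,T,N}, uppercase."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - NUC_ALPHABET
        if bad:
            raise FastaParseError(
                f"record {self.id!r}: disallowed nucleotide characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ProtSequence:
    """A named protein sequence over the 20 amino acids plus X, uppercase."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - PROT_ALPHABET
        if bad:
            raise FastaParseError(
                f"record {self.id!r}: disallowed amino-acid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: Literal["+", "-"] = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id!r}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AnnotationRecord:
    """One annotated feature destined for GFF3/TSV output."""

    interval: GenomicInterval
    feature: str
    score: float | None = None
    attributes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.feature not in FEATURE_VOCABULARY:
            raise ValueError(
                f"feature {self.feature!r} not in controlled vocabulary "
                f"{sorted(FEATURE_VOCABULARY)}"
            )


def revcomp(seq: str) -> str:
    """Reverse complement of a {A,C,G,T,N} string (N maps to N)."""
    bad = set(seq) - NUC_ALPHABET
    if bad:
        raise ValueError(f"cannot reverse-complement characters {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(a: str) -> str:
    """Watson-Crick complement of a single base (N -> N)."""
    return a.translate(_COMPLEMENT)


_PAIR = {"A": "T", "T": "A", "C": "G", "G": "C"}


def pairs(a: str, b: str) -> bool:
    """True iff base ``a`` Watson-Crick pairs with base ``b``.

    G.T wobble is a mismatch (DNA pairing); N never pairs.
    """
    return _PAIR.get(a) == b if a != "N" else False


def read_fasta(
    path: str | Path,
    alphabet: Literal["nucleotide", "protein"],
    tolerate_n: bool = False,
) -> list[NucSequence] | list[ProtSequence]:
    """Read a FASTA file into typed sequence records, order preserved.

    Residues are uppercased (soft-masking is ignored). For proteins, stop
    characters (``*``) are stripped. Characters outside the alphabet raise
    :class:`FastaParseError` naming the record and offset, unless
    ``tolerate_n`` is set for nucleotide input, in which case they are mapped
    to ``N``.
    """
    if alphabet not in ("nucleotide", "protein"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    allowed = NUC_ALPHABET if alphabet == "nucleotide" else PROT_ALPHABET
    out: list[NucSequence | ProtSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FastaParseError(f"{path}: record with empty header")
        residues = str(rec.seq).upper()
        if alphabet == "protein":
            residues = residues.replace("*", "")
        for offset, ch in enumerate(residues):
            if ch not in allowed:
                if alphabet == "nucleotide" and tolerate_n:
                    continue
                raise FastaParseError(
                    f"record {rec.id!r}: disallowed character {ch!r} at offset {offset}"
                )
        if alphabet == "nucleotide" and tolerate_n:
            residues = "".join(ch if ch in allowed else "N" for ch in residues)
        cls = NucSequence if alphabet == "nucleotide" else ProtSequence
        out.append(cls(id=rec.id, residues=residues))
    return out


def write_fasta(seqs: Iterable[NucSequence | ProtSequence], path: str | Path) -> None:
    """Write records as FASTA (60-column wrapping)."""
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def write_gff3(
    records: Iterable[AnnotationRecord],
    path: str | Path,
    seq_lengths: Mapping[str, int] | None = None,
    source: str = "fanzorkit",
) -> None:
    """Write annotation records as GFF3 (1-based inclusive coordinates).

    Records are emitted in deterministic (seq_id, start, feature) order. If
    ``seq_lengths`` is given, every interval is bounds-checked against it.
    """
    recs = sorted(records, key=lambda r: (r.interval.seq_id, r.interval.start, r.feature))
    if seq_lengths is not None:
        for r in recs:
            length = seq_lengths.get(r.interval.seq_id)
            if length is None:
                raise ValueError(f"interval references unknown sequence {r.interval.seq_id!r}")
            if r.interval.end > length:
                raise ValueError(
                    f"interval [{r.interval.start}, {r.interval.end}) exceeds "
                    f"length {length} of {r.interval.seq_id!r}"
                )
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in recs:
            score = "." if r.score is None else f"{r.score:g}"
            attrs = ";".join(f"{k}={v}" for k, v in r.attributes.items()) or "."
            fh.write(
                "\t".join(
                    (
                        r.interval.seq_id,
                        source,
                        r.feature,
                        str(r.interval.start + 1),
                        str(r.interval.end),
                        score,
                        r.interval.strand,
                        ".",
                        attrs,
                    )
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[AnnotationRecord]:
    """Read a GFF3 file written by :func:`write_gff3` back into records."""
    out: list[AnnotationRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            seq_id, _source, feature, start, end, score, strand, _phase, attrs = cols
            attributes = {}
            if attrs != ".":
                for pair in attrs.split(";"):
                    k, _, v = pair.partition("=")
                    attributes[k] = v
            out.append(
                AnnotationRecord(
                    interval=GenomicInterval(seq_id, int(start) - 1, int(end), strand),  # type: ignore[arg-type]
                    feature=feature,
                    score=None if score == "." else float(score),
                    attributes=attributes,
                )
            )
    return out
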