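"""Pairwise global alignment, percent identity and majority-rule consensus.

Identity figures for repeat families ("X% identical to the consensus", "88%
identical over the entire length") are computed from an end-gap-free global
alignment with affine gap costs: terminal overhangs are unpenalized and
excluded from the identity denominator, while internal gap columns count
against identity. The dynamic programming is delegated to
:class:`Bio.Align.PairwiseAligner`; scores, the scoring scheme and all
reporting conventions are owned here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align

from fanzorkit.seqio import NucSequence

_BASE_ORDER = "ACGT"  # consensus tie-break order


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap scoring: a gap of length k costs gap_open + k * gap_extend."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    end_gaps_free: bool = True

    def __post_init__(self) -> None:
        if self.match <= self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")


@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    matches: int
    aligned_columns: int


def _aligner(s: ScoringScheme) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = s.match
    al.mismatch_score = s.mismatch
    # biopython charges open_gap_score for the first gap position
    al.open_gap_score = s.gap_open + s.gap_extend
    al.extend_gap_score = s.gap_extend
    if s.end_gaps_free:
        for attr, legacy in (
            ("open_end_insertion_score", "target_end_open_gap_score"),
            ("extend_end_insertion_score", "target_end_extend_gap_score"),
            ("open_end_deletion_score", "query_end_open_gap_score"),
            ("extend_end_deletion_score", "query_end_extend_gap_score"),
        ):
            try:
                setattr(al, attr, 0.0)
            except AttributeError:  # older biopython
                setattr(al, legacy, 0.0)
    return al


def global_align(
    a: NucSequence | str,
    b: NucSequence | str,
    s: ScoringScheme | None = None,
) -> PairwiseAlignment:
    """Optimal affine-gap global alignment of two nucleotide sequences.

    With ``end_gaps_free`` (the default) terminal gaps are unpenalized, which
    aligns a fragment against a full-length sequence without cost for the
    overhangs. The traceback is deterministic (first co-optimal alignment of
    the aligner's fixed enumeration order).
    """
    s = s or ScoringScheme()
    sa = a.residues if isinstance(a, NucSequence) else a
    sb = b.residues if isinstance(b, NucSequence) else b
    if not sa or not sb:
        raise ValueError("cannot align empty sequences")
    aln = _aligner(s).align(sa, sb)[0]
    ga, gb = str(aln[0]), str(aln[1])
    matches, cols = _match_stats(ga, gb)
    return PairwiseAlignment(
        aligned_a=ga, aligned_b=gb, score=float(aln.score), matches=matches, aligned_columns=cols
    )


def _match_stats(ga: str, gb: str) -> tuple[int, int]:
    """(matches, columns) over the span between first and last aligned pair."""
    paired = [i for i in range(len(ga)) if ga[i] != "-" and gb[i] != "-"]
    if not paired:
        return 0, 0
    lo, hi = paired[0], paired[-1]
    matches = sum(1 for i in range(lo, hi + 1) if ga[i] == gb[i] and ga[i] != "-")
    return matches, hi - lo + 1


def percent_identity(aln: PairwiseAlignment) -> float:
    """100 * matches / aligned_columns over the end-gap-free span.

    Internal gap columns count in the denominator; terminal overhangs do not.
    """
    if aln.aligned_columns == 0:
        raise ValueError("alignment has no aligned columns")
    return 100.0 * aln.matches / aln.aligned_columns


@dataclass(frozen=True)
class ConsensusResult:
    consensus: str
    support: tuple[float, ...]  # fraction of rows agreeing, per emitted position
    n_rows: int


def build_consensus(msa: list[str]) -> ConsensusResult:
    """Majority-rule consensus of equal-length gapped rows.

    Per column the most frequent base among {A,C,G,T} wins, ties broken in
    A < C < G < T order; columns where the gap character is the strict
    plurality are dropped. Support is the fraction of all rows carrying the
    consensus base at that column.
    """
    if len(msa) < 2:
        raise ValueError("consensus requires >= 2 rows")
    width = len(msa[0])
    if any(len(row) != width for row in msa):
        raise ValueError("ragged alignment rows")
    cons: list[str] = []
    support: list[float] = []
    n = len(msa)
    for col in range(width):
        column = [row[col] for row in msa]
        counts = {b: 0 for b in _BASE_ORDER}
        gaps = 0
        for ch in column:
            if ch == "-":
                gaps += 1
            elif ch in counts:
                counts[ch] += 1
        best_base = max(_BASE_ORDER, key=lambda b: counts[b])  # ties: A<C<G<T
        if gaps > counts[best_base] or counts[best_base] == 0:
            continue
        cons.append(best_base)
        support.append(counts[best_base] / n)
    return ConsensusResult(consensus="".join(cons), support=tuple(support), n_rows=n)


def identity_to_consensus(
    copies: list[NucSequence],
    consensus: NucSequence | str,
    s: ScoringScheme | None = None,
) -> pd.DataFrame:
    """Percent identity of each copy to the family consensus."""
    cons = consensus.residues if isinstance(consensus, NucSequence) else consensus
    if not cons:
        raise ValueError("empty consensus")
    rows = []
    for copy in copies:
        aln = global_align(copy.residues, cons, s)
        rows.append({"copy_id": copy.id, "percent_identity": percent_identity(aln)})
    return pd.DataFrame(rows, columns=["copy_id", "percent_identity"])


def mean_pairwise_identity(seqs: list[NucSequence], s: ScoringScheme | None = None) -> float:
    """Mean percent identity over all unordered pairs."""
    if len(seqs) < 2:
        raise ValueError("need >= 2 sequences")
    vals = [
        percent_identity(global_align(seqs[i].residues, seqs[j].residues, s))
        for i in range(len(seqs))
        for j in range(i + 1, len(seqs))
    ]
    return float(np.mean(vals))
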