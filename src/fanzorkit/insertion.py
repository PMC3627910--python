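"""Variable-length TSD calling, target-site preference and family profiles.

The non-autonomous Helitron2 families carrying Fanzor1 ORFs are flanked by
target site duplications (TSDs) of variable length — typically about 7-19 bp,
occasionally hundreds of bp — inserted immediately downstream of T-rich
tetranucleotides (TTTT, TTTG, TTTC, TCTT, TGTT ...). Copies are frequently
5'-truncated while nearly all are intact at the 3' end, the signature of
one-ended (rolling-circle) replication. This module calls TSDs at given
insertion loci, reconstructs pre-insertion (empty) sites, and aggregates
family-level statistics.

TSD matching is exact: the duplication must be a single identical string in
both flanks, ending within ``slack`` bp of the left flank's 3' end and
starting within ``slack`` bp of the right flank's 5' end. Slack absorbs the
imprecise annotated boundaries of truncated copies.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np


class LocusError(ValueError):
    pass


@dataclass(frozen=True)
class InsertionLocus:
    """Flanks of one element insertion.

    ``left_flank``'s 3' end abuts the element 5' boundary; ``right_flank``'s
    5' end abuts the element 3' boundary.
    """

    locus_id: str
    left_flank: str
    right_flank: str
    element: str = ""


@dataclass(frozen=True)
class TsdCall:
    status: str  # "tsd" | "none"
    tsd_seq: str
    tsd_len: int
    left_slack: int
    right_slack: int
    target_tetranucleotide: str
    t_rich: bool


@dataclass
class FamilyInsertionSummary:
    family_id: str
    n_loci: int
    n_tsd: int
    tsd_fraction: float
    tsd_length_histogram: dict[int, int] = field(default_factory=dict)
    target_counts: dict[str, int] = field(default_factory=dict)
    t_rich_fraction: float = 0.0


@dataclass(frozen=True)
class TruncationProfile:
    family_id: str
    consensus_len: int
    coverage: np.ndarray
    five_prime_intact_fraction: float
    three_prime_intact_fraction: float


def check_target_site(tetranucleotide: str) -> bool:
    """True iff >= 3 of the 4 bases are T.

    This captures the enumerated T-rich target set (TTTT, TTTG, TTTC, TCTT,
    TGTT) plus permutations.
    """
    if len(tetranucleotide) != 4:
        raise ValueError(f"target site must be 4 bp, got {tetranucleotide!r}")
    return tetranucleotide.count("T") >= 3


def call_tsd(
    locus: InsertionLocus,
    min_len: int = 5,
    max_len: int = 25,
    slack: int = 3,
) -> TsdCall:
    """Call the TSD at one insertion locus.

    Finds the longest exact string (length <= ``max_len``) that terminates
    within ``slack`` bp of the left flank's 3' end and begins within ``slack``
    bp of the right flank's 5' end. If its length >= ``min_len`` the call is
    ``tsd``; ties on length are broken by smallest total slack, then smallest
    left slack, then smallest right slack. The target tetranucleotide (the
    4-mer immediately 5' of the 5'-TSD copy, or of the insertion point when
    there is no TSD) and its T-richness are always populated.
    """
    lf, rf = locus.left_flank, locus.right_flank
    need = max_len + slack
    if len(lf) < need or len(rf) < need:
        raise LocusError(
            f"locus {locus.locus_id!r}: flanks must be >= {need} bp "
            f"(got {len(lf)}, {len(rf)})"
        )
    best: tuple[int, int, int, int] | None = None  # (-L, a+b, a, b)
    for a in range(slack + 1):
        for b in range(slack + 1):
            for L in range(min(max_len, len(lf) - a, len(rf) - b), min_len - 1, -1):
                if lf[len(lf) - a - L : len(lf) - a] == rf[b : b + L]:
                    key = (-L, a + b, a, b)
                    if best is None or key < best:
                        best = key
                    break  # longer L already tried for this (a, b)
    if best is not None:
        L, a, b = -best[0], best[2], best[3]
        tsd_seq = rf[b : b + L]
        tgt_end = len(lf) - a - L
    else:
        L, a, b, tsd_seq = 0, 0, 0, ""
        tgt_end = len(lf)
    if tgt_end < 4:
        raise LocusError(f"locus {locus.locus_id!r}: no room for target tetranucleotide")
    target = lf[tgt_end - 4 : tgt_end]
    return TsdCall(
        status="tsd" if best is not None else "none",
        tsd_seq=tsd_seq,
        tsd_len=L,
        left_slack=a,
        right_slack=b,
        target_tetranucleotide=target,
        t_rich=check_target_site(target),
    )


def reconstruct_empty_site(locus: InsertionLocus, call: TsdCall) -> str:
    """Reconstruct the pre-insertion (empty) site from a locus and its call.

    No TSD: the flank concatenation. TSD: the concatenation with exactly one
    duplication copy (the right-flank copy) removed, so the result has length
    len(left) + len(right) - tsd_len.
    """
    lf, rf = locus.left_flank, locus.right_flank
    if call.status == "none":
        if call.tsd_len != 0:
            raise ValueError("inconsistent call: status none with nonzero tsd_len")
        return lf + rf
    a, b, L = call.left_slack, call.right_slack, call.tsd_len
    if (
        L != len(call.tsd_seq)
        or lf[len(lf) - a - L : len(lf) - a] != call.tsd_seq
        or rf[b : b + L] != call.tsd_seq
    ):
        raise ValueError(f"call does not match locus {locus.locus_id!r}")
    return lf + rf[:b] + rf[b + L :]


def summarize_family(
    loci: list[InsertionLocus],
    family_id: str = "",
    min_len: int = 5,
    max_len: int = 25,
    slack: int = 3,
) -> FamilyInsertionSummary:
    """Per-locus TSD calls aggregated into family-level statistics."""
    if not loci:
        raise ValueError("summarize_family requires at least one locus")
    hist: Counter[int] = Counter()
    targets: Counter[str] = Counter()
    n_tsd = 0
    n_trich = 0
    for locus in loci:
        try:
            call = call_tsd(locus, min_len=min_len, max_len=max_len, slack=slack)
        except LocusError:
            raise
        except Exception as exc:  # pragma: no cover - defensive relabelling
            raise LocusError(f"locus {locus.locus_id!r}: {exc}") from exc
        targets[call.target_tetranucleotide] += 1
        if call.t_rich:
            n_trich += 1
        if call.status == "tsd":
            n_tsd += 1
            hist[call.tsd_len] += 1
    n = len(loci)
    return FamilyInsertionSummary(
        family_id=family_id,
        n_loci=n,
        n_tsd=n_tsd,
        tsd_fraction=n_tsd / n,
        tsd_length_histogram=dict(sorted(hist.items())),
        target_counts=dict(sorted(targets.items())),
        t_rich_fraction=n_trich / n,
    )


def truncation_profile(
    copy_alignments: list[tuple[str, tuple[int, int]]],
    consensus_len: int,
    d: int = 20,
    family_id: str = "",
) -> TruncationProfile:
    """Per-position copy depth along the consensus plus terminal-intact rates.

    ``copy_alignments`` gives the consensus interval (0-based half-open)
    covered by each copy. A copy is 5'-intact when its alignment starts within
    ``d`` bp of position 0 and 3'-intact when it ends within ``d`` bp of the
    consensus 3' end. The one-ended replication signature is a coverage ramp:
    depth rising toward the 3' end.
    """
    if consensus_len <= 0:
        raise ValueError("consensus_len must be positive")
    delta = np.zeros(consensus_len + 1, dtype=np.int64)
    n = len(copy_alignments)
    five = three = 0
    for copy_id, (start, end) in copy_alignments:
        if not (0 <= start < end <= consensus_len):
            raise ValueError(
                f"copy {copy_id!r}: interval [{start}, {end}) outside [0, {consensus_len})"
            )
        delta[start] += 1
        delta[end] -= 1
        if start <= d:
            five += 1
        if end >= consensus_len - d:
            three += 1
    coverage = np.cumsum(delta[:-1])
    return TruncationProfile(
        family_id=family_id,
        consensus_len=consensus_len,
        coverage=coverage,
        five_prime_intact_fraction=five / n if n else 0.0,
        three_prime_intact_fraction=three / n if n else 0.0,
    )
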