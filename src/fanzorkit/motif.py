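"""Scanner for the conserved TnpB/Fanzor residue constellation.

TnpB proteins and their eukaryotic Fanzor homologues share a constellation of
strictly conserved residues in the C-terminal half:

    D - X(125,275) - [TS] - [TS] - X - X - [C4 zinc finger] - X(5,50) - R D

i.e. an aspartate anchor, a long weakly constrained spacer, two consecutive
threonine/serine positions, exactly two free positions, a four-cysteine zinc
ribbon (OrfB_Zn_ribbon), a short spacer and a terminal arginine-aspartate
dipeptide. Spacing bounds ``X(a,b)`` count residues strictly between the two
flanking anchors; ``X-X`` is an exact gap of two.

The scanner reports *every* anchor assignment satisfying the constraints, in
deterministic (pos_d, span, anchors) order; there is no score because the
signature defines presence/absence only.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import pandas as pd

from fanzorkit.seqio import ProtSequence


class ConfigurationError(ValueError):
    """Raised when a motif spec carries inconsistent bounds."""


@dataclass(frozen=True)
class MotifSpec:
    """Spacing bounds for the D...[TS][TS]..C4..RD signature.

    All gap bounds count residues strictly between the two flanking anchors.
    ``post_ts_gap`` is the exact number of unconstrained residues between the
    second [TS] position and the first zinc-finger cysteine. The internal C4
    spacings default to bounds that admit canonical CxxC...CxxC fingers; they
    are not printed anywhere and are fully configurable.
    """

    d_ts_min: int = 125
    d_ts_max: int = 275
    post_ts_gap: int = 2
    zf_gap12_min: int = 1
    zf_gap12_max: int = 6
    zf_gap23_min: int = 4
    zf_gap23_max: int = 30
    zf_gap34_min: int = 1
    zf_gap34_max: int = 6
    zf_rd_min: int = 5
    zf_rd_max: int = 50
    aux_anchors: tuple[tuple[str, int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for lo, hi, name in (
            (self.d_ts_min, self.d_ts_max, "d_ts"),
            (self.zf_gap12_min, self.zf_gap12_max, "zf_gap12"),
            (self.zf_gap23_min, self.zf_gap23_max, "zf_gap23"),
            (self.zf_gap34_min, self.zf_gap34_max, "zf_gap34"),
            (self.zf_rd_min, self.zf_rd_max, "zf_rd"),
        ):
            if lo < 0 or hi < 0:
                raise ConfigurationError(f"{name}: bounds must be >= 0")
            if lo > hi:
                raise ConfigurationError(f"{name}: min {lo} > max {hi}")
        if self.post_ts_gap < 0:
            raise ConfigurationError("post_ts_gap must be >= 0")
        for res, lo, hi in self.aux_anchors:
            if len(res) != 1 or lo < 0 or lo > hi:
                raise ConfigurationError(f"invalid aux anchor ({res!r}, {lo}, {hi})")

    @property
    def min_span(self) -> int:
        """Smallest possible pos_d2 - pos_d + 1 under these bounds."""
        return (
            1  # D
            + self.d_ts_min
            + 2  # [TS][TS]
            + self.post_ts_gap
            + 4  # C1..C4
            + self.zf_gap12_min
            + self.zf_gap23_min
            + self.zf_gap34_min
            + self.zf_rd_min
            + 2  # RD
        )


ANCHOR_FIELDS = (
    "pos_d",
    "pos_ts1",
    "pos_ts2",
    "pos_c1",
    "pos_c2",
    "pos_c3",
    "pos_c4",
    "pos_r",
    "pos_d2",
)


@dataclass(frozen=True)
class MotifHit:
    """One placement of the signature: 0-based indices of the nine anchors."""

    protein_id: str
    pos_d: int
    pos_ts1: int
    pos_ts2: int
    pos_c1: int
    pos_c2: int
    pos_c3: int
    pos_c4: int
    pos_r: int
    pos_d2: int

    @property
    def span(self) -> int:
        return self.pos_d2 - self.pos_d + 1

    def anchors(self) -> tuple[int, ...]:
        return tuple(getattr(self, f) for f in ANCHOR_FIELDS)

    def validate(self, residues: str) -> None:
        """Re-check residue identities directly against the sequence."""
        pos = self.anchors()
        if list(pos) != sorted(set(pos)):
            raise ValueError("anchor indices not strictly increasing")
        expect = ("D", "TS", "TS", "C", "C", "C", "C", "R", "D")
        for p, allowed in zip(pos, expect):
            if residues[p] not in allowed:
                raise ValueError(f"residue {residues[p]} at {p} not in {allowed}")


def _in_window(sorted_positions: list[int], lo: int, hi: int) -> list[int]:
    """Sub-list of positions p with lo <= p <= hi."""
    return sorted_positions[bisect_left(sorted_positions, lo) : bisect_right(sorted_positions, hi)]


def scan_protein(prot: ProtSequence, spec: MotifSpec | None = None) -> list[MotifHit]:
    """Return every distinct anchor assignment of the signature on ``prot``.

    Hits are sorted by (pos_d, span) then remaining anchors; the list is empty
    when no placement exists.
    """
    spec = spec or MotifSpec()
    s = prot.residues
    n = len(s)
    d_pos = [i for i, ch in enumerate(s) if ch == "D"]
    c_pos = [i for i, ch in enumerate(s) if ch == "C"]
    ts_pair = [i for i in range(n - 1) if s[i] in "TS" and s[i + 1] in "TS"]

    hits: list[MotifHit] = []
    for i in d_pos:
        for j in _in_window(ts_pair, i + 1 + spec.d_ts_min, i + 1 + spec.d_ts_max):
            c1 = j + 2 + spec.post_ts_gap  # exact gap after the [TS][TS] pair
            if c1 >= n or s[c1] != "C":
                continue
            for c2 in _in_window(c_pos, c1 + 1 + spec.zf_gap12_min, c1 + 1 + spec.zf_gap12_max):
                for c3 in _in_window(c_pos, c2 + 1 + spec.zf_gap23_min, c2 + 1 + spec.zf_gap23_max):
                    for c4 in _in_window(c_pos, c3 + 1 + spec.zf_gap34_min, c3 + 1 + spec.zf_gap34_max):
                        lo, hi = c4 + 1 + spec.zf_rd_min, c4 + 1 + spec.zf_rd_max
                        for r in range(lo, min(hi, n - 2) + 1):
                            if s[r] != "R" or s[r + 1] != "D":
                                continue
                            if not _aux_ok(s, r + 1, spec.aux_anchors):
                                continue
                            hits.append(
                                MotifHit(prot.id, i, j, j + 1, c1, c2, c3, c4, r, r + 1)
                            )
    hits.sort(key=lambda h: (h.pos_d, h.span) + h.anchors())
    return hits


def _aux_ok(s: str, last: int, aux: tuple[tuple[str, int, int], ...]) -> bool:
    """Check optional downstream anchors, each relative to the previous one."""
    prev = last
    for res, lo, hi in aux:
        nxt = None
        for p in range(prev + 1 + lo, min(prev + 1 + hi, len(s) - 1) + 1):
            if s[p] == res:
                nxt = p
                break
        if nxt is None:
            return False
        prev = nxt
    return True


def best_hit(hits: list[MotifHit]) -> MotifHit | None:
    """The minimal-span hit (ties: smallest pos_d), or None for no hits."""
    if not hits:
        return None
    return min(hits, key=lambda h: (h.span, h.pos_d) + h.anchors())


def scan_proteome(prots: list[ProtSequence], spec: MotifSpec | None = None) -> pd.DataFrame:
    """Scan a batch of proteins; one row per input, input order preserved.

    Columns: protein_id, has_motif, n_hits, and the best hit's anchor
    positions (pandas NA when absent).
    """
    spec = spec or MotifSpec()
    rows = []
    for p in prots:
        hits = scan_protein(p, spec)
        best = best_hit(hits)
        row: dict[str, object] = {
            "protein_id": p.id,
            "has_motif": bool(hits),
            "n_hits": len(hits),
        }
        for f in ANCHOR_FIELDS + ("span",):
            row[f] = getattr(best, f) if best is not None else pd.NA
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["protein_id", "has_motif", "n_hits", *ANCHOR_FIELDS, "span"]
    )
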