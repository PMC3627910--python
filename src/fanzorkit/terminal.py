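"""Terminal-structure detectors and Helitron1/Helitron2 classification.

Detection is purely combinatorial: inverted repeats and hairpin stems are
scored by Watson-Crick complementarity with a bounded mismatch count, with no
thermodynamic folding. G.T wobble pairs count as mismatches (DNA pairing).

Two Helitron groups are distinguished by their termini:

* **Helitron1** (canonical): conserved 5'-TC ... CTRR-3' ends and a single
  hairpin in the 3'-subterminal region.
* **Helitron2**: a 5'-T start, hairpins at *both* ends, and a pair of short
  (8-15 bp) asymmetric terminal inverted repeats (ATIRs) — the 5'-ATIR 0-2 bp
  from the 5' terminus (pairing downstream to form the 5' hairpin), the
  3'-ATIR subterminal, immediately upstream of the 3' hairpin.

Arm/stem maximality convention: reported arms and stems begin and end with a
complementary pair; mismatches are internal only. Without this the mismatch
budget would let reported arms absorb arbitrary non-pairing flanks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from fanzorkit.seqio import GenomicInterval, NucSequence, pairs


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class InvertedRepeat:
    """A pair of reverse-complementary arms near the two element termini."""

    left: GenomicInterval
    right: GenomicInterval
    arm_len: int
    mismatches: int
    left_offset: int  # bp from the 5' terminus to the left arm start
    right_offset: int  # bp from the right arm end to the 3' terminus


@dataclass(frozen=True)
class Hairpin:
    """An intrastrand stem-loop: two nearby reverse-complementary segments."""

    stem_left: GenomicInterval
    stem_right: GenomicInterval
    loop_len: int
    stem_len: int
    mismatches: int


@dataclass(frozen=True)
class AtirPair:
    """Asymmetric terminal inverted repeat pair diagnostic of Helitron2."""

    ir: InvertedRepeat
    five_prime_ok: bool  # left arm starts <= 2 bp from the 5' end
    three_prime_ok: bool  # right arm ends inside the 3'-subterminal window
    upstream_of_hairpin: bool  # right arm ends <= gap_max before a 3' hairpin


@dataclass(frozen=True)
class HelitronCall:
    verdict: str  # helitron1 | helitron2 | unclassified
    evidence: dict[str, bool]
    atir: AtirPair | None = None
    five_prime_hairpins: tuple[Hairpin, ...] = field(default_factory=tuple)
    three_prime_hairpins: tuple[Hairpin, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class HelitronParams:
    """Tunable windows and tolerances for terminal-structure detection.

    Ranges mirror the described element anatomy: ATIR arms 8-15 bp, 5'-ATIR
    offset <= 2 bp, 3'-ATIR roughly 20-30 bp from the 3' end (window widened
    to 15-40 for tolerance), ATIR-to-hairpin gap <= 3 bp.
    """

    tir_min_len: int = 10
    tir_max_offset: int = 5
    tir_max_mismatch_frac: float = 0.2
    stem_min: int = 6
    loop_min: int = 3
    loop_max: int = 15
    hairpin_max_mismatches: int = 1
    atir_min_len: int = 8
    atir_max_len: int = 15
    atir_max_mismatches: int = 1
    atir_five_prime_max_offset: int = 2
    atir_subterm_min: int = 15
    atir_subterm_max: int = 40
    atir_hairpin_gap_max: int = 3
    five_prime_window: int = 60
    three_prime_window: int = 60

    def __post_init__(self) -> None:
        if self.loop_min > self.loop_max:
            raise ConfigurationError("loop_min > loop_max")
        if self.atir_min_len > self.atir_max_len:
            raise ConfigurationError("atir_min_len > atir_max_len")


DEFAULT_PARAMS = HelitronParams()


def _arm_match_profile(seq: str, li: int, re: int, max_len: int) -> list[bool]:
    """match[k] = does seq[li+k] pair seq[re-1-k] (arm positions from outside in)."""
    return [pairs(seq[li + k], seq[re - 1 - k]) for k in range(max_len)]


def find_tirs(
    elem: NucSequence,
    min_len: int = 10,
    max_offset: int = 5,
    max_mismatch_frac: float = 0.2,
) -> InvertedRepeat | None:
    """Best terminal inverted repeat of an element, or None.

    Searches every left-arm start within ``max_offset`` of the 5' end and
    right-arm end within ``max_offset`` of the 3' end, and returns the
    maximal-arm-length repeat with mismatch fraction <= ``max_mismatch_frac``
    whose arms begin and end with complementary pairs. Ties are broken by
    fewest mismatches, then smallest left offset, then smallest right offset.
    """
    if min_len < 4:
        raise ConfigurationError("min_len must be >= 4")
    s = elem.residues
    n = len(s)
    if n <= 2 * min_len:
        raise ValueError(f"element {elem.id!r} too short for min_len {min_len}")
    best: tuple | None = None  # (-L, mism, i, j, candidate)
    for i in range(min(max_offset, n) + 1):
        for j in range(min(max_offset, n) + 1):
            cap = (n - i - j) // 2  # arms must not overlap
            if cap < min_len:
                continue
            match = _arm_match_profile(s, i, n - j, cap)
            if not match[0]:
                continue
            mism = 0
            for L in range(1, cap + 1):
                if not match[L - 1]:
                    mism += 1
                    continue  # arm must end with a complementary pair
                if L < min_len or mism > int(L * max_mismatch_frac):
                    continue
                key = (-L, mism, i, j)
                if best is None or key < best[:4]:
                    best = (
                        -L,
                        mism,
                        i,
                        j,
                        InvertedRepeat(
                            left=GenomicInterval(elem.id, i, i + L),
                            right=GenomicInterval(elem.id, n - j - L, n - j),
                            arm_len=L,
                            mismatches=mism,
                            left_offset=i,
                            right_offset=j,
                        ),
                    )
    return best[4] if best is not None else None


def find_hairpins(
    seq: NucSequence,
    window: GenomicInterval | None = None,
    stem_min: int = 6,
    loop_min: int = 3,
    loop_max: int = 15,
    max_mismatches: int = 1,
) -> list[Hairpin]:
    """All maximal stem-loops inside ``window``, sorted by stem start.

    For every loop placement the stem is extended outward as far as the
    mismatch budget allows; the stem must begin and end with complementary
    pairs, and a reported hairpin is never extendable by one complementary
    pair at either stem end (outward, or inward while keeping the loop >=
    ``loop_min``).
    """
    if loop_min > loop_max:
        raise ConfigurationError("loop_min > loop_max")
    s = seq.residues
    ws, we = (window.start, window.end) if window is not None else (0, len(s))
    if not (0 <= ws < we <= len(s)):
        raise ValueError("window outside sequence")
    out: list[Hairpin] = []
    for loop_start in range(ws + 1, we):
        for g in range(loop_min, loop_max + 1):
            right0 = loop_start + g
            if right0 >= we:
                break
            cap = min(loop_start - ws, we - right0)
            if cap < stem_min:
                continue
            # innermost pair must be complementary, else the loop owns it
            if not pairs(s[loop_start - 1], s[right0]):
                continue
            # inward extension across the loop would subsume this center
            if g - 2 >= loop_min and pairs(s[loop_start], s[right0 - 1]):
                continue
            match = [pairs(s[loop_start - 1 - t], s[right0 + t]) for t in range(cap)]
            best_k = 0
            mism = 0
            for k in range(1, cap + 1):
                if not match[k - 1]:
                    mism += 1
                    if mism > max_mismatches:
                        break
                    continue
                if mism <= max_mismatches:
                    best_k = k
            if best_k >= stem_min:
                sl = loop_start - best_k
                mm = sum(1 for t in range(best_k) if not match[t])
                out.append(
                    Hairpin(
                        stem_left=GenomicInterval(seq.id, sl, loop_start),
                        stem_right=GenomicInterval(seq.id, right0, right0 + best_k),
                        loop_len=g,
                        stem_len=best_k,
                        mismatches=mm,
                    )
                )
    out = _drop_contained(out)
    out.sort(key=lambda h: (h.stem_left.start, h.stem_left.end, h.loop_len))
    return out


def _contained(inner: Hairpin, outer: Hairpin) -> bool:
    return (
        inner is not outer
        and inner.stem_left.start >= outer.stem_left.start
        and inner.stem_left.end <= outer.stem_left.end
        and inner.stem_right.start >= outer.stem_right.start
        and inner.stem_right.end <= outer.stem_right.end
    )


def _drop_contained(hairpins: list[Hairpin]) -> list[Hairpin]:
    """Keep only hairpins whose stems are not nested inside another's stems."""
    return [h for h in hairpins if not any(_contained(h, o) for o in hairpins)]


def find_atir_pair(elem: NucSequence, params: HelitronParams = DEFAULT_PARAMS) -> AtirPair | None:
    """Best qualifying ATIR pair of an element, or None.

    Qualifying means: arm length within [atir_min_len, atir_max_len], left arm
    starting within ``atir_five_prime_max_offset`` of the 5' end, right arm
    ending inside the 3'-subterminal window, and located at most
    ``atir_hairpin_gap_max`` bp upstream of a detected 3' hairpin. Best is the
    longest arm, then fewest mismatches, then smallest offsets.
    """
    s = elem.residues
    n = len(s)
    if n < 60:
        raise ValueError("element too short for ATIR analysis")
    hp_window = GenomicInterval(elem.id, max(0, n - params.three_prime_window), n)
    hairpins = find_hairpins(
        elem,
        hp_window,
        stem_min=params.stem_min,
        loop_min=params.loop_min,
        loop_max=params.loop_max,
        max_mismatches=params.hairpin_max_mismatches,
    )
    hp_starts = sorted(h.stem_left.start for h in hairpins)
    best: tuple | None = None
    for a in range(params.atir_five_prime_max_offset + 1):
        for roff in range(params.atir_subterm_min, params.atir_subterm_max + 1):
            e = n - roff  # right arm end (exclusive)
            # must sit immediately upstream of a 3' hairpin stem
            if not any(0 <= hs - e <= params.atir_hairpin_gap_max for hs in hp_starts):
                continue
            for L in range(params.atir_max_len, params.atir_min_len - 1, -1):
                if a + L >= e - L:  # arms must not overlap
                    continue
                match = [pairs(s[a + k], s[e - 1 - k]) for k in range(L)]
                if not (match[0] and match[-1]):
                    continue
                mism = match.count(False)
                if mism > params.atir_max_mismatches:
                    continue
                key = (-L, mism, a, roff)
                if best is None or key < best[:4]:
                    ir = InvertedRepeat(
                        left=GenomicInterval(elem.id, a, a + L),
                        right=GenomicInterval(elem.id, e - L, e),
                        arm_len=L,
                        mismatches=mism,
                        left_offset=a,
                        right_offset=roff,
                    )
                    best = (-L, mism, a, roff, ir)
    if best is None:
        return None
    ir = best[4]
    return AtirPair(
        ir=ir,
        five_prime_ok=ir.left_offset <= params.atir_five_prime_max_offset,
        three_prime_ok=params.atir_subterm_min <= ir.right_offset <= params.atir_subterm_max,
        upstream_of_hairpin=True,
    )


def _overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    return a.start < b.end and b.start < a.end


def classify_helitron(elem: NucSequence, params: HelitronParams = DEFAULT_PARAMS) -> HelitronCall:
    """Classify an element as helitron1, helitron2 or unclassified.

    helitron2: a qualifying ATIR pair, a 5' hairpin overlapping >= 1 bp of the
    5'-ATIR, a 3' hairpin, and a 5'-T start. helitron1: 5'-TC start, CTRR-3'
    end (R = A/G), a 3'-subterminal hairpin, and no qualifying ATIR pair.
    Classification is DNA-structure-only; the orientation of any encoded
    RepHel protein plays no role.
    """
    s = elem.residues
    n = len(s)
    if n < 100:
        raise ValueError("element too short to classify")
    hp_kwargs = dict(
        stem_min=params.stem_min,
        loop_min=params.loop_min,
        loop_max=params.loop_max,
        max_mismatches=params.hairpin_max_mismatches,
    )
    five_hp = find_hairpins(
        elem, GenomicInterval(elem.id, 0, min(params.five_prime_window, n)), **hp_kwargs
    )
    three_hp = find_hairpins(
        elem, GenomicInterval(elem.id, max(0, n - params.three_prime_window), n), **hp_kwargs
    )
    atir = find_atir_pair(elem, params)

    hairpin_over_atir = False
    if atir is not None:
        hairpin_over_atir = any(
            _overlaps(h.stem_left, atir.ir.left) or _overlaps(h.stem_right, atir.ir.left)
            for h in five_hp
        )
    evidence = {
        "five_prime_end_match": s.startswith("TC"),
        "three_prime_end_match": len(s) >= 4
        and s.endswith(("CTAA", "CTAG", "CTGA", "CTGG")),
        "five_prime_hairpin": bool(five_hp),
        "three_prime_hairpin": bool(three_hp),
        "atir_pair": atir is not None,
        "five_prime_t_start": s.startswith("T"),
        "five_prime_hairpin_overlaps_atir": hairpin_over_atir,
    }
    if (
        evidence["atir_pair"]
        and evidence["five_prime_hairpin_overlaps_atir"]
        and evidence["three_prime_hairpin"]
        and evidence["five_prime_t_start"]
    ):
        verdict = "helitron2"
    elif (
        evidence["five_prime_end_match"]
        and evidence["three_prime_end_match"]
        and evidence["three_prime_hairpin"]
        and not evidence["atir_pair"]
    ):
        verdict = "helitron1"
    else:
        verdict = "unclassified"
    return HelitronCall(
        verdict=verdict,
        evidence=evidence,
        atir=atir,
        five_prime_hairpins=tuple(five_hp),
        three_prime_hairpins=tuple(three_hp),
    )
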