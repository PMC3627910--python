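"""Synthetic genomes with planted transposable elements and ground truth.

The generator emulates the insertion phenomenology of the Fanzor-bearing
families: elements with terminal inverted repeats (SPu-1-like), canonical
Helitron1 termini (5'-TC ... hairpin ... CTRR-3'), or Helitron2 termini
(5'-T, ATIR pair, hairpins at both ends); variable-length TSDs duplicated
from the target site; preferential insertion immediately 3' of T-rich
tetranucleotides; geometric 5' truncation (the one-ended replication
signature); and post-insertion substitution divergence.

Every stochastic choice flows from a single integer seed through derived
per-family substreams, so regeneration is byte-identical. Planted structures
are guarded against chance extension: the pairs immediately inside planted
arms and outside planted stems are forced non-complementary, so a detector
reporting exact coordinates is checking the detector, not luck.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from fanzorkit.insertion import InsertionLocus
from fanzorkit.seqio import GenomicInterval, NucSequence, revcomp
from fanzorkit.terminal import HelitronParams, find_atir_pair

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class TirStructure:
    arm_len: int = 33


@dataclass(frozen=True)
class Helitron1Structure:
    stem_len: int = 8
    loop_len: int = 4
    hairpin_offset: int = 10  # bp from stem_right end to the 3' terminus


@dataclass(frozen=True)
class Helitron2Structure:
    atir_len: int = 10
    five_offset: int = 1  # bp from the 5' end to the 5'-ATIR
    five_loop_len: int = 4
    three_stem_len: int = 7
    three_loop_len: int = 4
    atir_gap: int = 2  # 3'-ATIR end to 3' hairpin stem start
    tail: int = 5  # bp after the 3' hairpin to the terminus


Structure = TirStructure | Helitron1Structure | Helitron2Structure | None


@dataclass(frozen=True)
class TsdModel:
    kind: Literal["none", "fixed", "uniform"] = "none"
    lo: int = 0
    hi: int = 0

    def __post_init__(self) -> None:
        if self.kind == "uniform" and self.lo > self.hi:
            raise ValueError("uniform TSD model requires lo <= hi")

    def draw(self, rng: np.random.Generator) -> int:
        if self.kind == "none":
            return 0
        if self.kind == "fixed":
            return self.lo
        return int(rng.integers(self.lo, self.hi + 1))

    @property
    def max_len(self) -> int:
        return 0 if self.kind == "none" else self.hi if self.kind == "uniform" else self.lo


@dataclass(frozen=True)
class FamilySpec:
    """Generating parameters of one planted element family.

    Defaults mirror the studied families: ~7-19 bp TSDs of variable length,
    frequent 5' truncation coupled with intact 3' ends, and copies a few
    percent diverged from the family ancestor.
    """

    family_id: str
    element_len: int = 2100
    structure: Structure = None
    copy_number: int = 0
    substitution_rate: float = 0.0
    truncation_prob: float = 0.0
    truncation_mean_frac: float = 0.3
    tsd_model: TsdModel = field(default_factory=TsdModel)
    tsd_prob: float = 1.0  # probability a copy receives a TSD at all
    target_preference_prob: float = 0.0

    def __post_init__(self) -> None:
        for p, name in (
            (self.substitution_rate, "substitution_rate"),
            (self.truncation_prob, "truncation_prob"),
            (self.tsd_prob, "tsd_prob"),
            (self.target_preference_prob, "target_preference_prob"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")


@dataclass(frozen=True)
class TruthRecord:
    family_id: str
    copy_id: str
    interval: GenomicInterval
    truncation_offset: int
    tsd_len: int
    tsd_seq: str
    target_tetranucleotide: str
    pre_insertion_locus: str


@dataclass(frozen=True)
class SimulatedGenome:
    genome: NucSequence
    truth: list[TruthRecord]
    seed: int
    flank_len: int
    params_echo: dict

    def loci(self, flank_len: int | None = None) -> list[InsertionLocus]:
        """Insertion loci (flanks) for every truth record, ready for call_tsd."""
        f = flank_len if flank_len is not None else self.flank_len
        g = self.genome.residues
        out = []
        for rec in self.truth:
            s, e = rec.interval.start, rec.interval.end
            out.append(
                InsertionLocus(
                    locus_id=rec.copy_id,
                    left_flank=g[s - f : s],
                    right_flank=g[e : e + f],
                    element=g[s:e],
                )
            )
        return out


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p).tobytes().decode()


def _non_pairing_base(rng: np.random.Generator, partner: str) -> str:
    """A base that does not Watson-Crick pair with ``partner``."""
    options = [b for b in "ACGT" if b != _COMP[partner]]
    return options[int(rng.integers(0, 3))]


def _guard(seq: list[str], rng: np.random.Generator, left_pos: int, right_pos: int, n_pairs: int) -> None:
    """Force positions (left_pos+t, right_pos-t) to be non-complementary."""
    for t in range(n_pairs):
        seq[right_pos - t] = _non_pairing_base(rng, seq[left_pos + t])


def _base_avoiding(rng: np.random.Generator, partners: list[str]) -> str:
    """A base pairing with none of ``partners`` (at most two may be excluded)."""
    options = [b for b in "ACGT" if all(b != _COMP[p] for p in partners)]
    return options[int(rng.integers(0, len(options)))]


def make_element(spec: FamilySpec, rng_seed: int | np.random.Generator, gc: float = 0.5) -> NucSequence:
    """Generate one ancestral element embedding the requested terminal structure.

    TIR arms are exact reverse complements; Helitron1 elements carry 5'-TC and
    CTRR-3' ends plus a 3'-subterminal hairpin; Helitron2 elements carry a
    5'-T start, an ATIR pair and hairpins at both ends. Helitron1 elements are
    additionally rejection-sampled so that no chance ATIR pair qualifies —
    absence of the ATIR pair is part of the canonical structure definition.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    n = spec.element_len
    st = spec.structure
    if st is None:
        return NucSequence(spec.family_id, _random_seq(rng, n, gc))
    if isinstance(st, TirStructure):
        if n < 2 * st.arm_len + 30:
            raise ValueError(f"element_len {n} too short for {st.arm_len}-bp TIRs")
        s = list(_random_seq(rng, n, gc))
        arm = _random_seq(rng, st.arm_len, gc)
        s[: st.arm_len] = list(arm)
        s[n - st.arm_len :] = list(revcomp(arm))
        # block inward arm extension (mismatch budget is 20% of arm length)
        _guard(s, rng, st.arm_len, n - st.arm_len - 1, max(12, st.arm_len // 2))
        return NucSequence(spec.family_id, "".join(s))
    if isinstance(st, Helitron1Structure):
        block = 2 * st.stem_len + st.loop_len
        if n < block + st.hairpin_offset + 30:
            raise ValueError("element_len too short for Helitron1 structure")
        for _attempt in range(50):
            s = list(_random_seq(rng, n, gc))
            s[0:2] = ["T", "C"]
            s[n - 4 :] = ["C", "T", "AG"[int(rng.integers(0, 2))], "AG"[int(rng.integers(0, 2))]]
            hp_end = n - st.hairpin_offset  # exclusive end of stem_right
            hp_start = hp_end - block
            stem = _random_seq(rng, st.stem_len, gc)
            s[hp_start : hp_start + st.stem_len] = list(stem)
            s[hp_end - st.stem_len : hp_end] = list(revcomp(stem))
            # block outward stem extension on both sides
            _guard(s, rng, hp_end, hp_start - 1, 2)
            elem = NucSequence(spec.family_id, "".join(s))
            if find_atir_pair(elem, HelitronParams()) is None:
                return elem
        raise RuntimeError("could not generate Helitron1 element without a chance ATIR pair")
    if isinstance(st, Helitron2Structure):
        if st.atir_gap < 2:
            raise ValueError("atir_gap must be >= 2 so extension guards have room")
        a0 = st.five_offset
        atir = st.atir_len
        five_block_end = a0 + 2 * atir + st.five_loop_len
        tail_block = atir + st.atir_gap + 2 * st.three_stem_len + st.three_loop_len + st.tail
        if n < five_block_end + tail_block + 40:
            raise ValueError("element_len too short for Helitron2 structure")
        s = list(_random_seq(rng, n, gc))
        s[0] = "T"
        arm = list(_random_seq(rng, atir, gc))
        if arm[0] == "T":  # avoid the leading T extending the 5'-ATIR arm
            arm[0] = "ACG"[int(rng.integers(0, 3))]
        # 5'-ATIR pairs with its downstream reverse complement: the 5' hairpin
        s[a0 : a0 + atir] = arm
        loop_start = a0 + atir
        s[loop_start + st.five_loop_len : five_block_end] = list(revcomp("".join(arm)))
        # no outward extension of the 5' hairpin past the leading T
        _guard(s, rng, 0, five_block_end, 1) if a0 > 0 else None
        # 3' terminus: ATIR right arm, gap, hairpin, tail
        e = n - (st.atir_gap + 2 * st.three_stem_len + st.three_loop_len + st.tail)
        s[e - atir : e] = list(revcomp("".join(arm)))
        hp_start = e + st.atir_gap
        stem = _random_seq(rng, st.three_stem_len, gc)
        s[hp_start : hp_start + st.three_stem_len] = list(stem)
        hp_end = hp_start + 2 * st.three_stem_len + st.three_loop_len
        s[hp_end - st.three_stem_len : hp_end] = list(revcomp(stem))
        # gap bases: block outward extension of the 3' hairpin (budget 1 =>
        # two pairs) and of the ATIR pair along its own diagonal
        s[hp_start - 1] = _base_avoiding(rng, [s[hp_end]])
        atir_out = [s[a0 - 1]] if a0 >= 1 else []
        s[e] = _base_avoiding(rng, [s[hp_end + 1], *atir_out])
        # block inward extension of the ATIR pair itself (budget 1 => 2 pairs)
        _guard(s, rng, a0 + atir, e - atir - 1, 2)
        return NucSequence(spec.family_id, "".join(s))
    raise TypeError(f"unknown structure {st!r}")


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hit:
        current = arr[i].decode()
        others = [b for b in "ACGT" if b != current]
        arr[i] = others[int(rng.integers(0, 3))].encode()
    return arr.tobytes().decode()


def _truncation_offset(spec: FamilySpec, rng: np.random.Generator) -> int:
    """5'-truncation length: geometric with mean truncation_mean_frac * element_len."""
    if spec.truncation_prob <= 0.0 or rng.random() >= spec.truncation_prob:
        return 0
    mean_bp = max(1.0, spec.truncation_mean_frac * spec.element_len)
    t = int(rng.geometric(1.0 / mean_bp))
    return min(t, spec.element_len - 50)  # keep a detectable 3' stub


def plant_copies(
    genome_len: int,
    gc: float,
    specs: list[FamilySpec],
    seed: int,
    flank_len: int | None = None,
) -> SimulatedGenome:
    """Plant family copies into an i.i.d. background genome.

    Copies are placed at uniformly chosen, well-separated sites (no nesting;
    flanks of each locus are pure background). The TSD, when drawn, duplicates
    the ``L`` bases immediately 3' of the insertion point; target-preferring
    copies are placed so the tetranucleotide 5' of the insertion point is
    T-rich. Substitutions are applied to the element copy and to each TSD copy
    independently; the background is untouched. Truth records store the
    pre-insertion locus for empty-site round trips.
    """
    master = np.random.default_rng([seed, 0])
    bg = _random_seq(master, genome_len, gc)
    max_tsd = max((sp.tsd_model.max_len for sp in specs), default=0)
    if flank_len is None:
        flank_len = max(60, max_tsd + 20)
    sep = 2 * flank_len + max_tsd + 10
    margin = flank_len + max_tsd + 4

    # choose insertion points for all copies first, in background coordinates
    placements: list[tuple[int, int, FamilySpec, NucSequence, int]] = []
    points: list[int] = []
    trich_sites = None
    for fam_idx, sp in enumerate(specs):
        frng = np.random.default_rng([seed, fam_idx + 1])
        total = sp.copy_number * sp.element_len + sum(len(x[3]) for x in placements)
        if total >= genome_len:
            raise ValueError("total planted length must be smaller than genome_len")
        ancestor = make_element(sp, frng, gc)
        for copy_idx in range(sp.copy_number):
            want_trich = frng.random() < sp.target_preference_prob
            if want_trich and trich_sites is None:
                trich_sites = [
                    p
                    for p in range(margin, genome_len - margin)
                    if bg[p - 4 : p].count("T") >= 3
                ]
            p = None
            for _try in range(10_000):
                if want_trich:
                    if not trich_sites:
                        raise RuntimeError("no T-rich sites available")
                    cand = trich_sites[int(frng.integers(0, len(trich_sites)))]
                else:
                    cand = int(frng.integers(margin, genome_len - margin))
                if all(abs(cand - q) >= sep for q in points):
                    p = cand
                    break
            if p is None:
                raise RuntimeError("cannot place copy without overlap after bounded retries")
            points.append(p)
            placements.append((p, fam_idx, sp, ancestor, copy_idx))

    # apply insertions in ascending point order, tracking the coordinate shift
    placements.sort(key=lambda x: x[0])
    pieces: list[str] = []
    truth: list[TruthRecord] = []
    prev = 0
    shift = 0
    for p, fam_idx, sp, ancestor, copy_idx in placements:
        crng = np.random.default_rng([seed, fam_idx + 1, copy_idx + 1, 7])
        L = sp.tsd_model.draw(crng) if crng.random() < sp.tsd_prob else 0
        trunc = _truncation_offset(sp, crng)
        elem_seq = _mutate(ancestor.residues[trunc:], sp.substitution_rate, crng)
        tsd = bg[p : p + L]
        left_tsd = _mutate(tsd, sp.substitution_rate, crng)
        right_tsd = _mutate(tsd, sp.substitution_rate, crng)
        pieces.append(bg[prev : p])
        pieces.append(left_tsd)
        start = p + L + shift
        pieces.append(elem_seq)
        pieces.append(right_tsd)
        end = start + len(elem_seq)
        prev = p + L
        shift += L + len(elem_seq)
        if L > 0:
            pre = bg[p + L - flank_len : p + flank_len]
        else:
            pre = bg[p - flank_len : p + flank_len]
        truth.append(
            TruthRecord(
                family_id=sp.family_id,
                copy_id=f"{sp.family_id}_c{copy_idx}",
                interval=GenomicInterval("sim", start, end),
                truncation_offset=trunc,
                tsd_len=L,
                tsd_seq=tsd,
                target_tetranucleotide=bg[p - 4 : p],
                pre_insertion_locus=pre,
            )
        )
    pieces.append(bg[prev:])
    genome = NucSequence("sim", "".join(pieces))
    echo = {
        "genome_len": genome_len,
        "gc": gc,
        "seed": seed,
        "flank_len": flank_len,
        "families": [_spec_echo(sp) for sp in specs],
    }
    truth.sort(key=lambda r: r.interval.start)
    return SimulatedGenome(genome=genome, truth=truth, seed=seed, flank_len=flank_len, params_echo=echo)


def _spec_echo(sp: FamilySpec) -> dict:
    d = dataclasses.asdict(sp)
    d["structure"] = None if sp.structure is None else {
        "kind": type(sp.structure).__name__,
        **dataclasses.asdict(sp.structure),
    }
    return d


TRUTH_COLUMNS = [
    "seq_id",
    "start",
    "end",
    "family_id",
    "copy_id",
    "strand",
    "truncation_offset",
    "tsd_len",
    "tsd_seq",
    "target_tetranucleotide",
    "pre_insertion_locus",
]


def write_truth(sim: SimulatedGenome, path: str | Path) -> None:
    """Write the truth table as TSV with BED-compatible first three columns."""
    rows = [
        {
            "seq_id": r.interval.seq_id,
            "start": r.interval.start,
            "end": r.interval.end,
            "family_id": r.family_id,
            "copy_id": r.copy_id,
            "strand": r.interval.strand,
            "truncation_offset": r.truncation_offset,
            "tsd_len": r.tsd_len,
            "tsd_seq": r.tsd_seq,
            "target_tetranucleotide": r.target_tetranucleotide,
            "pre_insertion_locus": r.pre_insertion_locus,
        }
        for r in sim.truth
    ]
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> list[TruthRecord]:
    """Read a truth TSV back into records (round trip of write_truth)."""
    df = pd.read_csv(path, sep="\t", dtype={"tsd_seq": str, "pre_insertion_locus": str}, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        out.append(
            TruthRecord(
                family_id=row["family_id"],
                copy_id=row["copy_id"],
                interval=GenomicInterval(row["seq_id"], int(row["start"]), int(row["end"]), row["strand"]),
                truncation_offset=int(row["truncation_offset"]),
                tsd_len=int(row["tsd_len"]),
                tsd_seq=row["tsd_seq"] or "",
                target_tetranucleotide=row["target_tetranucleotide"],
                pre_insertion_locus=row["pre_insertion_locus"],
            )
        )
    return out
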