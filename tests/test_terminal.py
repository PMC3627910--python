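import numpy as np
import pytest

from conftest import random_dna
from fanzorkit.seqio import GenomicInterval, NucSequence, revcomp
from fanzorkit.simulate import (
    FamilySpec,
    Helitron1Structure,
    Helitron2Structure,
    TirStructure,
    make_element,
)
from fanzorkit.terminal import (
    ConfigurationError,
    HelitronParams,
    classify_helitron,
    find_atir_pair,
    find_hairpins,
    find_tirs,
)
from oracles import hairpin_oracle, tir_oracle


class TestFindTirs:
    def test_planted_exact_arms(self, rng):
        arm = random_dna(rng, 20)
        elem = NucSequence("e", arm + random_dna(rng, 100) + revcomp(arm))
        ir = find_tirs(elem, min_len=10, max_offset=5, max_mismatch_frac=0.2)
        assert (ir.arm_len, ir.mismatches, ir.left_offset, ir.right_offset) == (20, 0, 0, 0)

    def test_shuffled_element_matches_oracle_none(self, rng):
        arm = random_dna(rng, 20)
        s = list(arm + random_dna(rng, 100) + revcomp(arm))
        rng.shuffle(s)
        s = "".join(s)
        got = find_tirs(NucSequence("sh", s), 10, 5, 0.2)
        want = tir_oracle(s, 10, 5, 0.2)
        if want is None:
            assert got is None
        else:
            assert (got.arm_len, got.mismatches, got.left_offset, got.right_offset) == want

    def test_min_len_config_error(self, rng):
        with pytest.raises(ConfigurationError):
            find_tirs(NucSequence("e", random_dna(rng, 50)), min_len=3)

    def test_agrees_with_exhaustive_oracle(self, rng):
        """Random elements, some with planted degenerate arms."""
        checked = 0
        for i in range(120):
            if i % 3 == 0:
                s = random_dna(rng, 80)
            else:
                arm = random_dna(rng, int(rng.integers(10, 25)))
                core = random_dna(rng, int(rng.integers(40, 90)))
                ra = list(revcomp(arm))
                for _ in range(int(rng.integers(0, 3))):  # degrade the right arm
                    ra[int(rng.integers(0, len(ra)))] = "ACGT"[int(rng.integers(0, 4))]
                s = arm + core + "".join(ra)
            got = find_tirs(NucSequence("x", s), 8, 4, 0.2)
            want = tir_oracle(s, 8, 4, 0.2)
            if want is None:
                assert got is None
            else:
                assert (got.arm_len, got.mismatches, got.left_offset, got.right_offset) == want
            checked += 1
        assert checked == 120

    def test_strand_symmetry(self, rng):
        arm = random_dna(rng, 18)
        elem = NucSequence("e", "AC" + arm + random_dna(rng, 90) + revcomp(arm) + "T")
        fwd = find_tirs(elem, 10, 5, 0.2)
        rev = find_tirs(NucSequence("e_rc", revcomp(elem.residues)), 10, 5, 0.2)
        n = len(elem.residues)
        assert rev.arm_len == fwd.arm_len
        assert rev.mismatches == fwd.mismatches
        assert rev.left_offset == fwd.right_offset
        assert rev.right_offset == fwd.left_offset
        assert rev.left.start == n - fwd.right.end
        assert rev.right.end == n - fwd.left.start


class TestFindHairpins:
    def test_constructed_stem_loop(self):
        seq = NucSequence("h", "AAA" + "GGGGGGG" + "TTTT" + "CCCCCCC" + "AAA")
        hps = find_hairpins(seq, stem_min=6, loop_min=3, loop_max=15, max_mismatches=1)
        assert len(hps) == 1
        h = hps[0]
        assert (h.stem_len, h.loop_len, h.mismatches) == (7, 4, 0)
        assert h.stem_left.start == 3

    def test_poly_a_window_empty(self):
        seq = NucSequence("a", "A" * 60)
        assert find_hairpins(seq, stem_min=6, loop_min=3, loop_max=15, max_mismatches=1) == []

    def test_loop_bounds_config_error(self):
        with pytest.raises(ConfigurationError):
            find_hairpins(NucSequence("a", "ACGT" * 20), loop_min=9, loop_max=3)

    def test_agrees_with_bruteforce_oracle(self, rng):
        """Random windows plus planted stem-loops at recorded positions."""
        checked = 0
        for i in range(100):
            if i % 2 == 0:
                s = random_dna(rng, 50)
            else:
                stem = random_dna(rng, int(rng.integers(6, 10)))
                loop = random_dna(rng, int(rng.integers(3, 8)))
                pre = random_dna(rng, int(rng.integers(0, 12)))
                post = random_dna(rng, int(rng.integers(0, 12)))
                s = pre + stem + loop + revcomp(stem) + post
            got = find_hairpins(
                NucSequence("w", s), stem_min=5, loop_min=3, loop_max=10, max_mismatches=1
            )
            want = hairpin_oracle(s, 0, len(s), 5, 3, 10, 1)
            got_tuples = sorted(
                (h.stem_left.start, h.stem_len, h.loop_len, h.mismatches) for h in got
            )
            assert got_tuples == want
            checked += 1
        assert checked == 100

    def test_window_restricts_search(self, rng):
        stem = "GATTACAG"
        s = "T" * 20 + stem + "AAAA" + revcomp(stem) + "T" * 20
        seq = NucSequence("w", s)
        inside = find_hairpins(seq, GenomicInterval("w", 15, 50), stem_min=6, loop_min=3, loop_max=6, max_mismatches=0)
        outside = find_hairpins(seq, GenomicInterval("w", 0, 15), stem_min=6, loop_min=3, loop_max=6, max_mismatches=0)
        assert len(inside) == 1 and outside == []


class TestAtirPair:
    def _helitron2(self, seed=3, n=400):
        return make_element(FamilySpec("h2", element_len=n, structure=Helitron2Structure()), seed)

    def test_constructed_element_flags(self):
        elem = self._helitron2()
        pair = find_atir_pair(elem)
        assert pair is not None
        assert pair.ir.arm_len == 10
        assert pair.five_prime_ok and pair.three_prime_ok and pair.upstream_of_hairpin
        assert pair.ir.left_offset <= 2
        assert 15 <= pair.ir.right_offset <= 40

    def test_subterminal_constraint_violated(self):
        elem = self._helitron2()
        # push the 3' structures away from the terminus with 60 bp of padding
        padded = NucSequence("pad", elem.residues + "A" * 60)
        assert find_atir_pair(padded) is None


class TestClassifyHelitron:
    def test_constructed_helitron2(self):
        elem = make_element(FamilySpec("h2", element_len=500, structure=Helitron2Structure()), 11)
        call = classify_helitron(elem)
        assert call.verdict == "helitron2"
        assert call.evidence["atir_pair"] and call.evidence["five_prime_t_start"]

    def test_constructed_helitron1(self):
        elem = make_element(FamilySpec("h1", element_len=500, structure=Helitron1Structure()), 12)
        call = classify_helitron(elem)
        assert call.verdict == "helitron1"
        assert elem.residues.startswith("TC")
        assert elem.residues[-4:-2] == "CT" and elem.residues[-2] in "AG" and elem.residues[-1] in "AG"

    def test_plain_sequence_unclassified(self, rng):
        elem = NucSequence("r", "G" + random_dna(rng, 399))
        assert classify_helitron(elem).verdict == "unclassified"

    def test_verdict_pure_function_of_evidence(self, rng):
        for seed in range(10):
            for st in (Helitron1Structure(), Helitron2Structure(), TirStructure(12)):
                elem = make_element(FamilySpec("f", element_len=300, structure=st), seed)
                call = classify_helitron(elem)
                ev = call.evidence
                if (
                    ev["atir_pair"]
                    and ev["five_prime_hairpin_overlaps_atir"]
                    and ev["three_prime_hairpin"]
                    and ev["five_prime_t_start"]
                ):
                    expected = "helitron2"
                elif (
                    ev["five_prime_end_match"]
                    and ev["three_prime_end_match"]
                    and ev["three_prime_hairpin"]
                    and not ev["atir_pair"]
                ):
                    expected = "helitron1"
                else:
                    expected = "unclassified"
                assert call.verdict == expected

    def test_hundred_elements_per_class_all_correct(self):
        """Simulator-generated elements at zero divergence classify perfectly."""
        for structure, expect in (
            (Helitron1Structure(), "helitron1"),
            (Helitron2Structure(), "helitron2"),
        ):
            verdicts = [
                classify_helitron(
                    make_element(FamilySpec("f", element_len=300, structure=structure), seed)
                ).verdict
                for seed in range(100)
            ]
            assert verdicts.count(expect) == 100
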