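import numpy as np
import pytest

from conftest import random_dna
from fanzorkit.insertion import (
    InsertionLocus,
    LocusError,
    call_tsd,
    check_target_site,
    reconstruct_empty_site,
    summarize_family,
    truncation_profile,
)
from oracles import tsd_oracle


def make_locus(lid, lf, rf):
    return InsertionLocus(locus_id=lid, left_flank=lf, right_flank=rf)


class TestCheckTargetSite:
    @pytest.mark.parametrize(
        "tet,expected",
        [
            ("TTTT", True),
            ("TTTG", True),
            ("TTTC", True),
            ("TCTT", True),
            ("TGTT", True),
            ("ATTT", True),
            ("TTAG", False),
            ("ACGT", False),
        ],
    )
    def test_t_rich_rule(self, tet, expected):
        assert check_target_site(tet) is expected

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            check_target_site("TTT")


class TestCallTsd:
    def test_planted_duplication_with_trich_target(self, rng):
        tsd = "ACGTACGTC"
        lf = random_dna(rng, 20) + "TTTT" + tsd
        rf = tsd + random_dna(rng, 20)
        call = call_tsd(make_locus("l1", lf, rf), min_len=5, max_len=25, slack=3)
        assert call.status == "tsd"
        assert call.tsd_seq == tsd and call.tsd_len == 9
        assert call.target_tetranucleotide == "TTTT" and call.t_rich
        assert (call.left_slack, call.right_slack) == (0, 0)

    def test_independent_flanks_no_call(self, rng):
        call = call_tsd(make_locus("l2", random_dna(rng, 50), random_dna(rng, 50)))
        assert call.status == "none" and call.tsd_len == 0
        assert len(call.target_tetranucleotide) == 4

    def test_long_tsd_mode_recovers_443bp(self, rng):
        tsd = random_dna(rng, 443)
        lf = random_dna(rng, 70) + tsd
        rf = tsd + random_dna(rng, 70)
        call = call_tsd(make_locus("long", lf, rf), min_len=5, max_len=500, slack=3)
        assert call.status == "tsd" and call.tsd_len == 443

    def test_short_flanks_error_names_locus(self, rng):
        with pytest.raises(LocusError, match="shorty"):
            call_tsd(make_locus("shorty", "ACGTACG", "ACGTACG"), max_len=25, slack=3)

    def test_agrees_with_bruteforce_oracle_on_shifted_boundaries(self, rng):
        """Slack-shifted planted TSDs: calls equal exhaustive (suffix, prefix, slack) search."""
        checked = 0
        for i in range(200):
            L = int(rng.integers(5, 20))
            tsd = random_dna(rng, L)
            a = int(rng.integers(0, 4))  # element-side slip on each flank
            b = int(rng.integers(0, 4))
            lf = random_dna(rng, 40) + tsd + random_dna(rng, a)
            rf = random_dna(rng, b) + tsd + random_dna(rng, 40)
            call = call_tsd(make_locus(f"o{i}", lf, rf), min_len=5, max_len=25, slack=3)
            want = tsd_oracle(lf, rf, 5, 25, 3)
            if want is None:
                assert call.status == "none"
            else:
                assert call.status == "tsd"
                assert (call.tsd_len, call.left_slack, call.right_slack, call.tsd_seq) == want
            checked += 1
        assert checked == 200


class TestReconstructEmptySite:
    def test_no_tsd_junction_preserved(self):
        # flank alphabets guarantee no shared >=5-bp word near the junction
        lf = "AC" * 23 + "TTTT"
        rf = "T" + "G" * 49
        locus = make_locus("e", lf, rf)
        call = call_tsd(locus)
        assert call.status == "none"
        empty = reconstruct_empty_site(locus, call)
        assert empty == lf + rf
        assert "TTTTT" in empty  # the empty site spans TTTT|T across the junction

    def test_tsd_case_length_arithmetic(self, rng):
        tsd = random_dna(rng, 9)
        lf = random_dna(rng, 30) + tsd
        rf = tsd + random_dna(rng, 30)
        locus = make_locus("t", lf, rf)
        call = call_tsd(locus)
        assert call.status == "tsd"
        empty = reconstruct_empty_site(locus, call)
        assert len(empty) == len(lf) + len(rf) - call.tsd_len

    def test_inconsistent_call_rejected(self, rng):
        tsd = random_dna(rng, 9)
        lf = random_dna(rng, 30) + tsd
        rf = tsd + random_dna(rng, 30)
        locus = make_locus("t", lf, rf)
        call = call_tsd(locus)
        other = make_locus("u", random_dna(rng, 40), random_dna(rng, 40))
        with pytest.raises(ValueError):
            reconstruct_empty_site(other, call)


class TestSummarizeFamily:
    def _family(self, rng, n_tsd, n_none):
        loci = []
        for i in range(n_tsd):
            tsd = random_dna(rng, int(rng.integers(7, 20)))
            loci.append(
                make_locus(f"t{i}", random_dna(rng, 40) + tsd, tsd + random_dna(rng, 40))
            )
        for i in range(n_none):
            # disjoint flank alphabets: no shared word can exist
            lf = "".join(rng.choice(["A", "C"], size=50))
            rf = "".join(rng.choice(["G", "T"], size=50))
            loci.append(make_locus(f"n{i}", lf, rf))
        return loci

    def test_constructed_fraction(self, rng):
        summary = summarize_family(self._family(rng, 7, 3), family_id="fam")
        assert summary.n_loci == 10
        assert summary.n_tsd == 7
        assert summary.tsd_fraction == pytest.approx(0.7)
        assert sum(summary.tsd_length_histogram.values()) == summary.n_tsd

    def test_single_no_tsd_locus(self, rng):
        summary = summarize_family(self._family(rng, 0, 1))
        assert summary.tsd_fraction == 0.0
        assert summary.tsd_length_histogram == {}

    def test_reordering_invariance(self, rng):
        loci = self._family(rng, 5, 5)
        s1 = summarize_family(loci)
        s2 = summarize_family(list(reversed(loci)))
        assert s1.tsd_fraction == s2.tsd_fraction
        assert s1.tsd_length_histogram == s2.tsd_length_histogram
        assert s1.target_counts == s2.target_counts

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            summarize_family([])


class TestTruncationProfile:
    def test_full_length_copies(self):
        prof = truncation_profile([(f"c{i}", (0, 100)) for i in range(5)], 100, d=20)
        assert prof.five_prime_intact_fraction == 1.0
        assert prof.three_prime_intact_fraction == 1.0
        assert (prof.coverage == 5).all()

    def test_half_truncated_copies(self):
        prof = truncation_profile([(f"c{i}", (50, 100)) for i in range(5)], 100, d=20)
        assert prof.five_prime_intact_fraction == 0.0
        assert prof.three_prime_intact_fraction == 1.0
        assert prof.coverage[0] == 0 and prof.coverage[-1] == 5

    def test_out_of_range_interval_rejected(self):
        with pytest.raises(ValueError, match="c0"):
            truncation_profile([("c0", (10, 120))], 100)

    def test_geometric_truncation_gives_monotone_coverage(self, rng):
        L = 500
        aligns = []
        for i in range(60):
            t = min(int(rng.geometric(1 / 150)), L - 50) if rng.random() < 0.7 else 0
            aligns.append((f"c{i}", (t, L)))
        prof = truncation_profile(aligns, L)
        assert (np.diff(prof.coverage) >= 0).all()
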