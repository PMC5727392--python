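"""Branch-point, Py-tract, PWM and GC scoring against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from branchsense import ss_features as sf
from branchsense.io_formats import pwm_from_iupac, reverse_complement, sf1_pwm
from conftest import make_intron, oracle_match, oracle_ppt, oracle_pwm_max, random_dna

dna = st.text(alphabet="ACGT", min_size=7, max_size=120)


class TestMatchDegenerate:
    @pytest.mark.parametrize("seq, pattern, expected", [
        ("AAAAAAAA", "YNYYRAY", []),                 # poly-A has no pyrimidines
        ("TACTAACTACTAAC", "YNYYRAY", [0, 7]),
        ("CTCTCAC", "YUNAY", [2]),                   # the CTCTCAC BP consensus
        ("TTTCTTTCAAATGT", "AAATGT", [8]),
        ("ACGNACG", "ACG", [0, 4]),
    ])
    def test_known_matches(self, seq, pattern, expected):
        assert sf.match_degenerate(seq, pattern) == expected

    def test_sequence_n_never_matches(self):
        assert sf.match_degenerate("TNCTAAC", "YNYYRAY") == []
        assert sf.match_degenerate("N", "N") == []

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            sf.match_degenerate("ACGT", "AXGT")

    def test_agrees_with_brute_force_oracle(self, rng):
        patterns = ["YNYYRAY", "YUNAY", "TACTAAC", "CTCTCAC", "AAATGT",
                    "TTTCTTTCAAATGT", "RNY", "WSKM"]
        for _ in range(300):
            seq = random_dna(rng, int(rng.integers(10, 120)), alphabet="ACGTN")
            pat = patterns[rng.integers(len(patterns))]
            assert sf.match_degenerate(seq, pat) == oracle_match(seq, pat)


class TestU2PairingScore:
    @pytest.mark.parametrize("hept, score", [
        ("TACTAAC", 6.0),   # optimal BP, full Watson-Crick
        ("CTCTCAC", 3.0),   # WC at positions 3, 4, 7
        ("TTTTTTT", 3.0),   # WC at 1, 4 plus wobbles at 3, 7
        ("TACTAAT", 5.5),   # position 7 T:G wobble
        ("GGGGGGG", 1.0),   # wobbles at 2 and 5 only
        ("TACTATC", 6.0),   # branch position unscored (decoy-level concern)
        ("NNNNNNN", 0.0),
    ])
    def test_enumerated_scores(self, hept, score):
        assert sf.u2_pairing_score(hept) == score

    def test_only_tactaac_reaches_the_maximum(self):
        # exhaustive over all heptamers with the scored positions varied
        best = [h for h in _all_heptamers() if sf.u2_pairing_score(h) == 6.0]
        assert all(h[:5] == "TACTA" and h[6] == "C" for h in best)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="7 nt"):
            sf.u2_pairing_score("TACTAA")

    def test_score_bounded(self, rng):
        for _ in range(200):
            s = sf.u2_pairing_score(random_dna(rng, 7))
            assert 0.0 <= s <= 6.0


def _all_heptamers():
    import itertools
    for combo in itertools.product("ACGT", repeat=7):  # 16k, cheap
        yield "".join(combo)


class TestPwmScore:
    def test_uniform_pwm_scores_zero_everywhere(self, rng):
        pwm = pwm_from_iupac("NNN", pseudocount=0.0)
        score, _ = sf.pwm_max_score(random_dna(rng, 30), pwm)
        assert score == pytest.approx(0.0)

    def test_width_one_log_odds(self):
        pwm = pwm_from_iupac("A", pseudocount=0.01)
        p_a = (1 + 0.01) / (1 + 0.04)
        score, off = sf.pwm_max_score("CAC", pwm)
        assert score == pytest.approx(math.log2(p_a / 0.25))
        assert off == 1

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            sf.pwm_max_score("ACG", sf1_pwm())

    def test_ties_break_three_prime(self):
        pwm = pwm_from_iupac("AC", pseudocount=0.0)
        _, off = sf.pwm_max_score("ACGAC", pwm)
        assert off == 3

    def test_agrees_with_brute_force_on_random_sequences(self, rng):
        pwm = sf1_pwm()
        lo = pwm.log_odds
        for _ in range(100):
            seq = random_dna(rng, int(rng.integers(7, 80)), alphabet="ACGTN")
            score, _ = sf.pwm_max_score(seq, pwm)
            assert score == pytest.approx(oracle_pwm_max(seq, lo))

    @given(seq=dna, ext=st.text(alphabet="ACGT", min_size=1, max_size=20))
    @settings(derandomize=True, max_examples=60)
    def test_extension_never_decreases_max(self, seq, ext):
        pwm = sf1_pwm()
        assert sf.pwm_max_score(seq + ext, pwm)[0] >= sf.pwm_max_score(seq, pwm)[0] - 1e-12


class TestPptScore:
    @pytest.mark.parametrize("region, score, length", [
        ("GGAAGG", 0.0, 0),          # all-purine
        ("TTTTTTTTTT", 10.0, 10),
        ("TTAGTTTT", 4.0, 4),        # selects the 3' TTTT run
        ("CCCC", 2.0, 4),
    ])
    def test_known_segments(self, region, score, length):
        got_score, got_len, _ = sf.ppt_score(region)
        assert (got_score, got_len) == (score, length)

    def test_tie_breaks_toward_three_prime(self):
        score, length, start = sf.ppt_score("TTAATT")
        assert (score, length, start) == (2.0, 2, 4)

    def test_agrees_with_exhaustive_enumeration(self, rng):
        for _ in range(300):
            region = random_dna(rng, int(rng.integers(1, 200)))
            assert sf.ppt_score(region)[0] == pytest.approx(oracle_ppt(region))


class TestGcContent:
    @pytest.mark.parametrize("seq, frac", [
        ("GGCC", 1.0), ("AATT", 0.0), ("GANT", 1 / 3),
    ])
    def test_fractions_exclude_n(self, seq, frac):
        assert sf.gc_content(seq) == pytest.approx(frac)

    def test_all_n_is_missing(self):
        assert math.isnan(sf.gc_content("NNN"))


class TestCountBpMatches:
    def test_poly_a_intron_has_none(self):
        assert sf.count_bp_matches(make_intron("A" * 200)) == 0

    def test_two_planted_consensus_copies(self, rng):
        seq = random_dna(rng, 200, alphabet="A") + "TACTAACTACTAAC" + "AG"
        assert sf.count_bp_matches(make_intron(seq)) == 2

    def test_three_non_overlapping_planted_instances(self, rng):
        tail = list("A" * 100)
        for pos in (5, 40, 80):
            tail[pos : pos + 7] = "TACTAAC"
        seq = random_dna(rng, 100, alphabet="A") + "".join(tail)
        assert sf.count_bp_matches(make_intron(seq)) == 3

    def test_monotone_in_window(self, rng):
        iv = make_intron(random_dna(rng, 400))
        counts = [sf.count_bp_matches(iv, window=w) for w in (20, 50, 100, 200)]
        assert counts == sorted(counts)


class TestScoreIntron:
    def test_planted_tactaac_recovered(self, rng):
        # TACTAAC heptamer starting at -30 -> branch A at -25
        seq = list(random_dna(rng, 300))
        seq[-30:-23] = "TACTAAC"
        seq[-2:] = "AG"
        fv = sf.score_intron(make_intron("".join(seq)))
        assert fv.bp_best_pairing == 6.0
        assert fv.bp_distance == 25

    def test_no_pyrimidines_downstream_of_bp_gives_zero_ppt(self):
        # heptamer ends in A so the region from branch+1 to -3 is all-purine
        seq = "G" * 100 + "TACTAAA" + "GAGAGAGAGAGAGAGAGAAG"
        fv = sf.score_intron(make_intron(seq))
        assert fv.ppt_score == 0.0 and fv.ppt_length == 0

    def test_short_intron_rejected(self):
        with pytest.raises(ValueError, match="shorter than 7"):
            sf.score_intron(make_intron("ACGTAG"))

    def test_features_match_independent_recomputation(self, rng):
        pwm = sf1_pwm()
        for _ in range(50):
            seq = random_dna(rng, int(rng.integers(60, 600)))
            iv = make_intron(seq)
            fv = sf.score_intron(iv, pwm)
            assert fv.len_intron == len(seq)
            assert fv.gc_intron == pytest.approx(
                (seq.count("G") + seq.count("C")) / len(seq))
            assert fv.n_bp_matches_100 == len(oracle_match(seq[-100:], "YNYYRAY"))
            region = seq[-150:] if len(seq) > 150 else seq
            assert fv.bp_best_pwm == pytest.approx(oracle_pwm_max(region, pwm.log_odds))
            # best functional candidate by direct enumeration
            best = max(
                ((sf.u2_pairing_score(seq[i:i + 7]), i) for i in range(len(seq) - 6)
                 if seq[i + 5] == "A" and len(seq) - (i + 5) <= 150
                 and len(seq) - (i + 5) >= 4),
                default=None)
            if best is not None:
                assert fv.bp_best_pairing == best[0]

    def test_decoy_candidates_never_chosen_as_best(self, rng):
        # a perfect-pairing decoy (branch position not A) must lose to a
        # weaker functional candidate
        seq = list("G" * 120)
        seq[-40:-33] = "TACTATC"   # decoy: pairing 6.0 but no branch A
        seq[-25:-18] = "CTCTCAC"   # functional, pairing 3.0
        seq[-2:] = "AG"
        iv = make_intron("".join(seq))
        cands = sf.bp_candidates(iv)
        assert any(c.pairing_score == 6.0 and not c.functional for c in cands)
        fv = sf.score_intron(iv)
        assert fv.bp_best_pairing == 3.0
        assert fv.bp_distance == 20

    def test_strand_is_metadata_only_once_sequence_is_sense(self, rng):
        # IntronRecord stores the sense-strand sequence, so scoring must be
        # identical for the same sequence annotated on either strand; the
        # reverse complement of the genomic slice is taken at BED reading.
        seq = random_dna(rng, 250)
        plus = make_intron(seq, strand="+")
        minus = make_intron(seq, strand="-")
        assert sf.score_intron(plus).as_dict() == sf.score_intron(minus).as_dict()
        assert reverse_complement(reverse_complement(seq)) == seq


class TestFlankingDiff:
    def test_identical_vectors_give_zero(self):
        fv = sf.FeatureVector(bp_best_pairing=4.0, bp_best_pwm=1.5, ppt_score=7.0)
        diff = sf.flanking_diff(fv, fv)
        assert all(v == 0.0 for v in diff.values())

    def test_upstream_minus_downstream(self):
        up = sf.FeatureVector(bp_best_pairing=6.0, bp_best_pwm=2.0, ppt_score=9.0)
        dn = sf.FeatureVector(bp_best_pairing=3.0, bp_best_pwm=1.0, ppt_score=4.0)
        diff = sf.flanking_diff(up, dn)
        assert diff == {"bp_best_pairing": 3.0, "bp_best_pwm": 1.0, "ppt_score": 5.0}

    def test_missing_value_propagates(self):
        up = sf.FeatureVector(bp_best_pairing=float("nan"), bp_best_pwm=1.0,
                              ppt_score=2.0)
        dn = sf.FeatureVector(bp_best_pairing=5.0, bp_best_pwm=1.0, ppt_score=2.0)
        assert math.isnan(sf.flanking_diff(up, dn)["bp_best_pairing"])

    def test_random_pairs_equal_u_minus_d(self, rng):
        for _ in range(20):
            a, b = rng.normal(size=3), rng.normal(size=3)
            up = sf.FeatureVector(bp_best_pairing=a[0], bp_best_pwm=a[1], ppt_score=a[2])
            dn = sf.FeatureVector(bp_best_pairing=b[0], bp_best_pwm=b[1], ppt_score=b[2])
            diff = sf.flanking_diff(up, dn)
            assert diff["ppt_score"] == pytest.approx(a[2] - b[2])
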