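"""Window extraction, pair classification and match scoring."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from plsedit.ppr_model import expected_nucleotides, repeat_position
from plsedit.target_matching import (
    DEFAULT_WEIGHTS,
    MatchCategory,
    ScoringWeights,
    TargetWindow,
    classify_pair,
    count_perfect_PS_matches,
    extract_window,
    match_profile,
    max_attainable_score,
    reverse_complement_rna,
    score_profile,
)

CODED = [("T", "N"), ("S", "N"), ("T", "D"), ("S", "D"),
         ("N", "N"), ("N", "S"), ("N", "D")]


class TestExtractWindow:
    def test_right_truncation_pads_with_n(self):
        seq = "A" * 40 + "C" + "G" * 16  # site at index 40 of 57 nt
        w = extract_window(seq, 40, W=33, D=5)
        assert len(w.sequence) == 39
        assert w.site_nt == "C"
        # only 16 nt remain downstream but D=5 fits; left side intact
        assert "N" not in w.sequence

    def test_right_edge_pads_with_n(self):
        seq = "A" * 40 + "C" + "GG"
        w = extract_window(seq, 40, W=33, D=5)
        assert w.sequence.endswith("GGNNN")

    def test_site_at_origin_pads_left(self):
        w = extract_window("CAAAAAA", 0, W=33, D=5)
        assert w.sequence.startswith("N" * 33)
        assert w.site_nt == "C"

    def test_dna_input_becomes_rna(self):
        w = extract_window("TTTTCTTTT", 4, W=4, D=4)
        assert set(w.sequence) == {"U", "C"}

    def test_minus_strand_equals_plus_on_reverse_complement(self):
        seq = "ACGTACGGTACCTTAGCATGCATCGA"
        i = 10
        minus = extract_window(seq, i, W=5, D=3, strand="-")
        rc = reverse_complement_rna(seq)
        plus = extract_window(rc, len(seq) - 1 - i, W=5, D=3, strand="+")
        assert minus.sequence == plus.sequence

    def test_non_c_site_rejected_on_demand(self):
        with pytest.raises(ValueError, match="not C"):
            extract_window("AAAAA", 2, W=2, D=2, require_c=True)

    def test_site_outside_sequence(self):
        with pytest.raises(IndexError):
            extract_window("ACGT", 7)


class TestClassifyPair:
    @pytest.mark.parametrize("pair,nt,category", [
        (("T", "D"), "A", MatchCategory.PURINE_TRANSITION),  # G expected, A seen
        (("N", "D"), "U", MatchCategory.MATCH),              # U > C, U seen
        (("N", "D"), "C", MatchCategory.PYRIMIDINE_TRANSITION),
        (("T", "N"), "U", MatchCategory.MISMATCH),           # A expected, U seen
        (("N", "N"), "C", MatchCategory.MATCH),              # unranked C/U
        (("N", "N"), "U", MatchCategory.MATCH),
        (("N", "N"), "A", MatchCategory.MISMATCH),
        (("A", "E"), "G", MatchCategory.NO_EXPECTATION),
        (("T", "D"), "N", MatchCategory.NO_EXPECTATION),
    ])
    def test_categories(self, pair, nt, category):
        assert classify_pair(expected_nucleotides(*pair), nt) is category

    def test_exhaustive_over_code_and_alphabet(self):
        """Every coded pair × nucleotide maps to exactly one category and
        a purine expectation never yields a pyrimidine transition (and
        vice versa)."""
        for pair, nt in itertools.product(CODED, "ACGU"):
            exp = expected_nucleotides(*pair)
            cat = classify_pair(exp, nt)
            assert isinstance(cat, MatchCategory)
            if cat is MatchCategory.PURINE_TRANSITION:
                assert exp.primary in "AG" and nt in "AG"
            if cat is MatchCategory.PYRIMIDINE_TRANSITION:
                assert exp.primary in "CU" and nt in "CU"
            if cat is MatchCategory.MATCH:
                assert nt == exp.primary or (exp.unranked
                                             and nt == exp.secondary)


class TestMatchProfile:
    def test_ppr65_native_has_six_of_eight_ps_matches(self, native_profile):
        assert count_perfect_PS_matches(native_profile) == (6, 8)

    def test_l5_matches_native_guanosine(self, native_profile):
        (pair,) = [p for p in native_profile.pairs
                   if p.repeat.label == "L-5TD"]
        assert pair.position == -8 and pair.nt == "G"
        assert pair.category is MatchCategory.MATCH

    def test_all_n_window_is_neutral(self, ppr65):
        w = TargetWindow("N" * 39)
        prof = match_profile(ppr65, w)
        assert prof.score == 0.0
        assert all(p.category is MatchCategory.NO_EXPECTATION
                   for p in prof.pairs)
        # no matches; the denominator (coded P/S repeats) is a property of
        # the array, not the window
        assert count_perfect_PS_matches(prof) == (0, 8)

    def test_window_too_short_names_uncovered_repeat(self, ppr65):
        with pytest.raises(ValueError, match="P-15"):
            match_profile(ppr65, TargetWindow("N" * 16, W=10, D=5))

    def test_single_mutation_changes_exactly_one_pair(self, ppr65,
                                                      native_window,
                                                      native_profile):
        for pos in range(-native_window.W, native_window.D + 1):
            nt = native_window.at(pos)
            new = "A" if nt != "A" else "G"
            mutated = match_profile(ppr65, native_window.mutate(pos, new))
            changed = [
                i for i, (a, b) in enumerate(zip(native_profile.pairs,
                                                 mutated.pairs))
                if a != b
            ]
            in_register = -18 <= pos <= -1
            assert len(changed) == (1 if in_register else 0)


class TestScoring:
    def test_all_match_purine_toy_array_scores_eight(self):
        from plsedit.ppr_model import PPRArray, PPRRepeat
        arr = PPRArray("toy", tuple(
            PPRRepeat(index=i, ptype="P", res5="T", resL="D")
            for i in range(4, 0, -1)
        ))
        # G at every register position −7..−4
        w = TargetWindow("GGGGNNNNNN", W=7, D=2)
        assert match_profile(arr, w).score == 8.0

    def test_score_recomputation_matches(self, native_profile):
        assert score_profile(native_profile) == native_profile.score

    def test_native_outranks_minus12_purine_transition(self, ppr65,
                                                       native_window):
        """An A-to-G change at −12 converts the P-9TN match into a purine
        transition and must lower the score."""
        mutant = native_window.mutate(-12, "G")
        native = match_profile(ppr65, native_window)
        mutated = match_profile(ppr65, mutant)
        (pair,) = [p for p in mutated.pairs if p.position == -12]
        assert pair.category is MatchCategory.PURINE_TRANSITION
        assert native.score > mutated.score

    def test_match_to_mismatch_strictly_decreases_score(self, ppr65,
                                                        native_window,
                                                        native_profile):
        for p in native_profile.pairs:
            if p.category is not MatchCategory.MATCH or p.repeat.is_triplet:
                continue
            # cross the purine/pyrimidine divide to force a mismatch
            new_nt = "C" if p.nt in "AG" else "A"
            mutated = match_profile(ppr65, native_window.mutate(p.position,
                                                                new_nt))
            assert mutated.score < native_profile.score

    def test_promoting_l_repeats_raises_native_score(self, ppr65,
                                                     native_window):
        promoted = ScoringWeights(promote_l=True)
        assert (match_profile(ppr65, native_window, promoted).score
                > match_profile(ppr65, native_window).score)

    def test_max_attainable_bounds_any_window_score(self, ppr65,
                                                    native_window):
        cap = max_attainable_score(ppr65)
        assert match_profile(ppr65, native_window).score <= cap


@settings(max_examples=50, deadline=None)
@given(st.integers(0, 38),
       st.sampled_from("ACGU"))
def test_score_deterministic_under_mutation(pos_index, nt):
    """Profiling is a pure function: same window in, same score out."""
    from plsedit.fixtures import ppr65_array, ppr65_native_window
    arr, win = ppr65_array(), ppr65_native_window()
    mutated = win.mutate(pos_index - 33, nt)
    s1 = match_profile(arr, mutated).score
    s2 = match_profile(arr, mutated).score
    assert s1 == s2
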