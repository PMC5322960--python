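"""Frequency and similarity metrics against closed forms and oracles."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_coltheart_n, brute_old20, closed_form_fleiss_kappa, dp_levenshtein
from hellex.metrics import (
    EndingGroups,
    InsufficientLexiconError,
    MissingStressError,
    ZipfParams,
    colombo_ending,
    coltheart_n,
    fleiss_kappa,
    frequency_per_million,
    levenshtein,
    old20,
    old20_many,
    rime,
    rime_neighbourhood,
    stress_neighbourhood,
    syllable_frequency_table,
    zipf,
)
from hellex.syllabification import syllabify_orthographic

_AL = "αβγδεο"


def _rand_words(rng, n, lo=2, hi=8):
    return ["".join(rng.choice(_AL) for _ in range(rng.randint(lo, hi))) for _ in range(n)]


class TestZipf:
    def test_thousand_per_million(self):
        assert zipf(999, ZipfParams(1.0, 1e-9)) == pytest.approx(6.0, abs=1e-6)

    def test_zero_count_closed_form(self):
        assert zipf(0) == pytest.approx(3 - math.log10(46.9253), abs=1e-9)

    def test_one_per_million_is_three(self):
        for params in [ZipfParams(), ZipfParams(10.0, 0.5)]:
            denom = params.corpus_millions + params.types_millions
            assert zipf(denom - 1, params) == pytest.approx(3.0, abs=1e-9)

    def test_strictly_increasing_and_vectorized(self):
        vals = zipf(np.arange(0, 1000, 7))
        assert np.all(np.diff(vals) > 0)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            zipf(-1)

    def test_fpm_is_unsmoothed(self):
        assert frequency_per_million(46.89) == pytest.approx(1.0)


class TestLevenshtein:
    @pytest.mark.parametrize(
        "a,b,d",
        [("γερος", "γερος", 0), ("αρμα", "αρπα", 1), ("καμβας", "καβας", 1), ("", "αβγ", 3)],
    )
    def test_examples(self, a, b, d):
        assert levenshtein(a, b) == d

    @given(
        st.text(alphabet=_AL, max_size=8),
        st.text(alphabet=_AL, max_size=8),
        st.text(alphabet=_AL, max_size=8),
    )
    @settings(max_examples=200, deadline=None)
    def test_metric_axioms(self, a, b, c):
        assert levenshtein(a, b) == levenshtein(b, a)
        assert (levenshtein(a, b) == 0) == (a == b)
        assert levenshtein(a, c) <= levenshtein(a, b) + levenshtein(b, c)

    @given(st.text(alphabet="αβγδεζηώέ", max_size=9), st.text(alphabet="αβγδεζηώέ", max_size=9))
    @settings(max_examples=200, deadline=None)
    def test_matches_dp_oracle(self, a, b):
        assert levenshtein(a, b) == dp_levenshtein(a, b)


class TestColtheartN:
    def test_hand_example(self):
        assert coltheart_n("αβγ", {"αβδ", "δβγ", "αβγδ"}, stressed=True) == 2

    def test_self_excluded(self):
        assert coltheart_n("αβγ", {"αβγ"}) == 0

    def test_no_shared_length(self):
        assert coltheart_n("αβ", {"αβγδ", "α"}) == 0

    def test_final_sigma_folded(self):
        # γέρος vs γέροσ differ only in the sigma allograph: not neighbours
        assert coltheart_n("γερος", {"γεροσ"}) == 0

    def test_matches_brute_force(self):
        rng = random.Random(5)
        for _ in range(50):
            lex = _rand_words(rng, 30, 2, 5)
            w = lex[0]
            assert coltheart_n(w, lex, stressed=True) == brute_coltheart_n(w, lex)


class TestOld20:
    def test_all_neighbours_at_distance_one(self):
        lex = ["αβγδ" + c for c in _AL * 4][:21] + ["αβγδ"]
        assert old20("αβγδ", lex, k=21) == pytest.approx(1.0)

    def test_insufficient_lexicon_raises(self):
        with pytest.raises(InsufficientLexiconError):
            old20("αβγ", ["αβδ", "ααα"])

    def test_matches_brute_oracle_on_random_lexicons(self):
        rng = random.Random(17)
        for _ in range(30):
            lex = list(dict.fromkeys(_rand_words(rng, 40)))
            if len(lex) < 25:
                continue
            w = lex[0]
            assert old20(w, lex, k=20, stressed=True) == pytest.approx(
                brute_old20(w, lex, k=20)
            )

    def test_many_agrees_with_single(self):
        rng = random.Random(3)
        lex = list(dict.fromkeys(_rand_words(rng, 60)))
        singles = [old20(w, lex, k=20) for w in lex[:10]]
        batch = old20_many(lex[:10], lex, k=20)
        assert np.allclose(singles, batch)


class TestEndings:
    @pytest.mark.parametrize("word,expected", [("γέρος", "ερος"), ("καμβάς", "ας")])
    def test_rime(self, word, expected):
        assert rime(word) == expected

    def test_rime_needs_stress(self):
        with pytest.raises(MissingStressError):
            rime("γερος")

    @pytest.mark.parametrize(
        "word,expected", [("γυάλα", "αλα"), ("γέρος", "ερος"), ("ανθρώπου", "ωπου")]
    )
    def test_colombo_ending(self, word, expected):
        syl = syllabify_orthographic(word)
        assert colombo_ending(word, syl) == expected

    def test_colombo_undefined_for_monosyllables(self):
        syl = syllabify_orthographic("φως")
        with pytest.raises(MissingStressError):
            colombo_ending("φως", syl)


class TestStressNeighbourhood:
    def test_type_proportions(self):
        groups = stress_neighbourhood(["αλα"] * 4, [2, 2, 2, 3])
        assert groups.proportion_for("αλα", 2) == pytest.approx(0.75)
        assert groups.proportion_for("αλα", 3) == pytest.approx(0.25)

    def test_singleton_group(self):
        groups = stress_neighbourhood(["ος"], [1])
        assert groups.proportion_for("ος", 1) == 1.0

    def test_token_weighted(self):
        groups = stress_neighbourhood(["ος", "ος"], [1, 2], [10, 30])
        assert groups.proportion_for("ος", 1, "token") == pytest.approx(0.25)
        assert groups.proportion_for("ος", 2, "token") == pytest.approx(0.75)

    def test_proportions_sum_to_one(self):
        rng = random.Random(9)
        endings = [rng.choice(["α", "ος", "ση"]) for _ in range(60)]
        positions = [rng.choice([1, 2, 3]) for _ in range(60)]
        counts = [rng.randint(1, 50) for _ in range(60)]
        groups = stress_neighbourhood(endings, positions, counts)
        for e in set(endings):
            for weighting in ("type", "token"):
                assert groups.proportions(e, weighting).sum() == pytest.approx(1.0)

    def test_modal_tie_break_order(self):
        groups = EndingGroups(["α", "α"], [1, 3])
        assert groups.modal("α") == 3  # tie: antepenult precedes final


class TestRimeNeighbourhood:
    def test_singleton_is_zero(self):
        assert rime_neighbourhood("ας", 1, ["ας"], [1]) == 0

    def test_empty_lexicon(self):
        assert rime_neighbourhood("ας", 1, [], []) == 0

    def test_hand_built_lexicon_matches_brute_force(self):
        rimes = ["ας", "ας", "ας", "ερος", "ας"]
        positions = [1, 1, 2, 2, 1]
        expected = sum(1 for r, p in zip(rimes, positions) if r == "ας" and p == 1) - 1
        assert rime_neighbourhood("ας", 1, rimes, positions) == expected == 2


class TestSyllableFrequencies:
    def test_one_word_lexicon(self):
        tab = syllable_frequency_table([["πα", "τέ", "ρας"]], [2], stressed=True)
        assert (tab["type_count"] == 1).all() and (tab["token_count"] == 2).all()

    def test_shared_syllable_counts_types(self):
        tab = syllable_frequency_table([["πα", "ρα"], ["πα", "λο"]], [1, 5], stressed=True)
        assert tab.loc["πα", "type_count"] == 2
        assert tab.loc["πα", "token_count"] == 6

    def test_stress_stripping_merges_units(self):
        stressed = syllable_frequency_table([["τέ"], ["τε"]], [1, 1], stressed=True)
        stripped = syllable_frequency_table([["τέ"], ["τε"]], [1, 1], stressed=False)
        assert len(stressed) == 2 and len(stripped) == 1


class TestFleissKappa:
    def test_perfect_agreement(self):
        assert fleiss_kappa([[3, 0], [0, 3], [3, 0]]) == pytest.approx(1.0)

    def test_two_by_two_disagreement_closed_form(self):
        table = np.array([[1, 1], [1, 1]])
        assert fleiss_kappa(table) == pytest.approx(closed_form_fleiss_kappa(table))
        assert fleiss_kappa(table) == pytest.approx(-1.0)

    def test_matches_closed_form_on_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n_items, n_cat, n_raters = rng.integers(2, 10), rng.integers(2, 5), 4
            table = rng.multinomial(n_raters, np.ones(n_cat) / n_cat, size=n_items)
            expected = closed_form_fleiss_kappa(table)
            if math.isclose((table.sum(0) / table.sum()) @ (table.sum(0) / table.sum()), 1.0):
                continue
            assert fleiss_kappa(table) == pytest.approx(expected)

    def test_random_ratings_give_near_zero_kappa(self):
        rng = np.random.default_rng(7)
        table = rng.multinomial(6, [0.25] * 4, size=3000)
        assert abs(fleiss_kappa(table)) < 0.02

    def test_degenerate_single_category_is_nan(self):
        assert math.isnan(fleiss_kappa([[3, 0], [3, 0]]))

    def test_unequal_rater_counts_rejected(self):
        with pytest.raises(ValueError):
            fleiss_kappa([[3, 0], [2, 0]])
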