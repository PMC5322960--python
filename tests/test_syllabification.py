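"""Both syllabifiers, onset legality, and CiV disambiguation."""

import numpy as np
import pytest

from hellex.phonology import PhoneSeq, transcribe
from hellex.syllabification import (
    CiVResolver,
    CiVSite,
    CiVStats,
    ClusterRuleSet,
    ConfigurationError,
    NoNucleusError,
    Syllabification,
    UnresolvedCiVError,
    build_onset_inventory,
    civ_majority_table,
    cluster_is_legal_onset,
    default_onset_inventory,
    disambiguate_civ,
    find_civ_sites,
    syllabify_orthographic,
    syllabify_phonological,
)


@pytest.fixture(scope="module")
def rules():
    return ClusterRuleSet.strict()


class TestOnsetInventory:
    def test_maximal_prefixes_with_closure(self):
        inv = build_onset_inventory(["θρόνος", "πατέρας"])
        assert inv == {"θρ", "θ", "π"}

    def test_vowel_initial_contributes_nothing(self):
        assert build_onset_inventory(["αέρας"]) == set()

    def test_three_consonant_cluster_prefix_closure(self):
        assert build_onset_inventory(["στρατός"]) == {"στρ", "στ", "σ"}

    def test_default_inventory_contains_singles_and_common_clusters(self):
        inv = default_onset_inventory()
        assert {"θ", "θρ", "στρ", "μπ"} <= inv
        assert "σσ" not in inv  # no Greek word begins with a double consonant


class TestOrthographicSyllabification:
    @pytest.mark.parametrize(
        "word,expected",
        [
            ("θάλασσα", "θά-λασ-σα"),      # σσ splits
            ("πατέρας", "πα-τέ-ρας"),      # singles always onsets
            ("άνθρωπος", "άν-θρω-πος"),    # νθρ unattested, θρ attested
            ("γέρος", "γέ-ρος"),
            ("στρατός", "στρα-τός"),
            ("καμβάς", "καμ-βάς"),          # μβ not an attested onset
            ("νιώθω", "νιώ-θω"),            # merged CiV syllable
            ("κυάνιο", "κυ-ά-νι-ο"),        # full-vowel CiV parses
        ],
    )
    def test_examples(self, word, expected):
        assert syllabify_orthographic(word).hyphenated() == expected

    def test_concatenation_invariant(self, small_lexicon):
        for word in small_lexicon["word"]:
            syl = syllabify_orthographic(word)
            assert syl.flat() == word

    def test_stressed_unit_contains_the_tonos(self):
        syl = syllabify_orthographic("πατέρας")
        assert syl.stressed_unit == 2 and "έ" in syl.units[1]

    def test_no_vowel_raises(self):
        with pytest.raises(NoNucleusError):
            syllabify_orthographic("γκρ")

    def test_recursive_split_variant(self):
        # with an artificial inventory lacking θρ the remainder splits again
        inv = {"θ", "ν", "ρ", "π"}
        once = syllabify_orthographic("άνθρωπος", inv)
        twice = syllabify_orthographic("άνθρωπος", inv, recursive=True)
        assert once.hyphenated() == "άν-θρωπ-ος" or once.n_units == 3
        assert twice.n_units == 3


class TestClusterLegality:
    @pytest.mark.parametrize(
        "cluster,legal",
        [
            (("m", "v"), False),   # nasal+fricative fails both scales
            (("r", "m"), False),   # liquid-initial override
            (("r", "p"), False),
            (("p",), True),        # single consonant
            (("θ", "r"), True),    # fricative + liquid rises on manner
            (("p", "s"), True),
            (("f", "t"), True),    # labial place leftmost of coronal
            (("k", "t"), False),   # velar place not leftmost of coronal
            (("s", "t"), False),   # s + stop violates the manner scale
            (("m", "n"), True),    # labial nasal leftmost of coronal nasal
        ],
    )
    def test_verdicts(self, cluster, legal, rules):
        assert bool(cluster_is_legal_onset(cluster, rules)) is legal

    def test_verdict_carries_a_reason(self, rules):
        v = cluster_is_legal_onset(("m", "v"), rules)
        assert not v.legal and "scale" in v.reason

    def test_whitelist_precedes_scales(self, rules):
        permissive = ClusterRuleSet(
            profiles=rules.profiles, whitelist={("s", "t")},
            heterosyllabic_overrides=set(rules.heterosyllabic_overrides),
        )
        assert cluster_is_legal_onset(("s", "t"), permissive).legal

    def test_unknown_phone_is_a_configuration_error(self, rules):
        with pytest.raises(ConfigurationError):
            cluster_is_legal_onset(("q",), rules)

    def test_permissive_preset_flips_nasal_liquid_verdicts(self):
        iplr = ClusterRuleSet.iplr_style()
        for cl in [("m", "v"), ("r", "m"), ("r", "p")]:
            assert cluster_is_legal_onset(cl, iplr).legal

    def test_rule_roundtrip_through_json(self, tmp_path, rules):
        path = tmp_path / "rules.json"
        rules.to_json(path)
        back = ClusterRuleSet.from_json(path)
        assert back.profiles == rules.profiles
        assert back.strict_nasal_liquid == rules.strict_nasal_liquid


class TestPhonologicalSyllabification:
    @pytest.mark.parametrize(
        "word,expected",
        [
            ("καμβάς", "kam-'vas"),
            ("άρμα", "'ar-ma"),
            ("άρπα", "'ar-pa"),
            ("γυάλα", "'ʝa-la"),
            ("κυάνιο", "ci-'a-ni-o"),
            ("άνθρωπος", "'an-θro-pos"),
            ("στρατός", "stra-'tos"),   # word-initial run attaches wholly
        ],
    )
    def test_examples(self, word, expected, rules):
        syl = syllabify_phonological(transcribe(word), rules)
        assert syl.hyphenated() == expected

    def test_concatenation_and_stress_unit(self, rules):
        seq = transcribe("διαβάτης")
        syl = syllabify_phonological(seq, rules)
        assert syl.flat() == seq.phones
        assert syl.stressed_unit == 2

    def test_no_vowel_raises(self, rules):
        with pytest.raises(NoNucleusError):
            syllabify_phonological(PhoneSeq(("s", "t")), rules)

    def test_maximality_on_random_phone_runs(self, rules):
        """The coda's last consonant plus the chosen onset is never legal."""
        rng = np.random.default_rng(42)
        cons = ["p", "t", "k", "s", "f", "θ", "x", "v", "δ", "γ", "m", "n", "l", "r", "z"]
        for _ in range(300):
            phones = ["a"]
            for _ in range(rng.integers(1, 4)):
                phones += list(rng.choice(cons, rng.integers(0, 4)))
                phones.append("o")
            syl = syllabify_phonological(PhoneSeq(tuple(phones)), rules)
            assert syl.flat() == tuple(phones)
            units = syl.units
            for prev, unit in zip(units, units[1:]):
                onset = []
                for p in unit:
                    if p in ("a", "o"):
                        break
                    onset.append(p)
                if len(onset) > 1:
                    assert cluster_is_legal_onset(onset, rules).legal
                coda_last = None
                for p in reversed(prev):
                    if p in ("a", "o"):
                        break
                    coda_last = p
                    break
                if coda_last is not None and onset:
                    assert not cluster_is_legal_onset([coda_last] + onset, rules).legal


class TestCiV:
    def test_sites_found_with_cluster_labels(self):
        sites = find_civ_sites("κυάνιο")
        assert [(s.cluster, s.i_letters) for s in sites] == [("υα", "υ"), ("ιο", "ι")]

    def test_stressed_i_is_not_a_site(self):
        assert find_civ_sites("βιολί") == [
            CiVSite(start=1, i_letters="ι", v_letters="ο", cluster="ιο")
        ]
        assert find_civ_sites("ασθενείας") == []  # tonos on the i-group blocks
        assert find_civ_sites("άδειος")[0].cluster == "ειο"

    def test_vowel_initial_iv_is_not_a_site(self):
        assert find_civ_sites("ιατρός") == []

    def test_majority_counting_and_tie(self):
        # 9 of 10 carriers split ιο -> majority two; a 5-5 tie -> two
        stats = CiVStats("ιο", n_one_syllable=1, n_two_syllables=9)
        assert stats.majority == 2
        assert CiVStats("υο", 5, 5).majority == 2
        assert CiVStats("ια", 7, 3).majority == 1

    def test_civ_majority_table_from_gold_parses(self):
        parsed = [
            ("νιώθω", Syllabification(["νιώ", "θω"], 1)),
            ("κυάνιο", Syllabification(["κυ", "ά", "νι", "ο"], 2)),
        ]
        table = civ_majority_table(parsed)
        assert table["ιω"].n_one_syllable == 1
        assert table["ιο"].n_two_syllables == 1
        assert table["υα"].n_two_syllables == 1

    def test_exception_wins_over_majority(self):
        site = CiVSite(1, "ι", "ο", "ιο")
        stats = {"ιο": CiVStats("ιο", 0, 10)}
        decision = disambiguate_civ("νιο", site, stats, {"νιο": 1})
        assert decision.parse == 1 and decision.source == "exception"

    def test_unresolved_without_default_raises(self):
        site = CiVSite(1, "ι", "ο", "ιο")
        with pytest.raises(UnresolvedCiVError):
            disambiguate_civ("νιο", site, {}, {})
        assert disambiguate_civ("νιο", site, {}, {}, default=2).source == "default"

    def test_resolver_changes_the_parse(self):
        one = CiVResolver(default=1)
        two = CiVResolver(default=2)
        assert syllabify_orthographic("νιώθω", civ=one).n_units == 2
        assert syllabify_orthographic("νιώθω", civ=two).n_units == 3


class TestCrossParserAgreement:
    def test_unit_counts_agree_on_civ_free_words(self, small_lexicon, rules):
        inv = default_onset_inventory() | build_onset_inventory(small_lexicon["word"])
        for word in small_lexicon["word"]:
            orth = syllabify_orthographic(word, inv)
            phon = syllabify_phonological(transcribe(word), rules)
            assert orth.n_units == phon.n_units
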