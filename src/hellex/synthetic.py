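"""Seeded generator of Greek-like lexicons with controlled structure.

Words are composed from attested syllable parts (onset + nucleus, plus
an optional word-final coda), so a gold syllabification and a gold
transcription exist *by construction* and the parsers can be tested
against them.  The generator plants the statistical structure the
corpus analyses presuppose:

* every polysyllable draws an *ending* (pre-final nucleus + final
  syllable) from a per-part-of-speech inventory; each ending has a modal
  stress position and the word's stress falls on it with probability
  ``theta`` (the ending-consistency parameter), otherwise uniformly on
  the other positions of the Greek three-syllable window;
* part-of-speech categories carry distinct stress profiles (an
  adjective-like category disfavouring the pre-final position);
* token counts follow a Zipfian rank-frequency law.

Every generated word is CiV-free and uses only phonotactically legal
onsets, so both syllabifiers recover the generative parse exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["SyntheticConfig", "GenerationError", "generate"]


class GenerationError(RuntimeError):
    """The configuration cannot produce the requested lexicon."""


# (letters, phones) syllable parts; clusters are attested word onsets
# that are also scale-legal, so orthographic and phonological parses agree
_ONSETS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("β", ("v",)), ("γ", ("γ",)), ("δ", ("δ",)), ("ζ", ("z",)), ("θ", ("θ",)),
    ("κ", ("k",)), ("λ", ("l",)), ("μ", ("m",)), ("ν", ("n",)), ("π", ("p",)),
    ("ρ", ("r",)), ("σ", ("s",)), ("τ", ("t",)), ("φ", ("f",)), ("χ", ("x",)),
    ("ψ", ("p", "s")), ("ξ", ("k", "s")),
    ("πρ", ("p", "r")), ("πλ", ("p", "l")), ("τρ", ("t", "r")),
    ("κρ", ("k", "r")), ("κλ", ("k", "l")), ("θρ", ("θ", "r")),
    ("βρ", ("v", "r")), ("γρ", ("γ", "r")), ("δρ", ("δ", "r")),
    ("φλ", ("f", "l")), ("φρ", ("f", "r")), ("χρ", ("x", "r")),
)

_NUCLEI: tuple[tuple[str, str], ...] = (
    ("α", "a"), ("ε", "ε"), ("ο", "o"), ("ω", "o"),
    ("ι", "i"), ("η", "i"), ("ου", "u"), ("αι", "ε"),
)

_FRONT_PHONES = ("ε", "i")
_VELAR_PALATAL = {"κ": "c", "χ": "ç", "γ": "ʝ"}

_TONOS = {"α": "ά", "ε": "έ", "η": "ή", "ι": "ί", "ο": "ό", "υ": "ύ", "ω": "ώ"}

# category-flavoured final syllables (letters only; phones derived)
_FINALS: Mapping[str, tuple[str, ...]] = {
    "noun": ("τος", "νος", "ρος", "μος", "λος", "ρας", "νας", "τας",
             "της", "νης", "μα", "να", "ρα", "λα", "τα", "κος"),
    "adjective": ("κος", "ρος", "νος", "λος", "δης", "ρης", "νη", "λη",
                  "κη", "ρο", "νο", "λο"),
    "verb": ("ζω", "νω", "ρω", "θω", "φω", "βω", "χνω", "ζαν", "ναν", "ραν"),
}


@dataclass
class SyntheticConfig:
    """Study conditions of the generated lexicon.

    ``theta`` is the probability mass of each ending's modal stress
    position among its carriers (the ending-consistency parameter,
    0.5–1).  The syllable-length distribution and the part-of-speech
    mixture default to values typical of a Greek lemma database; the
    stress profiles give each category its own distribution of modal
    positions, with the adjective-like category disfavouring the
    pre-final position.
    """

    n_words: int = 10_000
    theta: float = 0.9
    seed: int = 0
    syllable_dist: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.008, 2: 0.105, 3: 0.24, 4: 0.30, 5: 0.22, 6: 0.094, 7: 0.033}
    )
    pos_mixture: Mapping[str, float] = field(
        default_factory=lambda: {"noun": 0.59, "adjective": 0.26, "verb": 0.15}
    )
    stress_profiles: Mapping[str, Mapping[int, float]] = field(
        default_factory=lambda: {
            "noun": {1: 0.25, 2: 0.45, 3: 0.30},
            "verb": {1: 0.15, 2: 0.55, 3: 0.30},
            "adjective": {1: 0.30, 2: 0.15, 3: 0.55},
        }
    )
    zipf_exponent: float = 1.05
    zipf_scale: float = 1_000_000.0
    n_endings_per_category: int = 40
    monosyllable_coda_prob: float = 0.5  # word-final ς on monosyllables

    def __post_init__(self):
        if not 0.5 <= self.theta <= 1.0:
            raise GenerationError("theta must lie in [0.5, 1]")
        if self.n_words < 1:
            raise GenerationError("n_words must be positive")


def _stress_nucleus(nucleus: str) -> str:
    """Place the tonos on the nucleus (second letter of a digraph)."""
    return nucleus[:-1] + _TONOS[nucleus[-1]]


def _onset_phones(onset: str, nucleus_phone: str, phones: tuple[str, ...]) -> tuple[str, ...]:
    """Palatalize a final velar onset consonant before a front vowel."""
    if onset and onset[-1] in _VELAR_PALATAL and nucleus_phone in _FRONT_PHONES:
        repl = {"k": "c", "x": "ç", "γ": "ʝ"}
        return phones[:-1] + (repl[phones[-1]],)
    return phones


@dataclass(frozen=True)
class _Ending:
    pre_nucleus: str        # letters of the pre-final syllable's nucleus
    pre_nucleus_phone: str
    final_letters: str
    final_phones: tuple[str, ...]
    modal: int              # planted modal stress position
    category: str

    @property
    def colombo(self) -> str:
        return self.pre_nucleus + self.final_letters


def _final_syllable_phones(letters: str) -> tuple[str, ...]:
    """Phones of a final syllable from the category tables (C+V(+coda))."""
    phone_map = {"ζ": "z", "ν": "n", "ρ": "r", "θ": "θ", "φ": "f", "β": "v",
                 "τ": "t", "μ": "m", "λ": "l", "κ": "k", "δ": "δ", "χ": "x",
                 "σ": "s", "ς": "s"}
    vowel_map = dict(_NUCLEI)
    out: list[str] = []
    i = 0
    while i < len(letters):
        pair = letters[i : i + 2]
        if pair in vowel_map:
            out.append(vowel_map[pair])
            i += 2
            continue
        ch = letters[i]
        if ch in vowel_map:
            out.append(vowel_map[ch])
        else:
            out.append(phone_map[ch])
        i += 1
    # palatalize velar directly before a front vowel (e.g. κη)
    for j in range(len(out) - 1):
        if out[j] in ("k", "x", "γ") and out[j + 1] in _FRONT_PHONES:
            out[j] = {"k": "c", "x": "ç", "γ": "ʝ"}[out[j]]
    return tuple(out)


def _build_endings(config: SyntheticConfig, rng: np.random.Generator) -> list[_Ending]:
    endings: list[_Ending] = []
    seen: set[str] = set()
    for category, finals in _FINALS.items():
        profile = config.stress_profiles[category]
        positions = np.array(sorted(profile))
        probs = np.array([profile[p] for p in positions], dtype=float)
        probs = probs / probs.sum()
        combos = [(nu, fi) for nu, _ in _NUCLEI for fi in finals]
        combos = [combos[j] for j in rng.permutation(len(combos))]
        taken = 0
        for nu, fi in combos:
            if taken >= config.n_endings_per_category:
                break
            colombo = nu + fi
            if colombo in seen:
                continue
            seen.add(colombo)
            modal = int(rng.choice(positions, p=probs))
            nu_phone = dict(_NUCLEI)[nu]
            endings.append(
                _Ending(nu, nu_phone, fi, _final_syllable_phones(fi), modal, category)
            )
            taken += 1
        if taken < config.n_endings_per_category:
            raise GenerationError(f"cannot build {config.n_endings_per_category} endings for {category}")
    return endings


def generate(config: SyntheticConfig | None = None) -> pd.DataFrame:
    """Generate a synthetic lexicon table with gold annotations.

    Returns a DataFrame with columns ``word``, ``frequency_count``,
    ``pos_primary`` and gold columns: hyphenated orthographic and
    phonological syllabifications, compact transcription, stress
    position, syllable count, and the planted Colombo ending.  The same
    configuration (including seed) reproduces the identical table.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)

    lengths = np.array(sorted(config.syllable_dist))
    lprobs = np.array([config.syllable_dist[k] for k in lengths], dtype=float)
    lprobs /= lprobs.sum()
    cats = sorted(config.pos_mixture)
    cprobs = np.array([config.pos_mixture[c] for c in cats], dtype=float)
    cprobs /= cprobs.sum()
    endings = _build_endings(config, rng)
    by_cat: dict[str, list[_Ending]] = {}
    for e in endings:
        by_cat.setdefault(e.category, []).append(e)

    lengths_ge3 = lengths[lengths >= 3]
    lprobs_ge3 = lprobs[lengths >= 3]
    lprobs_ge3 = lprobs_ge3 / lprobs_ge3.sum()

    rows = []
    seen_words: set[str] = set()
    max_tries = config.n_words * 50
    tries = 0
    while len(rows) < config.n_words:
        tries += 1
        if tries > max_tries:
            raise GenerationError(
                f"could not generate {config.n_words} unique words in {max_tries} draws"
            )
        category = str(rng.choice(cats, p=cprobs))
        n_syll = int(rng.choice(lengths, p=lprobs))

        if n_syll == 1:
            oi = int(rng.integers(len(_ONSETS)))
            ni = int(rng.integers(len(_NUCLEI)))
            onset, ophones = _ONSETS[oi]
            nucleus, nphone = _NUCLEI[ni]
            word = onset + nucleus
            phones = _onset_phones(onset, nphone, ophones) + (nphone,)
            if rng.random() < config.monosyllable_coda_prob:
                word += "ς"
                phones += ("s",)
            if word in seen_words:
                continue
            seen_words.add(word)
            rows.append(
                dict(word=word, pos_primary=category, gold_orth=[word],
                     gold_phones=[phones], gold_stress_position=0,
                     gold_n_syllables=1, gold_ending=None)
            )
            continue

        ending = by_cat[category][int(rng.integers(len(by_cat[category])))]
        if ending.modal == 3 and n_syll < 3:
            n_syll = int(rng.choice(lengths_ge3, p=lprobs_ge3))
        valid = list(range(1, min(3, n_syll) + 1))
        if rng.random() < config.theta:
            position = ending.modal
        else:
            others = [p for p in valid if p != ending.modal]
            position = int(others[int(rng.integers(len(others)))])

        syllables: list[str] = []       # letters, unstressed
        syl_phones: list[tuple[str, ...]] = []
        for _ in range(n_syll - 2):
            onset, ophones = _ONSETS[int(rng.integers(len(_ONSETS)))]
            nucleus, nphone = _NUCLEI[int(rng.integers(len(_NUCLEI)))]
            syllables.append(onset + nucleus)
            syl_phones.append(_onset_phones(onset, nphone, ophones) + (nphone,))
        onset, ophones = _ONSETS[int(rng.integers(len(_ONSETS)))]
        syllables.append(onset + ending.pre_nucleus)
        syl_phones.append(
            _onset_phones(onset, ending.pre_nucleus_phone, ophones)
            + (ending.pre_nucleus_phone,)
        )
        syllables.append(ending.final_letters)
        syl_phones.append(ending.final_phones)

        stressed_unit = n_syll - position + 1  # 1-based
        styled = list(syllables)
        k = stressed_unit - 1
        unit = styled[k]
        # tonos on the unit's nucleus: the last vowel run (before any coda)
        end = len(unit)
        while end > 0 and unit[end - 1] not in "αεηιουω":
            end -= 1
        start = end
        while start > 0 and unit[start - 1] in "αεηιουω":
            start -= 1
        styled[k] = unit[:start] + _stress_nucleus(unit[start:end]) + unit[end:]

        word = "".join(styled)
        if word in seen_words:
            continue
        seen_words.add(word)
        rows.append(
            dict(word=word, pos_primary=category, gold_orth=styled,
                 gold_phones=syl_phones, gold_stress_position=position,
                 gold_n_syllables=n_syll, gold_ending=ending.colombo)
        )

    # Zipfian token counts over the (randomly ordered) words
    ranks = np.arange(1, len(rows) + 1, dtype=float)
    counts = np.maximum(1, np.floor(config.zipf_scale / ranks**config.zipf_exponent))

    df = pd.DataFrame(
        {
            "word": [r["word"] for r in rows],
            "frequency_count": counts,
            "pos_primary": [r["pos_primary"] for r in rows],
            "gold_orth_syllables": ["-".join(r["gold_orth"]) for r in rows],
            "gold_phon_syllables": [
                "-".join("".join(p) for p in r["gold_phones"]) for r in rows
            ],
            "gold_transcription": ["".join("".join(p) for p in r["gold_phones"]) for r in rows],
            "gold_stress_position": [r["gold_stress_position"] for r in rows],
            "gold_n_syllables": [r["gold_n_syllables"] for r in rows],
            "gold_ending": [r["gold_ending"] for r in rows],
        }
    )
    return df
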