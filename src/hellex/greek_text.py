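"""Greek text model: normalization, letter classification, stress diacritics.

Modern Greek lowercase orthography marks lexical stress with the acute
accent (*tonos*) on exactly one vowel of every polysyllabic word.  All
downstream machinery (syllabification, transcription, metrics) assumes
words in a single canonical form: Unicode NFC, so accented vowels are
single code points and letter indices match naive letter counts.

The functions here establish and police that canonical form.
"""

from __future__ import annotations

import unicodedata
import warnings

__all__ = [
    "GreekTextError",
    "NonGreekCharacterError",
    "MalformedWordError",
    "VOWEL_LETTERS",
    "CONSONANT_LETTERS",
    "VOWEL_DIGRAPHS",
    "CONSONANT_DIGRAPHS",
    "normalize",
    "strip_stress",
    "stressed_vowel_index",
    "has_tonos",
    "is_vowel",
    "is_consonant",
    "base_letter",
    "fold_sigma",
]


class GreekTextError(ValueError):
    """Base class for Greek text-model errors."""


class NonGreekCharacterError(GreekTextError):
    """Input contains a character outside the Greek alphabet."""

    def __init__(self, char: str, position: int):
        self.char = char
        self.position = position
        super().__init__(f"non-Greek character {char!r} at position {position}")


class MalformedWordError(GreekTextError):
    """Word violates a structural invariant (e.g. two stress diacritics)."""


# 24-letter alphabet (lowercase) plus the word-final sigma allograph.
_PLAIN_VOWELS = "αεηιουω"
_PLAIN_CONSONANTS = "βγδζθκλμνξπρστφχψ"

# tonos-bearing vowels, dialytika vowels, and dialytika+tonos vowels
_TONOS = dict(zip("άέήίόύώ", _PLAIN_VOWELS.replace("ι", "ι")))
_TONOS = {"ά": "α", "έ": "ε", "ή": "η", "ί": "ι", "ό": "ο", "ύ": "υ", "ώ": "ω"}
_DIALYTIKA = {"ϊ": "ι", "ϋ": "υ"}
_DIALYTIKA_TONOS = {"ΐ": "ϊ", "ΰ": "ϋ"}  # strip_stress keeps the dialytika

#: all letters that count as vowels (any diacritic state)
VOWEL_LETTERS = frozenset(
    _PLAIN_VOWELS + "".join(_TONOS) + "".join(_DIALYTIKA) + "".join(_DIALYTIKA_TONOS)
)
#: all consonant letters, final sigma included
CONSONANT_LETTERS = frozenset(_PLAIN_CONSONANTS + "ς")

#: two-letter vowel graphemes read as a single vowel sound
VOWEL_DIGRAPHS = frozenset({"αι", "ει", "οι", "ου", "υι"})
#: two-letter consonant graphemes with a single (or nasal+stop) realization
CONSONANT_DIGRAPHS = frozenset({"μπ", "ντ", "γκ", "γγ", "τσ", "τζ"})

_ALL_GREEK = VOWEL_LETTERS | CONSONANT_LETTERS

_TONOS_TO_PLAIN = dict(_TONOS)
_TONOS_TO_PLAIN.update(_DIALYTIKA_TONOS)

_BASE = dict(_TONOS)
_BASE.update(_DIALYTIKA)
_BASE.update({"ΐ": "ι", "ΰ": "υ"})


def base_letter(ch: str) -> str:
    """Letter with every diacritic removed (``ά`` → ``α``, ``ΐ`` → ``ι``)."""
    return _BASE.get(ch, ch)


def has_tonos(ch: str) -> bool:
    """True if the letter bears the acute stress diacritic."""
    return ch in _TONOS_TO_PLAIN


def is_vowel(ch: str) -> bool:
    return ch in VOWEL_LETTERS


def is_consonant(ch: str) -> bool:
    return ch in CONSONANT_LETTERS


def fold_sigma(word: str) -> str:
    """Map final sigma to medial sigma for internal matching.

    The word-final allograph ``ς`` is the same letter as ``σ``; similarity
    metrics and cluster rules must not treat the two as different symbols.
    """
    return word.replace("ς", "σ")


def normalize(text: str, lowercase: bool = True) -> str:
    """Return the canonical form of a raw Greek word.

    The canonical form is NFC-composed (accented vowels are single code
    points), optionally lowercased, with a word-final ``σ`` produced by
    lowercasing mapped back to ``ς``.  Raises
    :class:`NonGreekCharacterError` for anything outside the Greek
    alphabet and :class:`MalformedWordError` for words carrying more than
    one tonos.
    """
    word = unicodedata.normalize("NFC", text.strip())
    if not word:
        raise GreekTextError("empty word after whitespace stripping")
    if lowercase and word != word.lower():
        warnings.warn(
            "uppercase input lowercased; uppercase Greek carries no stress diacritics",
            stacklevel=2,
        )
        word = word.lower()
        # str.lower is context-free: trailing Σ comes out as medial σ
        if word.endswith("σ"):
            word = word[:-1] + "ς"
    for i, ch in enumerate(word):
        if ch not in _ALL_GREEK:
            raise NonGreekCharacterError(ch, i)
    n_tonos = sum(has_tonos(ch) for ch in word)
    if n_tonos > 1:
        raise MalformedWordError(f"{word!r} carries {n_tonos} stress diacritics")
    return word


def strip_stress(word: str) -> str:
    """Remove the tonos, keeping dialytika; idempotent and length-preserving."""
    return "".join(_TONOS_TO_PLAIN.get(ch, ch) for ch in word)


def stressed_vowel_index(word: str) -> int | None:
    """0-based index of the tonos-bearing vowel, or None if unstressed.

    Monosyllables may legitimately lack a tonos, so None is a value, not
    an error; two diacritics are a malformed word.
    """
    hits = [i for i, ch in enumerate(word) if has_tonos(ch)]
    if not hits:
        return None
    if len(hits) > 1:
        raise MalformedWordError(f"{word!r} carries {len(hits)} stress diacritics")
    return hits[0]
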