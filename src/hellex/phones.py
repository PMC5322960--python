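"""Phone inventory for Modern Greek transcriptions.

Symbols follow the convention common in Greek psycholinguistic resources
(δ, γ, θ, ε, x as printed there) rather than strict IPA; an export
mapping to IPA is provided.  Affricates ``ts``/``dz`` are single phones.
"""

from __future__ import annotations

#: vowel phones ("e" accepted as a variant of "ε" on input)
VOWEL_PHONES = frozenset({"a", "ε", "e", "i", "o", "u"})

#: consonant phones
CONSONANT_PHONES = frozenset(
    {
        "p", "t", "k", "c", "b", "d", "g",            # stops
        "ts", "dz",                                    # affricates
        "f", "θ", "x", "ç", "v", "δ", "γ", "z", "ʝ", "s",  # fricatives
        "m", "n", "ɲ", "ŋ", "ɱ",                       # nasals
        "l", "ʎ", "r",                                 # liquids
    }
)

ALL_PHONES = VOWEL_PHONES | CONSONANT_PHONES

#: voiced consonants (drives σ-voicing and the voicing legality scale)
VOICED_CONSONANTS = frozenset(
    {"b", "d", "g", "dz", "v", "δ", "γ", "z", "ʝ", "m", "n", "ɲ", "ŋ", "ɱ", "l", "ʎ", "r"}
)

#: nasal → homorganic voiced stop pairs simplified by dropping the nasal
HOMORGANIC_NASAL_STOP = {("m", "b"), ("n", "d"), ("ŋ", "g")}

#: resource-style symbol → IPA
TO_IPA = {"δ": "ð", "γ": "ɣ", "ε": "e", "ts": "t͡s", "dz": "d͡z", "ç": "ç"}


def is_vowel_phone(p: str) -> bool:
    return p in VOWEL_PHONES


def to_ipa(phones) -> list[str]:
    """Map a phone sequence from resource-style symbols to IPA symbols."""
    return [TO_IPA.get(p, p) for p in phones]
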