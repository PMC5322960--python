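"""Rule-based grapheme-to-phoneme transcription of Modern Greek.

Greek orthography is highly consistent in the print-to-sound direction,
so a compact ordered rule table (longest grapheme first) transcribes a
word deterministically once one source of ambiguity is settled: the CiV
pattern, where an unstressed i-sounding grapheme before another vowel is
either a full [i] (two syllables) or is consumed into a glide /
palatalized consonant (one syllable).  That decision is supplied by the
syllabification layer (majority table + exception lexicon) and threaded
through here.

The symbol set is the resource style used by Greek lexical databases
(δ, γ, θ, ε); :func:`hellex.phones.to_ipa` maps it to IPA.
"""

from __future__ import annotations

from dataclasses import dataclass

from .greek_text import (
    GreekTextError,
    base_letter,
    has_tonos,
    is_consonant,
    is_vowel,
)
from .phones import (
    ALL_PHONES,
    HOMORGANIC_NASAL_STOP,
    VOICED_CONSONANTS,
    VOWEL_PHONES,
)
from .phones import to_ipa as _phones_to_ipa
from .syllabification import CiVResolver, Nucleus, parse_nuclei

__all__ = [
    "UnmappableGraphemeError",
    "PhoneSeq",
    "transcribe",
    "simplify_nasals",
    "comparison_normalize",
    "parse_transcription",
]


class UnmappableGraphemeError(GreekTextError):
    def __init__(self, grapheme: str, position: int):
        self.grapheme = grapheme
        self.position = position
        super().__init__(f"no phone mapping for {grapheme!r} at position {position}")


@dataclass(frozen=True)
class PhoneSeq:
    """Ordered phone symbols with at most one stress marker.

    ``stress_index`` addresses the stressed vowel phone (None for
    unstressed words, e.g. monosyllables written without a tonos).
    """

    phones: tuple[str, ...]
    stress_index: int | None = None

    def __post_init__(self):
        for p in self.phones:
            if p not in ALL_PHONES:
                raise ValueError(f"unknown phone symbol {p!r}")
        if self.stress_index is not None:
            if not 0 <= self.stress_index < len(self.phones):
                raise ValueError("stress_index out of range")
            if self.phones[self.stress_index] not in VOWEL_PHONES:
                raise ValueError("stress_index must address a vowel phone")

    @property
    def n_vowels(self) -> int:
        return sum(p in VOWEL_PHONES for p in self.phones)

    def to_string(self, stress_mark: str = "'") -> str:
        """Plain join with the stress mark before the stressed vowel."""
        parts = []
        for i, p in enumerate(self.phones):
            if self.stress_index == i and stress_mark:
                parts.append(stress_mark)
            parts.append(p)
        return "".join(parts)

    def to_ipa(self) -> "PhoneSeq":
        return PhoneSeq(tuple(_phones_to_ipa(self.phones)), self.stress_index)

    def __len__(self) -> int:
        return len(self.phones)


# letter-level voicing, used for σ-voicing and αυ/ευ realization
_VOICED_LETTERS = frozenset("βγδζλρμν")
_DIGRAPH_VOICING = {"μπ": True, "ντ": True, "γκ": True, "γγ": True, "τζ": True, "τσ": False}

_SINGLE_VOWEL = {"α": "a", "ε": "ε", "η": "i", "ι": "i", "ο": "o", "υ": "i", "ω": "o"}
_VOWEL_DIGRAPH_PHONE = {"ου": "u", "αι": "ε", "ει": "i", "οι": "i", "υι": "i"}
_PLAIN_CONSONANT = {
    "β": "v", "δ": "δ", "ζ": "z", "θ": "θ", "λ": "l", "μ": "m",
    "ν": "n", "π": "p", "ρ": "r", "σ": "s", "ς": "s", "τ": "t", "φ": "f",
}
_VELAR = {"κ": ("k", "c"), "χ": ("x", "ç"), "γ": ("γ", "ʝ")}
_PALATAL_OF = {"n": "ɲ", "l": "ʎ", "k": "c", "x": "ç", "γ": "ʝ"}


def _next_letter_voiced(word: str, i: int) -> bool:
    """Voicing of what follows position i (for σ-voicing / αυ-ευ)."""
    if i >= len(word):
        return False
    pair = base_letter(word[i]) + (base_letter(word[i + 1]) if i + 1 < len(word) else "")
    if pair in _DIGRAPH_VOICING:
        return _DIGRAPH_VOICING[pair]
    ch = base_letter(word[i])
    return is_vowel(word[i]) or ch in _VOICED_LETTERS


def transcribe(
    word: str,
    civ: CiVResolver | None = None,
    simplify: bool = True,
) -> PhoneSeq:
    """Transcribe a normalized, tonos-marked word into phones.

    ``civ`` resolves ambiguous CiV sites (the shipped resolver is used
    when omitted).  With ``simplify`` (default) nasal + homorganic voiced
    stop pairs lose the nasal, so the output never contains [mb], [nd]
    or [ŋg]; pass ``simplify=False`` to keep the allophonic nasal forms.
    """
    nuclei = parse_nuclei(word, civ)
    # letter position → ("glide"| "vowel", Nucleus) for group starts
    group_role: dict[int, tuple[str, Nucleus]] = {}
    for nu in nuclei:
        if nu.merged_civ:
            group_role[nu.start] = ("glide", nu)
            group_role[nu.core_start] = ("vowel", nu)
        else:
            group_role[nu.start] = ("vowel", nu)

    phones: list[str] = []
    stress: list[int] = []

    def front_ahead(i: int) -> bool:
        """Is the next vowel nucleus after position i a front vowel [ε/i]?

        A following glide group also counts as front (it palatalizes)."""
        j = i
        while j < len(word):
            if j in group_role:
                role, nu = group_role[j]
                if role == "glide":
                    return True
                group = word[nu.core_start : nu.core_end] if role == "vowel" else ""
                return _vowel_group_phone(group) in ("ε", "i")
            j += 1
        return False

    def _vowel_group_phone(group: str) -> str:
        bases = "".join(base_letter(c) for c in group)
        if len(bases) == 2 and bases in _VOWEL_DIGRAPH_PHONE:
            return _VOWEL_DIGRAPH_PHONE[bases]
        return _SINGLE_VOWEL.get(bases[0], "i")

    def apply_glide() -> None:
        # the consumed i-grapheme acts on the preceding consonant
        if phones and phones[-1] in ("c", "ç", "ʝ", "ɲ", "ʎ"):
            return  # already palatal(ized); the grapheme is absorbed
        if phones and phones[-1] in _PALATAL_OF:
            phones[-1] = _PALATAL_OF[phones[-1]]
        elif phones and phones[-1] in VOICED_CONSONANTS:
            phones.append("ʝ")
        elif phones and phones[-1] not in VOWEL_PHONES:
            phones.append("ç")
        else:  # no preceding consonant (defensive; CiV requires one)
            phones.append("ʝ")

    i = 0
    n = len(word)
    while i < n:
        if i in group_role:
            role, nu = group_role[i]
            if role == "glide":
                end = nu.core_start
                apply_glide()
                i = end
                continue
            group = word[i : nu.core_end] if nu.merged_civ else word[nu.start : nu.end]
            end = nu.core_end if nu.merged_civ else nu.end
            bases = "".join(base_letter(c) for c in group)
            stressed_here = any(has_tonos(c) for c in group)
            if len(bases) == 2 and bases[1] == "υ" and bases[0] in "αεη":
                head = {"α": "a", "ε": "ε", "η": "i"}[bases[0]]
                phones.append(head)
                if stressed_here:
                    stress.append(len(phones) - 1)
                phones.append("v" if _next_letter_voiced(word, end) else "f")
            else:
                phones.append(_vowel_group_phone(group))
                if stressed_here:
                    stress.append(len(phones) - 1)
            i = end
            continue

        ch = word[i]
        if not is_consonant(ch):
            raise UnmappableGraphemeError(ch, i)
        pair = ch + word[i + 1] if i + 1 < n else ""
        if pair in ("μπ", "ντ", "γκ", "γγ"):
            nasal, stop = {"μπ": ("m", "b"), "ντ": ("n", "d"),
                           "γκ": ("ŋ", "g"), "γγ": ("ŋ", "g")}[pair]
            if i == 0:
                phones.append(stop)
            else:
                phones.extend([nasal, stop])
            i += 2
            continue
        if pair == "γχ":
            phones.extend(["ŋ", "x"])
            i += 2
            continue
        if pair == "γξ":
            phones.extend(["ŋ", "k", "s"])
            i += 2
            continue
        if pair in ("τσ", "τζ"):
            phones.append("ts" if pair == "τσ" else "dz")
            i += 2
            continue
        if ch == "ξ":
            phones.extend(["k", "s"])
            i += 1
            continue
        if ch == "ψ":
            phones.extend(["p", "s"])
            i += 1
            continue
        if ch in _VELAR:
            back, front = _VELAR[ch]
            # palatalization requires immediate adjacency to the front vowel
            phones.append(front if (i + 1 in group_role and front_ahead(i + 1)) else back)
            i += 1
            continue
        if ch in ("σ", "ς"):
            nxt_is_cons = i + 1 < n and is_consonant(word[i + 1])
            phones.append("z" if nxt_is_cons and _next_letter_voiced(word, i + 1) else "s")
            i += 1
            continue
        if ch in _PLAIN_CONSONANT:
            phones.append(_PLAIN_CONSONANT[ch])
            i += 1
            continue
        raise UnmappableGraphemeError(ch, i)

    # degemination: double consonant letters (σσ, λλ, ...) are one sound
    out: list[str] = []
    stress_idx = stress[0] if stress else None
    for j, p in enumerate(phones):
        if out and out[-1] == p and p not in VOWEL_PHONES:
            if stress_idx is not None and j < stress_idx:
                stress_idx -= 1
            continue
        out.append(p)

    seq = PhoneSeq(tuple(out), stress_idx)
    return simplify_nasals(seq) if simplify else seq


def simplify_nasals(seq: PhoneSeq) -> PhoneSeq:
    """Drop nasals before homorganic voiced stops ([mb],[nd],[ŋg]); idempotent.

    The labiodental nasal [ɱ] is first mapped to [m].  The stress index
    is shifted to keep addressing the same vowel.
    """
    phones = ["m" if p == "ɱ" else p for p in seq.phones]
    stress = seq.stress_index
    changed = True
    while changed:
        changed = False
        out: list[str] = []
        new_stress = stress
        i = 0
        while i < len(phones):
            if i + 1 < len(phones) and (phones[i], phones[i + 1]) in HOMORGANIC_NASAL_STOP:
                if stress is not None and i < stress:
                    new_stress -= 1
                i += 1  # drop the nasal
                changed = True
                continue
            out.append(phones[i])
            i += 1
        phones, stress = out, new_stress
    return PhoneSeq(tuple(phones), stress)


def comparison_normalize(seq: PhoneSeq, word_is_monosyllable: bool | None = None) -> PhoneSeq:
    """Normalize a transcription for cross-database comparison.

    (i) monosyllables lose the (redundant) stress marker, (ii) nasal +
    homorganic stop pairs are simplified, (iii) [ɱ] is treated as [m].
    Symbol variants ([e] for [ε]) are also collapsed so that different
    symbol conventions compare equal.  Idempotent.
    """
    seq = simplify_nasals(seq)
    phones = tuple("ε" if p == "e" else p for p in seq.phones)
    stress = seq.stress_index
    if word_is_monosyllable is None:
        word_is_monosyllable = sum(p in VOWEL_PHONES for p in phones) == 1
    if word_is_monosyllable:
        stress = None
    return PhoneSeq(phones, stress)


def parse_transcription(text: str, normalize_symbols: bool = True) -> PhoneSeq:
    """Parse a printed transcription like ``[aku'mbao]`` or ``δʝa-'va-tis``.

    Brackets and hyphens are ignored; an apostrophe stresses the next
    vowel.  ``ts``/``dz`` are read as affricates.  With
    ``normalize_symbols`` IPA variants (ð, ɣ, e) map to resource style.
    """
    symmap = {"ð": "δ", "ɣ": "γ", "e": "ε", "ο": "o", "ɛ": "ε"} if normalize_symbols else {}
    phones: list[str] = []
    stress = None
    pending = False
    i = 0
    while i < len(text):
        ch = text[i]
        if ch in "[]-· ":
            i += 1
            continue
        if ch in "'ˈ":
            pending = True
            i += 1
            continue
        if text[i : i + 2] in ("ts", "dz"):
            phones.append(text[i : i + 2])
            i += 2
            continue
        p = symmap.get(ch, ch)
        if p not in ALL_PHONES:
            raise UnmappableGraphemeError(ch, i)
        phones.append(p)
        if pending and p in VOWEL_PHONES:
            stress = len(phones) - 1
            pending = False
        i += 1
    return PhoneSeq(tuple(phones), stress)
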