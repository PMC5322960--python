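"""Orthographic and phonological syllabification of Greek words.

Two syllabifiers live here because they answer different questions:

* :func:`syllabify_orthographic` implements the school-grammar rule used
  for hyphenation: an intervocalic consonant cluster opens the next
  syllable if and only if some Greek word *begins* with that cluster
  (attested-onset criterion); otherwise its first letter closes the
  previous syllable.

* :func:`syllabify_phonological` implements the maximal-onset principle
  over phone strings: each intervocalic consonant run contributes its
  longest *phonotactically legal* suffix as the next onset.  Legality is
  decided by ordinal manner/place-of-articulation scales plus a binary
  voicing criterion (see :class:`ClusterRuleSet`), a deliberately strict
  rule set under which clusters such as [mv], [rm] and [rp] are split.

Both share the vowel-nucleus parser, including the treatment of the
ambiguous CiV pattern (consonant + unstressed i-sounding grapheme +
vowel), which may read as one syllable (glide/palatalized) or two (full
[i]); disambiguation combines a per-cluster majority table with an
exception lexicon.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

from .greek_text import (
    GreekTextError,
    VOWEL_DIGRAPHS,
    base_letter,
    fold_sigma,
    has_tonos,
    is_consonant,
    is_vowel,
    strip_stress,
    stressed_vowel_index,
)
from .phones import VOWEL_PHONES

__all__ = [
    "NoNucleusError",
    "UnresolvedCiVError",
    "ConfigurationError",
    "Syllabification",
    "ConsonantProfile",
    "ClusterRuleSet",
    "LegalityVerdict",
    "CiVSite",
    "CiVStats",
    "CiVDecision",
    "CiVResolver",
    "Nucleus",
    "parse_nuclei",
    "find_civ_sites",
    "build_onset_inventory",
    "default_onset_inventory",
    "syllabify_orthographic",
    "cluster_is_legal_onset",
    "syllabify_phonological",
    "civ_majority_table",
    "disambiguate_civ",
    "default_civ_resolver",
]


class NoNucleusError(GreekTextError):
    """Word or phone string contains no vowel."""


class UnresolvedCiVError(GreekTextError):
    """A CiV site has neither majority statistics nor an exception entry."""


class ConfigurationError(ValueError):
    """A phone lacks a consonant profile in the rule set."""


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass
class Syllabification:
    """Ordered syllable units plus the 1-based index of the stressed unit.

    ``units`` holds strings for orthographic parses and tuples of phone
    symbols for phonological parses; either way the concatenation of the
    units reproduces the source exactly.  ``nuclei`` (orthographic only)
    gives, per unit, the span of the *core* vowel nucleus within the
    unit — for a merged CiV syllable this is the full vowel, not the
    glide grapheme.
    """

    units: list
    stressed_unit: int | None = None
    nuclei: list[tuple[int, int]] | None = None

    @property
    def n_units(self) -> int:
        return len(self.units)

    def flat(self):
        """Concatenation of the units (string or phone tuple)."""
        if self.units and isinstance(self.units[0], str):
            return "".join(self.units)
        out: tuple = ()
        for u in self.units:
            out += tuple(u)
        return out

    def hyphenated(self, stress_mark: str = "'") -> str:
        """Display form, e.g. ``δʝa-'va-tis`` or ``άν-θρω-πος``."""
        parts = []
        for i, u in enumerate(self.units, start=1):
            s = u if isinstance(u, str) else "".join(u)
            if stress_mark and self.stressed_unit == i and not isinstance(u, str):
                s = stress_mark + s
            parts.append(s)
        return "-".join(parts)

    def compact(self, stress_mark: str = "'") -> str:
        """Hyphen-free display form, e.g. ``a'dεna``."""
        parts = []
        for i, u in enumerate(self.units, start=1):
            s = u if isinstance(u, str) else "".join(u)
            if stress_mark and self.stressed_unit == i:
                s = stress_mark + s
            parts.append(s)
        return "".join(parts)


# ---------------------------------------------------------------------------
# vowel-nucleus parsing and CiV disambiguation
# ---------------------------------------------------------------------------

#: grapheme groups that in isolation read as [i] and may reduce to a glide
_I_SOUND_GROUPS = frozenset({"ι", "η", "υ", "ει", "οι", "υι"})

#: first members of the αυ/ευ/ηυ vowel+[v/f] groups
_UPSILON_HEADS = frozenset({"α", "ε", "η"})


@dataclass(frozen=True)
class CiVSite:
    """An ambiguous consonant + i-grapheme + vowel position in a word."""

    start: int          # letter index of the i-grapheme group
    i_letters: str      # the i-sounding group as written (e.g. "ι", "ει")
    v_letters: str      # the following vowel group as written
    cluster: str        # stress-stripped vowel-letter pattern, e.g. "ιο"


@dataclass
class CiVStats:
    """One-vs-two-syllable counts for an ambiguous vowel-letter cluster."""

    cluster: str
    n_one_syllable: int = 0
    n_two_syllables: int = 0

    @property
    def majority(self) -> int:
        """Majority parse; a tie resolves to two syllables (full vowel)."""
        if self.n_one_syllable > self.n_two_syllables:
            return 1
        return 2


@dataclass(frozen=True)
class CiVDecision:
    parse: int          # 1 or 2 syllables
    source: str         # "exception" | "majority" | "default"


class CiVResolver:
    """Decides CiV parses: exception lexicon first, then cluster majority.

    ``default`` (1 or 2) is used when neither source covers the site; if
    it is None such sites raise :class:`UnresolvedCiVError`.
    """

    def __init__(
        self,
        stats: Mapping[str, CiVStats] | None = None,
        exceptions: Mapping[str, int] | None = None,
        default: int | None = None,
    ):
        self.stats = dict(stats or {})
        self.exceptions = dict(exceptions or {})
        self.default = default

    def decide(self, word: str, site: CiVSite) -> CiVDecision:
        return disambiguate_civ(word, site, self.stats, self.exceptions, self.default)

    def __call__(self, word: str, site: CiVSite) -> CiVDecision:
        return self.decide(word, site)


def disambiguate_civ(
    word: str,
    site: CiVSite,
    stats: Mapping[str, CiVStats],
    exceptions: Mapping[str, int],
    default: int | None = None,
) -> CiVDecision:
    """Resolve one CiV site: exception entry wins, else cluster majority.

    The exception lexicon maps whole words to a parse (1 or 2) applied to
    all their sites.  With no entry and no statistics for the cluster the
    configured default applies, or :class:`UnresolvedCiVError` is raised.
    """
    key = strip_stress(word)
    if key in exceptions:
        return CiVDecision(int(exceptions[key]), "exception")
    if site.cluster in stats:
        return CiVDecision(stats[site.cluster].majority, "majority")
    if default is not None:
        return CiVDecision(int(default), "default")
    raise UnresolvedCiVError(
        f"CiV cluster {site.cluster!r} in {word!r}: no statistics, no exception entry"
    )


@dataclass(frozen=True)
class Nucleus:
    """A vowel nucleus: letter span plus the core (main-vowel) sub-span."""

    start: int
    end: int            # exclusive
    core_start: int
    core_end: int
    merged_civ: bool = False


def _vowel_groups(word: str) -> list[tuple[int, int]]:
    """Greedy left-to-right grouping of vowel letters into graphemes.

    Digraphs (αι, ει, οι, ου, υι and the αυ/ευ/ηυ groups) are kept
    together unless broken by a tonos on the first letter or a dialytika
    on the second.
    """
    groups: list[tuple[int, int]] = []
    i = 0
    n = len(word)
    while i < n:
        ch = word[i]
        if not is_vowel(ch):
            i += 1
            continue
        size = 1
        if i + 1 < n and is_vowel(word[i + 1]):
            c1, c2 = word[i], word[i + 1]
            b1, b2 = base_letter(c1), base_letter(c2)
            first_breaks = has_tonos(c1) or c1 in "ϊϋΐΰ"
            second_breaks = c2 in "ϊϋΐΰ"
            pair = b1 + b2
            if not first_breaks and not second_breaks:
                if pair in VOWEL_DIGRAPHS or (b1 in _UPSILON_HEADS and b2 == "υ"):
                    size = 2
        groups.append((i, i + size))
        i += size
    return groups


def find_civ_sites(word: str) -> list[CiVSite]:
    """All ambiguous CiV positions in a normalized word.

    A site needs: an unstressed, dialytika-free i-sounding grapheme
    group, immediately followed by another vowel group, and preceded by
    at least one consonant.
    """
    sites = []
    groups = _vowel_groups(word)
    for (s1, e1), (s2, e2) in zip(groups, groups[1:]):
        if e1 != s2:
            continue
        g1 = word[s1:e1]
        if strip_stress(g1) not in _I_SOUND_GROUPS:
            continue
        if any(has_tonos(c) or c in "ϊϋΐΰ" for c in g1):
            continue
        if s1 == 0 or not is_consonant(word[s1 - 1]):
            continue
        cluster = strip_stress(word[s1:e2])
        sites.append(CiVSite(s1, g1, word[s2:e2], cluster))
    return sites


def parse_nuclei(word: str, civ: CiVResolver | None = None) -> list[Nucleus]:
    """Vowel nuclei of a word, with CiV sites merged or split per ``civ``."""
    groups = _vowel_groups(word)
    if not groups:
        raise NoNucleusError(f"{word!r} contains no vowel")
    sites = {s.start: s for s in find_civ_sites(word)}
    nuclei: list[Nucleus] = []
    k = 0
    while k < len(groups):
        s, e = groups[k]
        site = sites.get(s)
        if (
            site is not None
            and k + 1 < len(groups)
            and groups[k + 1][0] == e
        ):
            resolver = civ if civ is not None else default_civ_resolver()
            decision = resolver(word, site)
            if decision.parse == 1:
                s2, e2 = groups[k + 1]
                nuclei.append(Nucleus(s, e2, core_start=s2, core_end=e2, merged_civ=True))
                k += 2
                continue
        nuclei.append(Nucleus(s, e, core_start=s, core_end=e))
        k += 1
    return nuclei


# ---------------------------------------------------------------------------
# orthographic (school-grammar) syllabification
# ---------------------------------------------------------------------------


def build_onset_inventory(words: Iterable[str]) -> set[str]:
    """Attested word-initial consonant clusters, prefix-closed.

    For each word the maximal initial consonant-letter run is recorded
    (stress-stripped, final sigma folded) together with all its prefixes:
    any prefix of an attested onset also begins some reading of a word.
    """
    inventory: set[str] = set()
    for word in words:
        w = fold_sigma(strip_stress(word))
        run = ""
        for ch in w:
            if is_consonant(ch):
                run += ch
            else:
                break
        for i in range(1, len(run) + 1):
            inventory.add(run[:i])
    return inventory


def default_onset_inventory() -> set[str]:
    """Onset inventory shipped with the package (attested Greek onsets)."""
    with resources.files("hellex.data").joinpath("onset_inventory.json").open(
        encoding="utf-8"
    ) as fh:
        return set(json.load(fh))


def syllabify_orthographic(
    word: str,
    inventory: set[str] | None = None,
    civ: CiVResolver | None = None,
    recursive: bool = False,
) -> Syllabification:
    """School-grammar syllabification of a normalized word.

    An intervocalic consonant cluster stays whole as the next syllable's
    onset if it is in the attested-onset ``inventory``; otherwise its
    first letter joins the previous syllable and the remainder opens the
    next one.  The grammar states this split once; ``recursive=True``
    re-applies it until the remainder is attested (documented extension).
    """
    if inventory is None:
        inventory = default_onset_inventory()
    nuclei = parse_nuclei(word, civ)
    n = len(nuclei)
    # boundaries[i] = letter index where unit i starts
    starts = [0]
    for left, right in zip(nuclei, nuclei[1:]):
        run = word[left.end : right.start]
        key = fold_sigma(strip_stress(run))
        split = 0
        # a single intervocalic consonant is always an onset
        if len(key) > 1 and key not in inventory:
            split = 1
            if recursive:
                while split < len(run) and fold_sigma(strip_stress(run[split:])) not in inventory:
                    split += 1
        starts.append(left.end + split)
    starts.append(len(word))
    units = [word[starts[i] : starts[i + 1]] for i in range(n)]

    stressed = None
    si = stressed_vowel_index(word)
    if si is not None:
        for i in range(n):
            if starts[i] <= si < starts[i + 1]:
                stressed = i + 1
                break
    unit_nuclei = [
        (nu.core_start - starts[i], nu.core_end - starts[i]) for i, nu in enumerate(nuclei)
    ]
    return Syllabification(units=units, stressed_unit=stressed, nuclei=unit_nuclei)


# ---------------------------------------------------------------------------
# phonotactic legality and phonological syllabification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConsonantProfile:
    """Ordinal articulation profile of a consonant phone.

    Lower ``moa_rank``/``poa_rank`` means further left on the respective
    scale; an onset pair is scale-legal when the first member is strictly
    leftmost on at least one scale.
    """

    phone: str
    moa_rank: int
    poa_rank: int
    voiced: bool
    manner: str  # stop | affricate | fricative | nasal | liquid


@dataclass
class ClusterRuleSet:
    """Configuration of the onset-legality engine.

    ``heterosyllabic_overrides`` may contain the pattern names
    ``"liquid-initial"`` and ``"nasal+liquid"`` or explicit cluster
    strings; such clusters are always split.  ``whitelist`` holds
    clusters that are always legal regardless of the scales (a slot for
    attested-cluster additions; empty by default).  With
    ``strict_nasal_liquid`` off, pairs containing a nasal or liquid are
    accepted without scale evaluation (the permissive policy of earlier
    resources); with it on they are evaluated on both scales.
    ``voicing_split`` makes falling voicing (voiced before voiceless)
    split a cluster on its own.
    """

    profiles: dict[str, ConsonantProfile]
    whitelist: set[tuple[str, ...]] = field(default_factory=set)
    heterosyllabic_overrides: set[str] = field(default_factory=set)
    strict_nasal_liquid: bool = True
    voicing_split: bool = True

    def __post_init__(self):
        explicit = {w for w in ("".join(c) for c in self.whitelist)}
        overlap = explicit & {
            o for o in self.heterosyllabic_overrides if o not in ("liquid-initial", "nasal+liquid")
        }
        if overlap:
            raise ConfigurationError(f"clusters both whitelisted and overridden: {overlap}")

    def profile(self, phone: str) -> ConsonantProfile:
        try:
            return self.profiles[phone]
        except KeyError:
            raise ConfigurationError(f"no consonant profile for phone {phone!r}") from None

    # -- presets ----------------------------------------------------------

    @classmethod
    def strict(cls) -> "ClusterRuleSet":
        """The package's default, stricter rule set (shipped config)."""
        return cls.from_json(
            resources.files("hellex.data").joinpath("cluster_rules.json")
        )

    @classmethod
    def iplr_style(cls) -> "ClusterRuleSet":
        """Permissive preset: nasal/liquid free pass, no voicing splits.

        Under this preset clusters like [mv], [rm], [rp] become legal
        onsets, reproducing the more liberal parses of earlier resources.
        """
        rules = cls.strict()
        rules.strict_nasal_liquid = False
        rules.voicing_split = False
        rules.heterosyllabic_overrides = set()
        return rules

    @classmethod
    def from_json(cls, path) -> "ClusterRuleSet":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        profiles = {
            p: ConsonantProfile(p, d["moa"], d["poa"], d["voiced"], d["manner"])
            for p, d in raw["phones"].items()
        }
        return cls(
            profiles=profiles,
            whitelist={tuple(c) for c in raw.get("whitelist", [])},
            heterosyllabic_overrides=set(raw.get("heterosyllabic_overrides", [])),
            strict_nasal_liquid=raw.get("strict_nasal_liquid", True),
            voicing_split=raw.get("voicing_split", True),
        )

    def to_json(self, path) -> None:
        raw = {
            "phones": {
                p: {
                    "moa": pr.moa_rank,
                    "poa": pr.poa_rank,
                    "voiced": pr.voiced,
                    "manner": pr.manner,
                }
                for p, pr in self.profiles.items()
            },
            "whitelist": [list(c) for c in sorted(self.whitelist)],
            "heterosyllabic_overrides": sorted(self.heterosyllabic_overrides),
            "strict_nasal_liquid": self.strict_nasal_liquid,
            "voicing_split": self.voicing_split,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(raw, fh, ensure_ascii=False, indent=1)


@dataclass(frozen=True)
class LegalityVerdict:
    legal: bool
    reason: str

    def __bool__(self) -> bool:
        return self.legal


def cluster_is_legal_onset(
    cluster: Sequence[str], rules: ClusterRuleSet
) -> LegalityVerdict:
    """Judge whether a consonant phone sequence may open a syllable.

    Single consonants are always legal.  Whitelisted clusters pass;
    override patterns fail; otherwise every adjacent pair must have its
    first member strictly leftmost on the manner or place scale and must
    not show falling voicing (when ``voicing_split`` is set).
    """
    cluster = tuple(cluster)
    if not cluster:
        raise ValueError("empty cluster")
    profiles = [rules.profile(p) for p in cluster]
    if len(cluster) == 1:
        return LegalityVerdict(True, "single consonant")
    if cluster in rules.whitelist:
        return LegalityVerdict(True, "whitelisted cluster")
    ov = rules.heterosyllabic_overrides
    if "liquid-initial" in ov and profiles[0].manner == "liquid":
        return LegalityVerdict(False, "liquid-initial cluster is always heterosyllabic")
    if "nasal+liquid" in ov:
        for p1, p2 in zip(profiles, profiles[1:]):
            if p1.manner == "nasal" and p2.manner == "liquid":
                return LegalityVerdict(False, "nasal+liquid cluster is always heterosyllabic")
    if "".join(cluster) in ov:
        return LegalityVerdict(False, "cluster listed as heterosyllabic")
    for p1, p2 in zip(profiles, profiles[1:]):
        pair = f"[{p1.phone}{p2.phone}]"
        if not rules.strict_nasal_liquid and (
            p1.manner in ("nasal", "liquid") or p2.manner in ("nasal", "liquid")
        ):
            continue  # permissive policy: nasal/liquid pairs pass unevaluated
        if not (p1.moa_rank < p2.moa_rank or p1.poa_rank < p2.poa_rank):
            return LegalityVerdict(
                False, f"{pair}: first member not leftmost on manner or place scale"
            )
        if rules.voicing_split and p1.voiced and not p2.voiced:
            return LegalityVerdict(False, f"{pair}: falling voicing forces a split")
    return LegalityVerdict(True, "all adjacent pairs scale-legal")


def syllabify_phonological(seq, rules: ClusterRuleSet | None = None) -> Syllabification:
    """Maximal-onset syllabification of a phone sequence.

    ``seq`` is a :class:`~hellex.phonology.PhoneSeq` (or anything with
    ``phones`` and ``stress_index``).  For each intervocalic consonant
    run, the longest legal suffix becomes the next syllable's onset and
    the remainder the previous coda; a single consonant always attaches
    to the onset.  Word-initial runs join the first syllable wholly,
    whatever their legality, and the legality of the resulting codas is
    not checked.
    """
    if rules is None:
        rules = ClusterRuleSet.strict()
    phones = list(seq.phones)
    stress_index = seq.stress_index
    vowel_pos = [i for i, p in enumerate(phones) if p in VOWEL_PHONES]
    if not vowel_pos:
        raise NoNucleusError(f"phone sequence {phones!r} contains no vowel")
    starts = [0]
    for left, right in zip(vowel_pos, vowel_pos[1:]):
        run = phones[left + 1 : right]
        onset_len = 0
        for k in range(len(run), 0, -1):
            if k == 1 or cluster_is_legal_onset(run[-k:], rules):
                onset_len = k
                break
        starts.append(right - onset_len)
    starts.append(len(phones))
    units = [tuple(phones[starts[i] : starts[i + 1]]) for i in range(len(vowel_pos))]
    stressed = None
    if stress_index is not None:
        for i in range(len(units)):
            if starts[i] <= stress_index < starts[i + 1]:
                stressed = i + 1
                break
    return Syllabification(units=units, stressed_unit=stressed)


# ---------------------------------------------------------------------------
# CiV majority statistics
# ---------------------------------------------------------------------------


def civ_majority_table(
    parsed: Iterable[tuple[str, Syllabification]]
) -> dict[str, CiVStats]:
    """Per-cluster one-vs-two-syllable counts from gold syllabifications.

    ``parsed`` yields (word, orthographic syllabification) pairs whose
    parses are taken as verified.  A site counts as one syllable when the
    i-grapheme and the following vowel sit in the same unit.
    """
    table: dict[str, CiVStats] = {}
    for word, syllab in parsed:
        starts = []
        pos = 0
        for u in syllab.units:
            starts.append(pos)
            pos += len(u)
        ends = starts[1:] + [pos]
        for site in find_civ_sites(word):
            unit_of_i = next(
                i for i, (s, e) in enumerate(zip(starts, ends)) if s <= site.start < e
            )
            v_start = site.start + len(site.i_letters)
            same = starts[unit_of_i] <= v_start < ends[unit_of_i]
            stats = table.setdefault(site.cluster, CiVStats(site.cluster))
            if same:
                stats.n_one_syllable += 1
            else:
                stats.n_two_syllables += 1
    return table


_DEFAULT_RESOLVER: CiVResolver | None = None


def default_civ_resolver() -> CiVResolver:
    """Resolver built from the shipped majority table and exception lexicon.

    The shipped majority counts are curated defaults for the common
    ambiguous clusters; the exception lexicon is a small word list (TSV:
    word, one|two).  Unlisted clusters default to two syllables, the
    conservative full-vowel reading.
    """
    global _DEFAULT_RESOLVER
    if _DEFAULT_RESOLVER is None:
        data = resources.files("hellex.data")
        with data.joinpath("civ_majority.json").open(encoding="utf-8") as fh:
            raw = json.load(fh)
        stats = {c: CiVStats(c, d[0], d[1]) for c, d in raw.items()}
        exceptions: dict[str, int] = {}
        with data.joinpath("civ_exceptions.tsv").open(encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                word, parse = line.split("\t")
                exceptions[strip_stress(word)] = 1 if parse == "one" else 2
        _DEFAULT_RESOLVER = CiVResolver(stats, exceptions, default=2)
    return _DEFAULT_RESOLVER
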