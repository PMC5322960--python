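"""Lexicon tables: readers/writers, PoS annotation, and the build pipeline.

A lexicon table is a pandas DataFrame with one row per word, starting
from the minimal schema (``word``, ``frequency_count``) and growing the
full set of derived columns via :func:`build_database`: syllabifications
(orthographic and phonological), transcription, stress position,
frequency scales (fpm, Zipf), similarity metrics (Coltheart's N,
OLD20/PLD20), stress-regularity measures (rime, ending, neighbourhood
proportions), syllable frequencies and part-of-speech tags.

Files are TSV (UTF-8) by default, with a CSV export and a documented,
reversible ASCII transliteration for systems without Greek text support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .greek_text import GreekTextError, strip_stress
from .metrics import ZipfParams
from .phonology import transcribe
from .stress import stress_position
from .syllabification import (
    CiVResolver,
    ClusterRuleSet,
    build_onset_inventory,
    default_civ_resolver,
    default_onset_inventory,
    syllabify_orthographic,
    syllabify_phonological,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "ASCII_TO_GREEK",
    "GREEK_TO_ASCII",
    "to_ascii",
    "from_ascii",
    "read_lexicon",
    "write_lexicon",
    "PosDictionary",
    "pos_annotate",
    "BuildConfig",
    "build_database",
    "COLUMN_ORDER",
]


class SchemaError(ValueError):
    """A lexicon file lacks mandatory columns."""


# ---------------------------------------------------------------------------
# reversible ASCII transliteration
# ---------------------------------------------------------------------------

#: one-to-one letter map; tonos is a trailing apostrophe on the stressed
#: vowel, dialytika a trailing double quote (tonos last when combined).
GREEK_TO_ASCII = {
    "α": "a", "β": "b", "γ": "g", "δ": "d", "ε": "e", "ζ": "z", "η": "h",
    "θ": "8", "ι": "i", "κ": "k", "λ": "l", "μ": "m", "ν": "n", "ξ": "3",
    "ο": "o", "π": "p", "ρ": "r", "σ": "s", "ς": "c", "τ": "t", "υ": "y",
    "φ": "f", "χ": "x", "ψ": "4", "ω": "w",
}
ASCII_TO_GREEK = {v: k for k, v in GREEK_TO_ASCII.items()}

_DIACRITIC_DECOMP = {
    "ά": ("α", "'"), "έ": ("ε", "'"), "ή": ("η", "'"), "ί": ("ι", "'"),
    "ό": ("ο", "'"), "ύ": ("υ", "'"), "ώ": ("ω", "'"),
    "ϊ": ("ι", '"'), "ϋ": ("υ", '"'), "ΐ": ("ι", '"\''), "ΰ": ("υ", '"\''),
}
_DIACRITIC_COMPOSE = {(base, marks): ch for ch, (base, marks) in _DIACRITIC_DECOMP.items()}


def to_ascii(word: str) -> str:
    """Transliterate a Greek word to the reversible ASCII dialect."""
    out = []
    for ch in word:
        base, marks = _DIACRITIC_DECOMP.get(ch, (ch, ""))
        out.append(GREEK_TO_ASCII[base] + marks)
    return "".join(out)


def from_ascii(text: str) -> str:
    """Invert :func:`to_ascii`."""
    out = []
    i = 0
    while i < len(text):
        ch = ASCII_TO_GREEK[text[i]]
        i += 1
        marks = ""
        while i < len(text) and text[i] in "'\"":
            marks += text[i]
            i += 1
        if marks:
            marks = '"\'' if set(marks) == {'"', "'"} else marks
            ch = _DIACRITIC_COMPOSE[(ch, marks)]
        out.append(ch)
    return "".join(out)


# ---------------------------------------------------------------------------
# reading and writing
# ---------------------------------------------------------------------------

_COUNT_ALIASES = ("frequency_count", "frequency", "count")


def read_lexicon(path, dialect: str = "utf8", sep: str = "\t"):
    """Read a delimited lexicon file into a typed table.

    The header must contain ``word`` and a frequency column (one of
    ``frequency_count``/``frequency``/``count``).  Malformed rows (wrong
    field count, non-numeric frequency) are collected into the returned
    table's ``attrs["errors"]`` list, not silently dropped.  The
    ``ascii`` dialect decodes the reversible transliteration.
    """
    with open(path, encoding="utf-8" if dialect == "utf8" else "ascii") as fh:
        header = fh.readline().rstrip("\n").split(sep)
        if "word" not in header:
            raise SchemaError("missing mandatory column 'word'")
        count_col = next((c for c in _COUNT_ALIASES if c in header), None)
        if count_col is None:
            raise SchemaError("missing mandatory frequency column")
        rows, errors = [], []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split(sep)
            if len(fields) != len(header):
                errors.append((lineno, line, "wrong field count"))
                continue
            rec = dict(zip(header, fields))
            try:
                rec[count_col] = float(rec[count_col])
            except ValueError:
                errors.append((lineno, line, f"non-numeric {count_col}"))
                continue
            rows.append(rec)
    df = pd.DataFrame(rows, columns=header)
    if count_col != "frequency_count":
        df = df.rename(columns={count_col: "frequency_count"})
    if dialect == "ascii":
        df["word"] = df["word"].map(from_ascii)
    df.attrs["errors"] = errors
    if errors:
        logger.warning("%d malformed rows in %s", len(errors), path)
    return df


def write_lexicon(df: pd.DataFrame, path, dialect: str = "utf8", sep: str = "\t") -> None:
    """Write a lexicon table as TSV (or CSV via ``sep=','``)."""
    out = df.copy()
    if dialect == "ascii":
        out["word"] = out["word"].map(to_ascii)
    out.to_csv(path, sep=sep, index=False, encoding="utf-8" if dialect == "utf8" else "ascii")


# ---------------------------------------------------------------------------
# part of speech
# ---------------------------------------------------------------------------

#: closed tag set used by the dictionary interface
POS_TAGS = (
    "noun", "adjective", "verb", "adverb", "article", "pronoun",
    "quantifier", "numeral", "preposition", "conjunction", "particle",
    "interjection",
)


class PosDictionary:
    """Word → ordered PoS tags; the first tag is the headword category."""

    def __init__(self, entries: Mapping[str, list[str]]):
        for word, tags in entries.items():
            for t in tags:
                if t not in POS_TAGS:
                    raise ValueError(f"unknown PoS tag {t!r} for {word!r}")
        self.entries = dict(entries)

    @classmethod
    def from_tsv(cls, path) -> "PosDictionary":
        """Load a two-column TSV: word <TAB> comma-separated tags."""
        entries = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                word, tags = line.split("\t")
                entries[word] = [t.strip() for t in tags.split(",")]
        return cls(entries)

    @classmethod
    def fixture(cls) -> "PosDictionary":
        """Small synthetic dictionary shipped for tests and examples."""
        return cls.from_tsv(resources.files("hellex.data").joinpath("pos_fixture.tsv"))

    def lookup(self, word: str) -> list[str]:
        return self.entries.get(word, [])


def pos_annotate(df: pd.DataFrame, dictionary: PosDictionary) -> pd.DataFrame:
    """Attach ``pos_primary`` / ``pos_secondary`` via dictionary cross-check.

    The dictionary's first category becomes the primary tag; additional
    categories become secondary tags.  Unmatched words are tagged
    ``unknown`` (a value, not an error).
    """
    primary, secondary = [], []
    for word in df["word"]:
        tags = dictionary.lookup(word)
        primary.append(tags[0] if tags else "unknown")
        secondary.append(",".join(tags[1:]))
    out = df.copy()
    out["pos_primary"] = primary
    out["pos_secondary"] = secondary
    return out


# ---------------------------------------------------------------------------
# build pipeline
# ---------------------------------------------------------------------------

#: fixed, versioned output column order (schema v1)
COLUMN_ORDER = [
    "word", "frequency_count", "fpm", "zipf",
    "pos_primary", "pos_secondary",
    "orth_syllables", "phon_syllables", "transcription",
    "n_syllables", "stress_position",
    "rime", "stress_ending",
    "coltheart_n_stressed", "coltheart_n_unstressed",
    "old20_stressed", "old20_unstressed",
    "pld20_stressed", "pld20_unstressed",
    "rime_n", "stress_nbhd_type_prop", "stress_nbhd_token_prop",
    "mean_syll_freq_stressed", "mean_syll_freq_unstressed",
    "error",
]


@dataclass
class BuildConfig:
    """Everything :func:`build_database` needs besides the word counts."""

    zipf_params: ZipfParams = field(default_factory=ZipfParams)
    rules: ClusterRuleSet | None = None
    onset_inventory: set[str] | None = None  # None: shipped + input-derived
    civ: CiVResolver | None = None           # None: shipped resolver
    pos_dictionary: PosDictionary | None = None
    compute_similarity: bool = True          # N / OLD20 / PLD20 (quadratic)
    old20_k: int = 20


# single-char aliases for multi-char phones so phone strings have one
# symbol per phone (keeps PLD distances unit-cost per phone)
_PHONE_CHAR = {"ts": "ʦ", "dz": "ʣ"}


def _phone_string(phones) -> str:
    return "".join(_PHONE_CHAR.get(p, p) for p in phones)


def build_database(wordfreq: pd.DataFrame, config: BuildConfig | None = None) -> pd.DataFrame:
    """Annotate a word + frequency-count table with every derived column.

    Per-word failures never abort the pipeline; they are recorded in the
    ``error`` column and the row's derived fields stay missing.  Given
    the same configuration the output is deterministic.
    """
    config = config or BuildConfig()
    rules = config.rules or ClusterRuleSet.strict()
    civ = config.civ or default_civ_resolver()

    df = wordfreq.copy().reset_index(drop=True)
    if "word" not in df.columns:
        raise SchemaError("missing mandatory column 'word'")
    count_col = next((c for c in _COUNT_ALIASES if c in df.columns), None)
    if count_col is None:
        raise SchemaError("missing mandatory frequency column")
    if count_col != "frequency_count":
        df = df.rename(columns={count_col: "frequency_count"})
    if (df["frequency_count"] < 0).any():
        raise ValueError("negative frequency counts")

    inventory = config.onset_inventory
    if inventory is None:
        inventory = default_onset_inventory() | build_onset_inventory(df["word"])

    n = len(df)
    cols: dict[str, list] = {
        c: [None] * n for c in COLUMN_ORDER if c not in ("word", "frequency_count")
    }
    orth_units: list = [None] * n
    phon_units: list = [None] * n
    phone_strings: list = [None] * n          # no stress mark
    phone_strings_stressed: list = [None] * n  # "ˈ" before the stressed vowel

    for i, word in enumerate(df["word"]):
        try:
            orth = syllabify_orthographic(word, inventory, civ)
            seq = transcribe(word, civ)
            phon = syllabify_phonological(seq, rules)
            pos = stress_position(orth)
            orth_units[i] = orth.units
            phon_units[i] = phon.units
            phone_strings[i] = _phone_string(seq.phones)
            marked = list(seq.phones)
            if seq.stress_index is not None:
                marked.insert(seq.stress_index, "ˈ")
            phone_strings_stressed[i] = _phone_string(marked)
            cols["orth_syllables"][i] = orth.hyphenated()
            cols["phon_syllables"][i] = phon.hyphenated()
            cols["transcription"][i] = seq.to_string()
            cols["n_syllables"][i] = orth.n_units
            cols["stress_position"][i] = pos
            if pos != 0:
                cols["rime"][i] = _metrics.rime(word) if orth.stressed_unit else None
                cols["stress_ending"][i] = _metrics.colombo_ending(word, orth)
            cols["error"][i] = ""
        except (GreekTextError, ValueError) as exc:
            cols["error"][i] = f"{type(exc).__name__}: {exc}"

    ok = np.array([e == "" for e in cols["error"]])

    counts = df["frequency_count"].to_numpy(dtype=float)
    cols["fpm"] = _metrics.frequency_per_million(counts, config.zipf_params).tolist()
    cols["zipf"] = _metrics.zipf(counts, config.zipf_params).tolist()

    # stress neighbourhood (entry included in its own ending group)
    endings = [cols["stress_ending"][i] for i in range(n)]
    positions = [cols["stress_position"][i] for i in range(n)]
    poly = [i for i in range(n) if ok[i] and endings[i] is not None]
    if poly:
        groups = _metrics.stress_neighbourhood(
            [endings[i] for i in poly],
            [positions[i] for i in poly],
            counts[poly],
        )
        for i in poly:
            cols["stress_nbhd_type_prop"][i] = groups.proportion_for(
                endings[i], positions[i], "type"
            )
            cols["stress_nbhd_token_prop"][i] = groups.proportion_for(
                endings[i], positions[i], "token"
            )

    # rime neighbourhood
    rimed = [i for i in range(n) if ok[i] and cols["rime"][i] is not None]
    rimes = [cols["rime"][i] for i in rimed]
    rpos = [positions[i] for i in rimed]
    for i, r, p in zip(rimed, rimes, rpos):
        cols["rime_n"][i] = _metrics.rime_neighbourhood(r, p, rimes, rpos)

    # syllable frequency tables and per-entry means
    ok_idx = [i for i in range(n) if ok[i]]
    for stressed, col in ((True, "mean_syll_freq_stressed"), (False, "mean_syll_freq_unstressed")):
        table = _metrics.syllable_frequency_table(
            [orth_units[i] for i in ok_idx],
            counts[ok_idx],
            stressed=stressed,
            params=config.zipf_params,
        )
        for i in ok_idx:
            units = orth_units[i] if stressed else [strip_stress(u) for u in orth_units[i]]
            cols[col][i] = _metrics.mean_syllable_frequency(units, table)

    # orthographic and phonological similarity (quadratic; optional)
    if config.compute_similarity and len(ok_idx) > config.old20_k:
        words_ok = [df["word"][i] for i in ok_idx]
        for stressed, suffix in ((True, "stressed"), (False, "unstressed")):
            for i in ok_idx:
                cols[f"coltheart_n_{suffix}"][i] = _metrics.coltheart_n(
                    df["word"][i], words_ok, stressed=stressed
                )
            old = _metrics.old20_many(words_ok, words_ok, k=config.old20_k, stressed=stressed)
            pld_in = [
                (phone_strings_stressed if stressed else phone_strings)[i] for i in ok_idx
            ]
            pld = _metrics.old20_many(pld_in, pld_in, k=config.old20_k, stressed=stressed)
            for j, i in enumerate(ok_idx):
                cols[f"old20_{suffix}"][i] = old[j]
                cols[f"pld20_{suffix}"][i] = pld[j]

    if config.pos_dictionary is not None:
        ann = pos_annotate(df[["word"]], config.pos_dictionary)
        cols["pos_primary"] = ann["pos_primary"].tolist()
        cols["pos_secondary"] = ann["pos_secondary"].tolist()
    else:
        cols["pos_primary"] = ["unknown"] * n
        cols["pos_secondary"] = [""] * n

    out = df[["word", "frequency_count"]].copy()
    for c in COLUMN_ORDER:
        if c in ("word", "frequency_count"):
            continue
        out[c] = cols[c]
    return out
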