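"""Frequency and similarity metrics for lexicon tables.

Zipf frequency scale, Levenshtein distance (via edlib), Coltheart's N,
OLD20/PLD20, rime and stress (ending-based) neighbourhoods, syllable
frequency tables and Fleiss' kappa.

All string metrics fold word-final sigma to medial sigma before
comparison (the allographs are the same letter) and take a
``stressed`` switch selecting whether the tonos is kept or stripped,
mirroring the dual stressed/unstressed columns of Greek lexical
databases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss_kappa

from .greek_text import fold_sigma, strip_stress, stressed_vowel_index
from .syllabification import Syllabification

__all__ = [
    "ZipfParams",
    "zipf",
    "frequency_per_million",
    "levenshtein",
    "coltheart_n",
    "old20",
    "old20_many",
    "rime",
    "colombo_ending",
    "EndingGroups",
    "stress_neighbourhood",
    "rime_neighbourhood",
    "syllable_frequency_table",
    "mean_syllable_frequency",
    "fleiss_kappa",
    "InsufficientLexiconError",
    "MissingStressError",
]


class InsufficientLexiconError(ValueError):
    """OLD20 requested with fewer than 20 candidate entries."""


class MissingStressError(ValueError):
    """A stress-dependent metric was asked of an unstressed polysyllable."""


# ---------------------------------------------------------------------------
# frequency scales
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ZipfParams:
    """Corpus constants of the Zipf scale, both in millions.

    Defaults are the constants of the source corpus behind the package's
    reference lexicon format: a 46.89-million-token corpus with 0.0353
    million distinct word types.
    """

    corpus_millions: float = 46.89
    types_millions: float = 0.0353

    def __post_init__(self):
        if self.corpus_millions <= 0 or self.types_millions < 0:
            raise ValueError("corpus and type sizes must be positive")
        if self.corpus_millions + self.types_millions <= 0:
            raise ValueError("denominator must be positive")


def zipf(count, params: ZipfParams = ZipfParams()):
    """Zipf value: log10 of Laplace-smoothed frequency per million, plus 3.

    ``zipf = log10((count + 1) / (corpus_millions + types_millions)) + 3``;
    a value of 3 corresponds to 1 occurrence per million tokens.  Accepts
    scalars or arrays; negative counts are a domain error.
    """
    arr = np.asarray(count, dtype=float)
    if np.any(arr < 0):
        raise ValueError("negative frequency count")
    out = np.log10((arr + 1.0) / (params.corpus_millions + params.types_millions)) + 3.0
    return float(out) if np.isscalar(count) or arr.ndim == 0 else out


def frequency_per_million(count, params: ZipfParams = ZipfParams()):
    """Raw (unsmoothed) frequency per million tokens."""
    arr = np.asarray(count, dtype=float)
    out = arr / params.corpus_millions
    return float(out) if np.isscalar(count) or arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# string similarity
# ---------------------------------------------------------------------------


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insertions, deletions, substitutions)."""
    if a == b:
        return 0
    return edlib.align(a, b)["editDistance"]


def _prep(word: str, stressed: bool) -> str:
    w = fold_sigma(word)
    return w if stressed else strip_stress(w)


def coltheart_n(word: str, lexicon: Iterable[str], stressed: bool = False) -> int:
    """Entries of equal length at Hamming distance exactly 1 (self excluded)."""
    w = _prep(word, stressed)
    n = 0
    for entry in lexicon:
        e = _prep(entry, stressed)
        if len(e) != len(w) or e == w:
            continue
        if sum(c1 != c2 for c1, c2 in zip(w, e)) == 1:
            n += 1
    return n


def old20(word: str, lexicon: Iterable[str], k: int = 20, stressed: bool = False) -> float:
    """Mean Levenshtein distance to the k closest other entries (OLD20).

    The word itself (exact string match, once) is excluded.  Fewer than
    ``k`` candidates raise :class:`InsufficientLexiconError` rather than
    silently averaging a partial set.
    """
    w = _prep(word, stressed)
    dists = []
    self_seen = False
    for entry in lexicon:
        e = _prep(entry, stressed)
        if e == w and not self_seen:
            self_seen = True
            continue
        dists.append(levenshtein(w, e))
    if len(dists) < k:
        raise InsufficientLexiconError(f"need at least {k} candidates, have {len(dists)}")
    return float(np.mean(np.partition(np.asarray(dists, dtype=float), k - 1)[:k]))


def old20_many(
    words: Sequence[str], lexicon: Sequence[str], k: int = 20, stressed: bool = False
) -> np.ndarray:
    """OLD20 for many words against one lexicon, with length pruning.

    Candidates are scanned in order of length difference from the target;
    the scan stops once the length difference alone exceeds the current
    k-th smallest distance (|len(a) - len(b)| lower-bounds the distance).
    """
    lex = [_prep(e, stressed) for e in lexicon]
    by_len: dict[int, list[str]] = {}
    for e in lex:
        by_len.setdefault(len(e), []).append(e)
    lengths = sorted(by_len)
    out = np.empty(len(words), dtype=float)
    for wi, word in enumerate(words):
        w = _prep(word, stressed)
        dists: list[int] = []
        self_seen = False
        worst = math.inf
        for diff in range(0, (max(lengths[-1], len(w)) + 1)):
            if diff > worst:
                break
            for L in ({len(w) + diff, len(w) - diff} if diff else {len(w)}):
                for e in by_len.get(L, ()):
                    if e == w and not self_seen:
                        self_seen = True
                        continue
                    dists.append(levenshtein(w, e))
            if len(dists) >= k:
                worst = np.partition(np.asarray(dists), k - 1)[k - 1]
        if len(dists) < k:
            raise InsufficientLexiconError(
                f"need at least {k} candidates, have {len(dists)}"
            )
        out[wi] = float(np.mean(np.partition(np.asarray(dists, dtype=float), k - 1)[:k]))
    return out


# ---------------------------------------------------------------------------
# stress-regularity endings
# ---------------------------------------------------------------------------


def rime(word: str) -> str:
    """Letters from the stressed vowel (inclusive) to the end, stress-stripped."""
    idx = stressed_vowel_index(word)
    if idx is None:
        raise MissingStressError(f"{word!r} carries no stress diacritic")
    return strip_stress(word[idx:])


def colombo_ending(word: str, syllab: Syllabification) -> str:
    """Ending from the pre-final syllable's nucleus vowel to the last letter.

    Stress diacritics are stripped.  Defined for words of at least two
    syllables; the nucleus of a merged CiV syllable is its full vowel,
    not the glide grapheme.
    """
    if syllab.n_units < 2:
        raise MissingStressError(f"{word!r}: ending undefined for monosyllables")
    if syllab.nuclei is None:
        raise ValueError("syllabification lacks nucleus spans (orthographic required)")
    prefinal = syllab.n_units - 2
    offset = sum(len(u) for u in syllab.units[:prefinal])
    nucleus_start = offset + syllab.nuclei[prefinal][0]
    return strip_stress(word[nucleus_start:])


class EndingGroups:
    """Stress-position counts per (stress-stripped) word ending.

    Built from parallel sequences of endings, numeric stress positions
    (1 = final, 2 = pre-final, 3 = antepenultimate) and token frequency
    counts.  Exposes type- and token-based proportions and the modal
    position per ending; every entry is included in its own group.
    """

    #: tie-break order: the corpus-global frequency order of positions
    TIE_BREAK: tuple[int, ...] = (2, 3, 1)

    def __init__(
        self,
        endings: Sequence[str],
        positions: Sequence[int],
        counts: Sequence[float] | None = None,
        tie_break: tuple[int, ...] | None = None,
    ):
        if counts is None:
            counts = np.ones(len(endings))
        df = pd.DataFrame({"ending": endings, "position": positions, "count": counts})
        self.type_counts = df.groupby(["ending", "position"]).size().unstack(fill_value=0)
        self.token_counts = (
            df.groupby(["ending", "position"])["count"].sum().unstack(fill_value=0.0)
        )
        if tie_break is not None:
            self.TIE_BREAK = tuple(tie_break)

    def _table(self, weighting: str) -> pd.DataFrame:
        if weighting == "type":
            return self.type_counts
        if weighting == "token":
            return self.token_counts
        raise ValueError(f"unknown weighting {weighting!r}")

    def __contains__(self, ending: str) -> bool:
        return ending in self.type_counts.index

    def proportions(self, ending: str, weighting: str = "type") -> pd.Series:
        row = self._table(weighting).loc[ending]
        return row / row.sum()

    def proportion_for(self, ending: str, position: int, weighting: str = "type") -> float:
        props = self.proportions(ending, weighting)
        return float(props.get(position, 0.0))

    def modal(self, ending: str, weighting: str = "type") -> int:
        """Modal stress position of the group; ties resolve by TIE_BREAK."""
        row = self._table(weighting).loc[ending]
        best = row.max()
        candidates = set(row.index[row == best])
        for pos in self.TIE_BREAK:
            if pos in candidates:
                return int(pos)
        return int(min(candidates))


def stress_neighbourhood(
    endings: Sequence[str],
    positions: Sequence[int],
    counts: Sequence[float] | None = None,
) -> EndingGroups:
    """Group entries by their (Colombo) ending and tally stress positions."""
    return EndingGroups(endings, positions, counts)


def rime_neighbourhood(
    word_rime: str, position: int, rimes: Sequence[str], positions: Sequence[int]
) -> int:
    """Other entries matching the target's rime string and stress position.

    The rime fixes the letter-distance of the stress from the word end,
    so matching entries share both the ending letters and the stress
    locus; the target itself (one occurrence) is excluded.
    """
    n = sum(1 for r, p in zip(rimes, positions) if r == word_rime and p == position)
    return max(n - 1, 0)


# ---------------------------------------------------------------------------
# syllable frequencies
# ---------------------------------------------------------------------------


def syllable_frequency_table(
    syllables: Sequence[Sequence[str]],
    counts: Sequence[float],
    stressed: bool = False,
    params: ZipfParams = ZipfParams(),
) -> pd.DataFrame:
    """Type/token counts and per-million rates for every syllable unit.

    ``syllables`` holds one syllable list per entry; ``counts`` the token
    frequency of each entry.  With ``stressed=False`` the tonos is
    stripped from the units before tallying.
    """
    rows: dict[str, list[float]] = {}
    for units, cnt in zip(syllables, counts):
        for u in units:
            s = u if isinstance(u, str) else "".join(u)
            if not stressed:
                s = strip_stress(s)
            rec = rows.setdefault(s, [0, 0.0])
            rec[0] += 1
            rec[1] += cnt
    df = pd.DataFrame(
        [(s, t, tok) for s, (t, tok) in rows.items()],
        columns=["syllable", "type_count", "token_count"],
    ).set_index("syllable")
    df["per_million"] = df["token_count"] / params.corpus_millions
    return df.sort_values("token_count", ascending=False)


def mean_syllable_frequency(
    units: Sequence[str], table: pd.DataFrame, column: str = "per_million"
) -> float:
    """Mean frequency of an entry's syllables under a frequency table."""
    vals = []
    for u in units:
        s = u if isinstance(u, str) else "".join(u)
        s = s if s in table.index else strip_stress(s)
        vals.append(table[column].get(s, 0.0))
    return float(np.mean(vals)) if vals else float("nan")


# ---------------------------------------------------------------------------
# inter-rater agreement
# ---------------------------------------------------------------------------


def fleiss_kappa(ratings) -> float:
    """Fleiss' kappa for an item × category count matrix.

    Every item must be rated by the same number of raters (n ≥ 2).
    Returns NaN when chance agreement is 1 (a single used category),
    where kappa is undefined.
    """
    table = np.asarray(ratings, dtype=float)
    if table.ndim != 2:
        raise ValueError("ratings must be a 2-D item x category matrix")
    row_sums = table.sum(axis=1)
    if len(set(row_sums.tolist())) != 1:
        raise ValueError("unequal rater counts per item")
    if row_sums[0] < 2:
        raise ValueError("need at least two raters per item")
    p_cat = table.sum(axis=0) / table.sum()
    if np.isclose((p_cat**2).sum(), 1.0):
        return float("nan")
    return float(_sm_fleiss_kappa(table))
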