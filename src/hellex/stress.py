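"""Stress-position extraction, ending-based prediction, distributions.

Greek lexical stress falls within a three-syllable window at the end of
the word; positions are coded numerically from the word end (1 = final,
2 = pre-final, 3 = antepenultimate, 0 = monosyllable).  Word endings are
strongly associated with stress position, and two predictors exploit
this:

* the *ending-majority* predictor assigns each polysyllable the modal
  stress position of the group of words sharing its orthographic ending
  (the stretch from the pre-final syllable's nucleus vowel to the last
  letter, stress-stripped);
* the *rime-hierarchy* predictor scans the word's suffixes from longest
  to shortest and uses the modal position of the first suffix attested
  as a rime (stressed vowel to final letter) in the lexicon.

Both are evaluated by type (entry counts) or token (frequency mass).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .greek_text import strip_stress
from .metrics import EndingGroups, MissingStressError
from .syllabification import Syllabification

__all__ = [
    "MONOSYLLABLE",
    "FINAL",
    "PREFINAL",
    "ANTEPENULT",
    "POSITION_LABELS",
    "stress_position",
    "EndingStressModel",
    "RimeHierarchyModel",
    "StressPredictionResults",
    "evaluate_stress_prediction",
    "distribution_tables",
]

MONOSYLLABLE = 0
FINAL = 1
PREFINAL = 2
ANTEPENULT = 3

POSITION_LABELS = {
    MONOSYLLABLE: "monosyllable",
    FINAL: "final",
    PREFINAL: "pre-final",
    ANTEPENULT: "antepenultimate",
}


def position_label(pos: int) -> str:
    return POSITION_LABELS.get(pos, f"earlier({pos})")


def stress_position(syllab: Syllabification) -> int:
    """Numeric stress position counted from the word end.

    Monosyllables return 0; a polysyllable without a stressed unit is a
    data error.  Values above 3 are representable (non-Greek or synthetic
    input) but violate the Greek three-syllable window.
    """
    if syllab.n_units == 1:
        return MONOSYLLABLE
    if syllab.stressed_unit is None:
        raise MissingStressError("polysyllable without a stressed unit")
    return syllab.n_units - syllab.stressed_unit + 1


# ---------------------------------------------------------------------------
# predictors
# ---------------------------------------------------------------------------


@dataclass
class StressPredictionResults:
    """Evaluation of a stress predictor on a lexicon.

    ``accuracy`` is the proportion of polysyllabic entries (type) or of
    their frequency mass (token) whose predicted position matches the
    true one; ``confusion`` is a true × predicted table in the same
    weighting.  Entries the predictor cannot cover (ending unattested)
    count as incorrect and are tallied in ``n_unpredicted``.
    """

    method: str
    weighting: str
    accuracy: float
    confusion: pd.DataFrame
    n_entries: int
    n_unpredicted: int = 0

    def summary(self) -> str:
        lines = [
            f"Stress prediction by {self.method} ({self.weighting} weighting)",
            f"  polysyllabic entries: {self.n_entries}"
            + (f" ({self.n_unpredicted} without prediction)" if self.n_unpredicted else ""),
            f"  accuracy: {self.accuracy:.4f}",
            "",
            self.confusion.to_string(),
        ]
        return "\n".join(lines)


class EndingStressModel:
    """Ending-majority stress predictor.

    ``fit`` tallies stress positions per orthographic ending (each entry
    included in its own group); ``predict`` returns the group's modal
    position.  ``weighting`` selects whether modal positions are found
    by entry counts ("type") or frequency mass ("token"); ties break in
    the corpus-global order pre-final > antepenultimate > final.
    """

    def __init__(self, weighting: str = "type", tie_break: tuple[int, ...] = (2, 3, 1)):
        self.weighting = weighting
        self.tie_break = tie_break
        self.groups_: EndingGroups | None = None

    def fit(
        self,
        endings: Sequence[str],
        positions: Sequence[int],
        counts: Sequence[float] | None = None,
    ) -> "EndingStressModel":
        self.groups_ = EndingGroups(endings, positions, counts, tie_break=self.tie_break)
        return self

    def predict_one(self, ending: str) -> int | None:
        """Modal position for one ending; None when the ending is unattested."""
        if self.groups_ is None:
            raise RuntimeError("model is not fitted")
        if ending not in self.groups_:
            return None
        return self.groups_.modal(ending, self.weighting)

    def predict(self, endings: Sequence[str]) -> list[int | None]:
        return [self.predict_one(e) for e in endings]


class RimeHierarchyModel:
    """Longest-suffix rime predictor.

    ``fit`` indexes stress-position counts by rime string (stressed
    vowel to final letter, stress-stripped).  ``predict`` scans a word's
    suffixes from longest to shortest and returns the modal position of
    the first attested one.
    """

    def __init__(self, weighting: str = "type", tie_break: tuple[int, ...] = (2, 3, 1)):
        self.weighting = weighting
        self.tie_break = tie_break
        self.index_: EndingGroups | None = None

    def fit(
        self,
        rimes: Sequence[str],
        positions: Sequence[int],
        counts: Sequence[float] | None = None,
    ) -> "RimeHierarchyModel":
        self.index_ = EndingGroups(rimes, positions, counts, tie_break=self.tie_break)
        return self

    def predict_one(self, word: str) -> int | None:
        if self.index_ is None:
            raise RuntimeError("model is not fitted")
        bare = strip_stress(word)
        for start in range(len(bare)):
            suffix = bare[start:]
            if suffix in self.index_:
                return self.index_.modal(suffix, self.weighting)
        return None

    def predict(self, words: Sequence[str]) -> list[int | None]:
        return [self.predict_one(w) for w in words]


def evaluate_stress_prediction(
    true_positions: Sequence[int],
    predicted: Sequence[int | None],
    counts: Sequence[float] | None = None,
    n_syllables: Sequence[int] | None = None,
    method: str = "ending",
    weighting: str = "type",
) -> StressPredictionResults:
    """Score predictions against true stress positions.

    Monosyllables (true position 0) are excluded.  A prediction of None,
    or one whose numeric value exceeds the word's syllable count, counts
    as incorrect.  ``counts`` switches the accuracy to frequency mass.
    """
    true_arr = np.asarray(true_positions)
    mask = true_arr != MONOSYLLABLE
    if not mask.any():
        raise ValueError("no polysyllabic entries to evaluate")
    w = np.ones(len(true_arr)) if counts is None else np.asarray(counts, dtype=float)
    pred = np.array([-1 if p is None else int(p) for p in predicted])
    if n_syllables is not None:
        nsyl = np.asarray(n_syllables)
        pred = np.where(pred > nsyl, -2, pred)  # impossible position -> incorrect
    correct = (pred == true_arr) & mask
    acc = float(w[correct].sum() / w[mask].sum())
    conf = (
        pd.DataFrame({"true": true_arr[mask], "predicted": pred[mask], "w": w[mask]})
        .groupby(["true", "predicted"])["w"]
        .sum()
        .unstack(fill_value=0.0)
    )
    return StressPredictionResults(
        method=method,
        weighting=weighting,
        accuracy=acc,
        confusion=conf,
        n_entries=int(mask.sum()),
        n_unpredicted=int(((pred == -1) & mask).sum()),
    )


# ---------------------------------------------------------------------------
# distribution tables
# ---------------------------------------------------------------------------


def distribution_tables(
    df: pd.DataFrame,
    by: str = "overall",
    count_col: str = "frequency_count",
    params_corpus_millions: float | None = None,
) -> pd.DataFrame:
    """Stress-position distributions by types and tokens.

    ``df`` needs columns ``stress_position``, ``n_syllables``,
    ``count_col`` and, for ``by="pos"``, ``pos_primary``.  ``overall``
    mirrors the canonical database table with monosyllables kept as a
    separate row (they can only stress their sole syllable); ``by=
    "syllable_length"`` gives one distribution per syllable count;
    ``by="pos"`` restricts to nouns, adjectives and verbs.  Token counts
    are reported per million when a corpus size is given.
    """
    d = df.copy()
    scale = 1e6 / (params_corpus_millions * 1e6) if params_corpus_millions else 1.0

    def _tab(sub: pd.DataFrame, keys) -> pd.DataFrame:
        g = sub.groupby(keys, observed=True)
        out = pd.DataFrame(
            {
                "type_count": g.size(),
                "token_count": g[count_col].sum() * scale,
            }
        )
        return out

    if by == "overall":
        d["row"] = np.where(
            d["n_syllables"] == 1,
            "monosyllable",
            d["stress_position"].map(position_label),
        )
        tab = _tab(d, "row")
    elif by == "syllable_length":
        poly = d[d["n_syllables"] > 1].copy()
        poly["position"] = poly["stress_position"].map(position_label)
        tab = _tab(poly, ["n_syllables", "position"])
    elif by == "pos":
        sub = d[d["pos_primary"].isin(["noun", "adjective", "verb"])].copy()
        sub = sub[sub["n_syllables"] > 1]
        sub["position"] = sub["stress_position"].map(position_label)
        tab = _tab(sub, ["pos_primary", "position"])
    else:
        raise ValueError(f"unknown grouping {by!r}")

    level = 0 if by == "overall" else list(range(tab.index.nlevels - 1))
    for col in ("type_count", "token_count"):
        if by == "overall":
            tab[col.replace("_count", "_pct")] = 100 * tab[col] / tab[col].sum()
        else:
            tab[col.replace("_count", "_pct")] = (
                100 * tab[col] / tab.groupby(level=level)[col].transform("sum")
            )
    return tab
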