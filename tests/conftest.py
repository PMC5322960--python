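"""Shared fixtures and independent oracle implementations.

The oracles are deliberately naive (pure-Python dynamic programming,
exhaustive counting, closed-form formulas) and independent of the code
paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from hellex.synthetic import SyntheticConfig, generate

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def dp_levenshtein(a: str, b: str) -> int:
    """Textbook dynamic-programming edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def brute_old20(word: str, lexicon: list[str], k: int = 20) -> float:
    dists = sorted(dp_levenshtein(word, e) for e in lexicon if e != word)
    return float(np.mean(dists[:k]))


def brute_coltheart_n(word: str, lexicon: list[str]) -> int:
    return sum(
        1
        for e in lexicon
        if e != word
        and len(e) == len(word)
        and sum(c1 != c2 for c1, c2 in zip(e, word)) == 1
    )


def closed_form_fleiss_kappa(table: np.ndarray) -> float:
    """Fleiss' kappa from its defining formula."""
    table = np.asarray(table, dtype=float)
    n = table.sum(axis=1)[0]
    p_cat = table.sum(axis=0) / table.sum()
    p_item = ((table**2).sum(axis=1) - n) / (n * (n - 1))
    p_bar = p_item.mean()
    p_e = (p_cat**2).sum()
    return (p_bar - p_e) / (1 - p_e)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def small_lexicon():
    """A 300-word seeded synthetic lexicon with gold annotations."""
    return generate(SyntheticConfig(n_words=300, seed=11))


@pytest.fixture(scope="session")
def big_lexicon():
    """A 10,000-word seeded synthetic lexicon (θ = 0.9)."""
    return generate(SyntheticConfig(n_words=10_000, theta=0.9, seed=1))
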