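# hellex

A Greek psycholinguistic lexicon toolkit: rule-based grapheme-to-phoneme
transcription, orthographic (school-grammar) and phonological
(maximal-onset) syllabification, lexical-stress analysis, orthographic
and phonological similarity metrics, and a pipeline that turns a plain
word + frequency list into a fully annotated lexicon table.

It is aimed at psycholinguists building or extending lexical databases
for Modern Greek: selecting stimuli by stress neighbourhood, syllable
frequency, Coltheart's N or OLD20, or enriching a frequency corpus with
phonological and stress annotations.

## What it computes

* **Transcription** — an ordered grapheme→phone rule table (digraphs,
  velar palatalization κ/χ/γ → c/ç/ʝ, σ-voicing, αυ/ευ → [av/af, ev/ef],
  nasal+stop simplification [mb]→[b]), with the ambiguous **CiV**
  pattern (consonant + unstressed i-grapheme + vowel) resolved by a
  majority table plus exception lexicon: κυάνιο → [ci-'a-ni-o] but
  γυάλα → ['ʝa-la].
* **Syllabification** — orthographic: an intervocalic cluster opens a
  syllable iff some Greek word begins with it; phonological: maximal
  onset under manner/place-of-articulation scales with a voicing
  criterion, a strict rule set under which [mv], [rm], [rp] are split
  (καμβάς → kam-'vas, άρμα → 'ar-ma).
* **Stress** — positions in the Greek three-syllable window (final,
  pre-final, antepenultimate); ending-majority and rime-hierarchy
  predictors with type/token evaluation; distribution tables by
  syllable length and part of speech.
* **Metrics** — Zipf value `log10((count+1)/(46.89+0.0353)) + 3`,
  frequency per million, Levenshtein distance, Coltheart's N,
  OLD20/PLD20, rime and stress neighbourhood, syllable frequency
  tables, Fleiss' kappa.
* **Synthetic lexicons** — a seeded generator of Greek-like words with
  planted ending→stress consistency θ, Zipfian counts and
  part-of-speech stress profiles, used throughout the test suite.

See `docs/methods.md` for the models and their assumptions.

## Worked example

```python
import pandas as pd
from hellex import BuildConfig, PosDictionary, build_database

wordfreq = pd.DataFrame(
    {"word": ["γέρος", "πατέρας", "καμβάς"], "frequency_count": [30, 20, 10]}
)
db = build_database(wordfreq, BuildConfig(pos_dictionary=PosDictionary.fixture(),
                                          compute_similarity=False))
print(db[["word", "orth_syllables", "phon_syllables", "n_syllables",
          "stress_position", "stress_ending", "zipf"]].to_string(index=False))
```

prints

```
   word orth_syllables phon_syllables  n_syllables  stress_position stress_ending     zipf
  γέρος         γέ-ρος        'ʝε-ros            2                2          ερος 2.819955
πατέρας      πα-τέ-ρας     pa-'tε-ras            3                2          ερας 2.650812
 καμβάς        καμ-βάς       kam-'vas            2                1         αμβας 2.369986
```

Each row carries the school-grammar and maximal-onset parses (note the
[mv] split in καμβάς), the stress position counted from the word end
(2 = pre-final, 1 = final), the orthographic ending that defines the
word's stress neighbourhood (from the pre-final syllable's nucleus
vowel to the last letter, stress-stripped), and the Zipf frequency
value (3 ≈ 1 per million; these toy counts sit just below that).

The same operations are available word-by-word
(`transcribe`, `syllabify_orthographic`, `syllabify_phonological`,
`rime`, `old20`, …) and from the command line:

```sh
hellex transcribe words.txt        # word TAB transcription
hellex syllabify --mode phon words.txt
hellex build wordfreq.tsv --out lexicon.tsv
hellex simulate --n 10000 --theta 0.9 --seed 1 --out synth.tsv
```

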