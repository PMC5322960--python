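# Methods

This note documents the linguistic models implemented in `hellex`, the
choices made where the design was genuinely open, and what the
synthetic-data tests do and do not establish.

## Text model

Words are held in Unicode NFC, so accented vowels (ά, ΐ, …) are single
code points and letter indices coincide with naive letter counts.
Lexical stress is the acute diacritic (tonos), at most one per word;
uppercase input is lowercased (uppercase Greek carries no diacritics)
with the word-final sigma allograph restored.  For every metric and
rule lookup, ς is folded to σ — the allographs are one letter — while
output preserves the written form.  Vowels with dialytika (ϊ, ϋ) are
treated as distinct letters in metrics; the dialytika survives stress
stripping.  This treatment of dialytika in similarity metrics is an
assumption (alternatives exist), flagged here deliberately.

## Grapheme-to-phoneme transcription

Greek orthography is nearly deterministic from print to sound, so the
transcriber is an ordered rule table applied longest-grapheme-first:
vowel digraphs (ου, αι, ει, οι, υι), the αυ/ευ/ηυ groups (υ realized
[v] before voiced segments, [f] before voiceless or word-finally),
consonant digraphs (μπ, ντ, γκ/γγ → plain voiced stop word-initially,
nasal + stop word-medially; τσ/τζ → affricates), velar palatalization
(κ, χ, γ → c, ç, ʝ immediately before front vowels), σ-voicing before
voiced consonants, and degemination of double consonant letters.
Symbols follow the convention of Greek lexical databases (δ, γ, θ, ε);
`PhoneSeq.to_ipa()` maps to IPA (ð, ɣ, θ, e).

The one systematic ambiguity is the CiV pattern: consonant + unstressed
i-sounding grapheme + vowel, which reads either as a full [i] (two
syllables: κυάνιο [ci-'a-ni-o]) or as a glide/palatalization (one
syllable: γυάλα ['ʝa-la], νιώθω ['ɲo-θo]).  The decision is made by the
syllabification layer (below) and threaded into the transcriber.  When
the i-grapheme is consumed: a preceding ν/λ palatalizes to [ɲ]/[ʎ], a
preceding velar palatalizes (κ→c, χ→ç, γ→ʝ), otherwise a glide is
inserted — [ʝ] after voiced consonants (διαβάτης [δʝa-'va-tis]), [ç]
after voiceless ones (κλεψιά [kle-'psça]).

Nasal + homorganic voiced stop pairs ([mb], [nd], [ŋg]) are simplified
by dropping the nasal; this is the default output (αντένα [a'dεna]) and
can be disabled (`simplify=False`) for the allophonic forms.  The
cross-database comparison normalization additionally unstresses
monosyllables, maps the labiodental nasal [ɱ] to [m], and collapses the
[e]/[ε] symbol variants, so that different symbol conventions compare
equal.

## Syllabification

**Orthographic (school-grammar).**  One syllable per vowel-grapheme
group; an intervocalic consonant cluster opens the next syllable iff a
Greek word *begins* with that cluster, otherwise its first letter
closes the previous syllable (the grammar states this split once; a
recursive variant is available behind a flag and documented as an
extension).  Single intervocalic consonants are always onsets.  The
attested-onset inventory ships as JSON and can be rebuilt from any word
list; inventories are prefix-closed (στρ attested ⇒ στ, σ attested),
since any prefix of a word-initial cluster also begins a word reading.

**Phonological (maximal onset).**  Over the phone string, each
intervocalic consonant run contributes its longest *legal* suffix as
the next onset; the remainder becomes the previous coda.  Word-initial
runs attach wholly to the first syllable whatever their legality, and
coda legality is not checked (for runs of three or more consonants the
rightmost-maximal-legal-suffix rule cannot guarantee it).

**Onset legality.**  Consonants carry ordinal manner
(stop < affricate < fricative < nasal < liquid) and place
(labial < coronal < palatal < velar) ranks plus binary voicing, shipped
as an editable JSON config — the classification is data, the engine is
code.  A pair is scale-legal when its first member is strictly leftmost
on manner *or* place.  The default rule set is deliberately strict:
nasal/liquid pairs are evaluated on both scales (no "free pass"),
falling voicing (voiced before voiceless) forces a split on its own,
and liquid-initial and nasal+liquid clusters are always heterosyllabic.
Under these rules [mv] (καμβάς → kam-'vas), [rm] and [rp] (άρμα, άρπα)
are split, while [θr], [ps], [ft], [mn] remain legal.  The voicing
criterion is implemented as *falling* voicing rather than any
disagreement, because a symmetric reading would wrongly split
voiceless-fricative + liquid onsets like [θr].  A permissive preset
(`ClusterRuleSet.iplr_style()`) restores the liberal policy of earlier
resources (nasal/liquid free pass, no voicing splits), under which
[mv], [rm], [rp] become legal — the rule set alone determines the flip.
A whitelist slot exists for attested clusters that the scales reject
(s+stop, κτ, …); it ships empty because no authoritative enumeration is
available, and users can populate it.

**CiV disambiguation.**  An exception lexicon (word → one|two) wins
over a per-cluster majority table; a tie in the majority counts
resolves to two syllables (the conservative full-vowel reading); sites
covered by neither raise an error unless a default is configured.  The
shipped majority counts are curated defaults for the common clusters
and the shipped exception list covers the documented examples; both are
plain-text configs meant to be replaced by corpus-derived tables
(`civ_majority_table`) where gold parses exist.

## Metrics

* **Zipf** = log10((count + 1) / (corpus_millions + types_millions)) + 3,
  i.e. log10 of Laplace-smoothed frequency per million plus 3; value 3
  marks 1 per million.  Defaults: 46.89 M tokens, 0.0353 M types.
* **Levenshtein** is unit-cost edit distance (edlib backend);
  **Coltheart's N** counts same-length entries at Hamming distance 1;
  **OLD20/PLD20** average the 20 smallest distances to other entries,
  with a length-difference pruning scan for corpus-scale computation.
  Fewer than 20 candidates is an error, not a silent partial mean.
  The target itself is excluded from all three.
* **Rime** = letters from the stressed vowel to the end (stress-
  stripped); **ending** (Colombo's criterion) = from the pre-final
  syllable's nucleus vowel to the end.  For a merged CiV syllable the
  nucleus is the full vowel, not the glide grapheme (γυάλα → "αλα").
  **Rime neighbourhood** counts other entries with identical rime and
  stress position; **stress neighbourhood** is the proportion of
  same-ending entries sharing the target's stress position, *including*
  the target in its own group (so single-carrier endings give 1.0 and a
  fully consistent lexicon is perfectly predictable).
* **Syllable frequency** tables tally type and token counts and
  per-million rates for stressed and stress-stripped units separately.
* **Fleiss' kappa** wraps the statsmodels implementation with shape
  validation; a single used category makes chance agreement 1 and kappa
  undefined (NaN).

## Stress analysis

Positions are counted from the word end (1 final, 2 pre-final,
3 antepenultimate; 0 monosyllable); Greek confines stress to this
three-syllable window.  The ending-majority predictor assigns each
polysyllable the modal position of its ending group; the rime-hierarchy
predictor scans suffixes longest-first and uses the first one attested
as a rime.  Ties break pre-final > antepenultimate > final, the
corpus-global frequency order; the order is configurable.  Evaluation
is by type (entry counts) or token (frequency mass, using raw counts so
results are invariant to corpus-size normalization); monosyllables are
excluded, unpredicted entries and predictions exceeding the word's
syllable count score as incorrect.

## Synthetic lexicons

The generator composes words from attested syllable parts — onsets that
are both attested word-initial clusters and scale-legal, CV nuclei, and
word-final codas only — so gold syllabifications and transcriptions
exist by construction, there are no CiV sites or internal codas, and
both parsers must recover the generative parse exactly.  Planted
structure: each polysyllable draws an ending (pre-final nucleus + final
syllable) from a per-category inventory; stress falls on the ending's
modal position with probability θ (default 0.9), else uniformly on the
other valid positions (word length is resampled to ≥ 3 syllables when
the modal position is antepenultimate, keeping the planted mass exact).
Token counts follow a Zipf law (default exponent 1.05 over 10,000
words, top count 10⁶).  Part-of-speech mixture defaults to
noun .59 / adjective .26 / verb .15, with stress-profile defaults that
make adjectives disfavour the pre-final position while nouns and verbs
favour it — a stylized version of the patterns reported for Greek
lemmas.  The syllable-length distribution defaults to a 1–7-syllable
profile peaking at four syllables, matching published Greek lemma
counts.

What the synthetic tests show: the parsers are exact on words built
from legal parts; the predictors recover planted consistency (token
accuracy within the 99% binomial CI of θ using the Kish effective
sample size of the Zipfian weights; θ = 1 gives exactly 1.0); the
qualitative category patterns are reproduced.  What they do not show:
behaviour on real Greek morphology (hiatus, CiV sites, internal codas,
loanwords), on which the rule configs — not the algorithms — carry the
burden; the worked-example suite covers those paths pointwise.

## Numerical and degenerate-input choices

Problem sizes in the shipped checks: structural invariants on 10,000
generated words; parameter recovery at n = 10,000; similarity-metric
correlation at n = 1,500 (the OLD20/PLD20 computation is quadratic).
Determinism: every stochastic component takes a seed; rebuilding a
database from the same inputs and config is byte-identical.  Degenerate
inputs: vowel-less strings raise a no-nucleus error; unstressed
polysyllables raise a missing-stress error from stress-dependent
operations; per-word failures in the build pipeline are recorded in an
`error` column without aborting the run.

## Known limitations

Polytonic Greek, cross-word sandhi and prosody are out of scope.  The
PoS interface is a dictionary cross-check; no contextual tagger is
included, and the shipped dictionary is a small synthetic fixture.  The
theoretical status of palatalization versus syllable structure is not
resolved here — the CiV machinery is an engineering device, not a
phonological claim.
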