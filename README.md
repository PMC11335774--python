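# lexstat

Disambiguated lexical-statistics databases from dependency-parsed corpora,
for psycholinguistic stimulus selection.

Researchers assembling word stimuli (for lexical decision, eye tracking,
priming, ...) need to manipulate one lexical property while matching all the
others: surface and lemma frequency, length, letter N-gram frequencies,
orthographic neighborhood, word class and morphology. For a morphologically
rich language such as Finnish — thousands of potential forms per noun or
verb, pervasive form/lemma ambiguity — these norms must be computed from a
parsed corpus, not a plain word list. `lexstat` builds such a database from
[CoNLL-U](https://universaldependencies.org/format.html) (Universal
Dependencies) corpora and lets you query it with a small conjunctive query
language or look up ready-made word lists.

## What it computes

A database row is the unique quadruple *(lemma, word class, surface form,
core-feature string)*, where the core features are the disambiguating subset
of UD morphology (case, number, person; verb form, mood, tense, voice;
clitic, derivation; possessor person/number). On top of the raw counts:

- **Relative frequencies** per million tokens of the stored (post-pruning)
  corpus: `rel(x) = x · 10⁶ / N`.
- **N-gram statistics**: token-weighted corpus tables of letter bigrams and
  initial/final trigrams; per form, the average bigram frequency
  `bigramfreq(w) = (1/(|w|−1)) Σᵢ count(wᵢwᵢ₊₁)` and the initial/final
  trigram frequencies (assigned only to forms of length ≥ 4).
- **Form ambiguity** — the probability that a token of form *f* belongs to a
  *different* lemma/word-class reading:
  `ambform(l, p, f) = 1 − freq(l, p, f) / freq(f)`.
- **Lemma ambiguity** — the frequency-weighted probability that a token of
  lemma/word-class *(l, p)* surfaces as an ambiguous form:
  `amblemma(l, p) = Σ_f freq(l, p, f) · 1[ambform(l, p, f) ≥ 0.01] / lemmafreq(l, p)`,
  the 1 % threshold absorbing parser noise.
- **Orthographic neighborhood** (filtered Coltheart's N): distinct same-length
  forms at Hamming distance 1, where candidates with form frequency
  ≥ `autofreq` (10 000) enter automatically, those below `minfreq` (100) are
  excluded, and the band between is arbitrated by a pluggable validity
  oracle (e.g. membership in a spelling lexicon).

Queries are AND-conjunctions of `key operator value` parts
(`=`, `!=`, `<`, `>`, `in`, `not in`, bare flags), all input lowercased:

```
pos in noun,num and end in sta,na,a and case = nom and number = sing
and len> 5 and len< 9 and rellemmafreq> 1 and relfrequency> 0.1
and not compound and posspers not in 1,2,3 and ambform< 0.95
```

## Worked example

The package ships exact fixtures of published worked examples for Finnish.
The form *voi* is at once the present-tense verb *voida* ('to be able to'),
an interjection ('oh'), and the noun 'butter':

```python
from lexstat import builtin_fixture, db_from_spec, evaluate

db = db_from_spec(builtin_fixture("table3_voi"))
print(evaluate(db, "form = voi")[
    ["lemma", "lemmafreq", "pos", "frequency", "ambform", "amblemma", "feats"]
].to_string(index=False))
```

```
lemma  lemmafreq  pos  frequency  ambform  amblemma                                        feats
voida   15663469 VERB    7810951 0.048742       1.0 Number=Sing|Person=3|Tense=Pres|VerbForm=Fin
voida   15663469 VERB    4196751 0.048742       1.0 Number=Sing|Person=0|Tense=Pres|VerbForm=Fin
voida   15663469 VERB    3655767 0.048742       1.0                      Tense=Pres|VerbForm=Fin
  voi     750292 INTJ     750292 0.954434       1.0                                            _
  voi      52296 NOUN      52296 0.996824       1.0                         Case=Nom|Number=Sing
```

Reading the ambiguity column: a token spelled *voi* is only ~4.9 % likely to
be something other than the verb, but 95.4 % likely to be something other
than the interjection and 99.7 % other than the noun — the noun 'butter' is
a poor visual stimulus if you need its reading to be the one accessed. `amblemma` is 1.0 for every reading here
because the single form *voi* is ambiguous (ambform ≥ 0.01) for each owner;
an uninflectable interjection can never escape that.

The same pipeline from the shell:

```
lexstat build corpus.conllu --db lexicon.db
lexstat prune --db lexicon.db --min-freq 10
lexstat query "form = silmäsi" --db lexicon.db --out rows.csv
lexstat wordlist stimuli.txt --db lexicon.db --mode nonword --out ngrams.csv
```

On the *silmäsi* fixture ('your eye(s)') the query returns its three
analyses — plural nominative, singular genitive, singular nominative — as
three CSV rows with frequencies 13464, 4600 and 1307.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
rebuilds the worked-example databases from their fixtures, verifies the
ambiguity values and query results above, round-trips a seeded synthetic
corpus through CoNLL-U text, pruning, aggregation, querying (cross-checked
against a brute-force row scanner) and wordlist lookup, then writes the
results JSON to `--out`.
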