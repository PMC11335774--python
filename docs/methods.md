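# Methods

## The database model

The unit of storage is the quadruple **(lemma, word class, surface form,
core-feature string)**; exactly one row exists per quadruple, carrying the
number of corpus tokens with that exact reading. Lemma-level quantities use
the pair (lemma, word class) as the lemma key. Forms and lemmas are
lowercased on ingestion so that frequencies are case-insensitive; all
relative values are computed against the token total of the data actually
stored, so pruning changes both raw survivorship and every per-million
value. Derived statistics are therefore only computed *after* pruning, and
any prune invalidates them.

### Core features and their serialization

Eleven UD features are retained: Case, Number, Person, VerbForm, Mood,
Tense, Voice, Clitic, Derivation, and the possessor's Person[psor] /
Number[psor]. The set balances disambiguation against combinatorial
explosion and parser noise: features like Degree, Polarity and Style are
projected away before aggregation, so two tokens differing only in a
dropped feature merge into one row. The canonical feature string is the
CoNLL-U convention — `Key=Value` pairs joined by `|` in case-insensitive
alphabetical key order, `_` for the empty set — and row identity is defined
as equality of these strings.

### Token pre-filter

A token is counted only if both its form and lemma consist of characters in
the per-language charset (Finnish default: `a–z å ä ö š ž`, digits, internal
hyphen and apostrophe), begin with an alphanumeric character and contain at
least one letter, and if the form is 2–100 characters long. The lower bound
reflects that Finnish has no one-character words; the upper bound removes
web-crawler artifacts (real Finnish words max out around 40 characters).
Compounds are flagged when the lemma contains the compound separator
(default `#`, the Finnish UD convention); the separator is stripped from
the stored lemma so queries use plain orthography. Multiword-token range
rows and empty-node rows of CoNLL-U are skipped: counts are per running
syntactic word.

### Merging and pruning

Partial databases (e.g. one per input file) merge by key union with
frequency summation — an UPSERT — and the test suite verifies that sharded
building equals single-pass aggregation exactly. Pruning removes rows below
a minimum frequency and rows with word class PUNCT, SYM or X, then
recomputes the token total over survivors; it is idempotent.

## Derived statistics

- **posx**: AUX folds into VERB; all other tags map to themselves. Queries
  on the word class use posx unless a value names `aux` explicitly.
- **N-gram tables** are token-weighted: each distinct form contributes its
  form-level total frequency to every bigram occurrence inside it
  (multiplicity counted) and, at length ≥ 3, to its initial and final
  trigram. The published description of bigram counting is a footnote not
  available to us; token weighting with within-form multiplicity is this
  package's stated interpretation, consistent with the "cumulative
  frequency" wording and per-million scaling. Length-3 forms feed the
  trigram *tables* but receive no trigram *features*: the features require
  length ≥ 4, since a three-letter word's only trigram would be
  simultaneously initial and final.
- **ambform** and **amblemma** are stored at full precision; the
  three-decimal precision seen in exports is a rendering rule only. The
  amblemma threshold (default 0.01) is inclusive: a form with
  ambform exactly at the threshold counts as ambiguous. It is exposed as a
  parameter because it is a noise allowance, not a structural constant.
- **Neighborhood** is computed over distinct orthographic forms (not rows),
  with candidate inclusion decided by form-level total frequency:
  automatic at ≥ autofreq (10 000), excluded below minfreq (100), otherwise
  delegated to the validity oracle. The defaults were tuned on a
  multi-billion-token corpus and deliberately not rescaled for small
  databases. The oracle replaces a language-bound morphological analyzer;
  the default accepts everything, and the CLI can load a wordlist lexicon
  instead. The implementation buckets forms by single-position wildcard
  patterns (linear in total characters); an O(n²) pairwise scan serves as
  the independent test oracle.

## Query language

Conjunction-only: parts joined by `and`, no OR, no parentheses, no ≤/≥.
Set membership via `in`/`not in` is the only disjunction. All input is
lowercased. Rows lacking a feature fail positive predicates on it and
satisfy negative ones — `posspers not in 1,2,3` must keep words with no
possessive suffix. Result ordering is descending form frequency with
lexicographic tie-break (the choice is ours; the original tool's GUI is
merely sortable); the row cap defaults to 10 000. Values containing commas
cannot appear in `in` lists (the grammar has no quoting). The key set is
table-driven (`lexstat.query.DEFAULT_REGISTRY`) so it can be corrected or
extended per language. The vectorized evaluator (pandas masks) is
cross-checked in the tests against an independent row-by-row scanner on
randomized databases and queries.

## Synthetic data

`lexstat.fixtures` states corpora as exact multisets of readings with
multiplicities; the CoNLL-U emitter shuffles token order by seed, and every
aggregate is seed-invariant by construction (verified). The built-in
fixtures reproduce the published worked-example tables cell for cell,
including the 16,466,057-token *voi* table. What the generator does *not*
emulate: sentence structure (heads/deprels are a flat dummy analysis),
Zipfian frequency distributions, or realistic parser noise beyond what the
fixtures encode — so a green property suite establishes algebraic
correctness of the pipeline, not robustness to real parser error patterns.
Full-corpus published values that depend on rows outside the printed tables
(e.g. the verb reading's ambform of 0.050, or amblemma 0.512/0.913) are
context, not test targets; the fixture-computable values (0.954, 0.997,
1.000, the 156,925 lemma total, the 0.914 weighted indicator sum) are
asserted exactly at the printed precision.

## Numerical and degenerate-input choices

Relative frequency on an empty database raises rather than returning 0/0.
N-gram annotation requires length ≥ 2 (one bigram). ambform values are exact
rational arithmetic in floating point; the partition invariant
Σ(1 − ambform) = 1 per form is tested at 1e−9. Ties in hashing/ordering
never affect stored values: all aggregation is order-invariant, which the
shuffle-seed tests enforce. Storage is a single-file SQLite database
(stdlib `sqlite3`) holding the entry table and metadata (language, token
total, applied minimum frequency); loading reconstructs the in-memory
database losslessly and derived statistics are recomputed on demand.

## Limitations

No dependency parsing, no boilerplate cleaning, no morphological family
size, no syllable features, no phonological variables, no OR queries, no
GUI. Excel/clipboard export is out of scope (CSV/TSV cover the data path).
Neighborhood quality for languages other than Finnish depends entirely on
the validity oracle supplied.
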