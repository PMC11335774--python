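"""Derived lexical statistics over a pruned lexicon.

This module computes everything the stimulus-selection queries filter on
beyond raw row frequency:

* lemma frequencies — token count of a (lemma, word class) pair summed over
  all its surface forms and feature strings;
* relative frequencies — occurrences per one million tokens of the stored
  (post-pruning) corpus;
* letter N-gram tables and per-form features — token-weighted corpus counts
  of bigrams and of initial/final trigrams, and the per-form average-bigram
  and trigram frequencies derived from them;
* two ambiguity measures, ``ambform`` and ``amblemma``;
* filtered orthographic neighborhood size (Hamming distance 1).

ambform(lemma, pos, form) is the probability that a token of the surface
form belongs to a *different* (lemma, pos) reading:

    ambform(l, p, f) = 1 - freq(l, p, f) / freq(f)

where freq(l, p, f) sums over feature strings and freq(f) over every reading
of the form.  amblemma(lemma, pos) is the frequency-weighted probability
that a token of the lemma surfaces as an ambiguous form, a form counting as
unambiguous only when its ambform lies below a noise threshold (1% by
default — with parser noise, demanding exactly zero would mark nearly
everything ambiguous):

    amblemma(l, p) = sum_f freq(l, p, f) * [ambform(l, p, f) >= t] / lemmafreq(l, p)

Neighborhood counts distinct same-length forms differing in exactly one
character, filtered against noise: candidates at or above ``autofreq`` are
included automatically, candidates below ``minfreq`` are excluded, and the
band in between is arbitrated by a pluggable validity oracle (standing in
for a language-specific morphological analyzer / spelling dictionary).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Callable, Dict, Mapping, Optional, Tuple

import pandas as pd

from .db import LexiconDB, compute_posx  # noqa: F401  (re-exported)

__all__ = [
    "NgramTables",
    "NgramFeatures",
    "NeighborhoodParams",
    "DerivedStats",
    "compute_lemma_freq",
    "compute_form_freq",
    "relative",
    "build_ngram_tables",
    "annotate_ngrams",
    "compute_ambform",
    "compute_amblemma",
    "compute_neighborhood",
    "compute_aggregates",
    "as_table",
    "compute_posx",
    "DEFAULT_AMBIGUITY_THRESHOLD",
    "PER_MILLION",
]

PER_MILLION = 1_000_000

#: a form is "unambiguous" for amblemma iff its ambform is below this
DEFAULT_AMBIGUITY_THRESHOLD = 0.01

#: trigram features are only assigned to forms of at least four letters: for
#: a three-letter word the single trigram would be both the first and the
#: last three letters at once.
MIN_TRIGRAM_FORM_LEN = 4


class UndefinedDatabaseError(ValueError):
    """Relative frequencies are undefined on an empty (zero-token) database."""


def relative(raw: float, total_tokens: int) -> float:
    """Occurrences per one million tokens of the stored corpus."""
    if total_tokens <= 0:
        raise UndefinedDatabaseError("database holds zero tokens")
    return raw * PER_MILLION / total_tokens


@dataclass
class NgramTables:
    """Corpus-wide token-weighted letter N-gram counts.

    Each distinct surface form contributes its form-level total frequency to
    every bigram occurrence within it (multiplicity counted: *aalto* with
    frequency 10 adds 10 to each of aa, al, lt, to) and, when at least three
    letters long, once to the initial- and final-trigram counts.
    """

    bigram: Counter = field(default_factory=Counter)
    initial_trigram: Counter = field(default_factory=Counter)
    final_trigram: Counter = field(default_factory=Counter)
    scaling_base: int = 0


@dataclass(frozen=True)
class NgramFeatures:
    """Per-form N-gram statistics (trigram fields absent below length 4)."""

    bigramfreq: float
    initrigramfreq: Optional[int]
    fintrigramfreq: Optional[int]
    relbigramfreq: float
    relinitrigramfreq: Optional[float]
    relfintrigramfreq: Optional[float]


@dataclass
class NeighborhoodParams:
    """Noise filter for orthographic-neighborhood candidates.

    The defaults (autofreq 10,000, minfreq 100) were tuned on a
    multi-billion-token corpus and are deliberately not rescaled for smaller
    databases.  ``validity_oracle`` replaces the original language-bound
    morphological analyzer; the default accepts every candidate in the band.
    """

    autofreq: int = 10_000
    minfreq: int = 100
    validity_oracle: Callable[[str], bool] = lambda form: True

    def __post_init__(self) -> None:
        if self.minfreq > self.autofreq:
            raise ValueError("minfreq must not exceed autofreq")

    def includes(self, form: str, formfreq: int) -> bool:
        if formfreq >= self.autofreq:
            return True
        if formfreq < self.minfreq:
            return False
        return bool(self.validity_oracle(form))


def compute_lemma_freq(db: LexiconDB) -> Dict[Tuple[str, str], int]:
    """Token count per (lemma, pos), summed over forms and feature strings."""
    out: Dict[Tuple[str, str], int] = defaultdict(int)
    for e in db.entries.values():
        out[(e.lemma, e.pos)] += e.frequency
    return dict(out)


def compute_form_freq(db: LexiconDB) -> Dict[str, int]:
    """Token count per surface form, summed over all readings."""
    out: Dict[str, int] = defaultdict(int)
    for e in db.entries.values():
        out[e.form] += e.frequency
    return dict(out)


def build_ngram_tables(db: LexiconDB) -> NgramTables:
    tables = NgramTables(scaling_base=db.total_tokens)
    for form, freq in compute_form_freq(db).items():
        for i in range(len(form) - 1):
            tables.bigram[form[i : i + 2]] += freq
        if len(form) >= 3:
            tables.initial_trigram[form[:3]] += freq
            tables.final_trigram[form[-3:]] += freq
    return tables


def annotate_ngrams(form: str, tables: NgramTables) -> NgramFeatures:
    """N-gram features for any letter string, word or nonword.

    bigramfreq is the arithmetic mean of the corpus counts of the form's
    ``len - 1`` bigrams; trigram features exist only for length >= 4.
    Relative values are per million tokens of the table's corpus.
    """
    if len(form) < 2:
        raise ValueError(f"form {form!r} shorter than 2 characters")
    bigrams = [form[i : i + 2] for i in range(len(form) - 1)]
    bigramfreq = sum(tables.bigram[b] for b in bigrams) / len(bigrams)
    if len(form) >= MIN_TRIGRAM_FORM_LEN:
        init = tables.initial_trigram[form[:3]]
        fin = tables.final_trigram[form[-3:]]
    else:
        init = fin = None
    rel = lambda x: None if x is None else relative(x, tables.scaling_base)
    return NgramFeatures(
        bigramfreq=bigramfreq,
        initrigramfreq=init,
        fintrigramfreq=fin,
        relbigramfreq=relative(bigramfreq, tables.scaling_base),
        relinitrigramfreq=rel(init),
        relfintrigramfreq=rel(fin),
    )


def compute_ambform(db: LexiconDB) -> Dict[Tuple[str, str, str], float]:
    """Form-ambiguity per (lemma, pos, form) triple.

    Every feature-string row of the same triple carries the same value; a
    form owned by a single (lemma, pos) scores 0, and the scores of a form's
    owners always satisfy sum(1 - ambform) == 1.
    """
    triple_freq: Dict[Tuple[str, str, str], int] = defaultdict(int)
    for e in db.entries.values():
        triple_freq[(e.lemma, e.pos, e.form)] += e.frequency
    form_freq = compute_form_freq(db)
    return {
        (l, p, f): 1.0 - freq / form_freq[f]
        for (l, p, f), freq in triple_freq.items()
    }


def compute_amblemma(
    db: LexiconDB,
    ambform: Mapping[Tuple[str, str, str], float],
    threshold: float = DEFAULT_AMBIGUITY_THRESHOLD,
) -> Dict[Tuple[str, str], float]:
    """Lemma-ambiguity per (lemma, pos): the frequency-weighted share of the
    lemma's tokens realized as an ambiguous form (ambform >= threshold)."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    triple_freq: Dict[Tuple[str, str, str], int] = defaultdict(int)
    for e in db.entries.values():
        triple_freq[(e.lemma, e.pos, e.form)] += e.frequency
    num: Dict[Tuple[str, str], int] = defaultdict(int)
    den: Dict[Tuple[str, str], int] = defaultdict(int)
    for (l, p, f), freq in triple_freq.items():
        den[(l, p)] += freq
        if ambform[(l, p, f)] >= threshold:
            num[(l, p)] += freq
    return {lp: num[lp] / den[lp] for lp in den}


def compute_neighborhood(
    db: LexiconDB,
    params: Optional[NeighborhoodParams] = None,
) -> Dict[str, int]:
    """Orthographic neighborhood size (filtered Coltheart's N) per form.

    Implemented by bucketing forms on single-character wildcard patterns, so
    two forms share a bucket iff they are identical except at one position;
    this is linear in total characters instead of quadratic in forms.
    Counts distinct orthographic forms, not database rows.
    """
    if params is None:
        params = NeighborhoodParams()
    form_freq = compute_form_freq(db)
    included = {f for f, n in form_freq.items() if params.includes(f, n)}
    buckets: Dict[Tuple[int, int, str], list] = defaultdict(list)
    for f in form_freq:
        for i in range(len(f)):
            buckets[(len(f), i, f[:i] + f[i + 1 :])].append(f)
    hood: Dict[str, int] = {f: 0 for f in form_freq}
    for (_, i, _), members in buckets.items():
        for w in members:
            for v in members:
                # same bucket => same length and identical outside position i
                if v is not w and v[i] != w[i] and v in included:
                    hood[w] += 1
    return hood


@dataclass
class DerivedStats:
    """All aggregate statistics of a database, computed post-pruning."""

    lemma_freq: Dict[Tuple[str, str], int]
    form_freq: Dict[str, int]
    ngrams: NgramTables
    ambform: Dict[Tuple[str, str, str], float]
    amblemma: Dict[Tuple[str, str], float]
    hood: Dict[str, int]
    threshold: float
    neighborhood_params: NeighborhoodParams


def compute_aggregates(
    db: LexiconDB,
    neighborhood: Optional[NeighborhoodParams] = None,
    threshold: float = DEFAULT_AMBIGUITY_THRESHOLD,
) -> DerivedStats:
    """Compute and attach every derived statistic to ``db.stats``."""
    ambform = compute_ambform(db)
    stats = DerivedStats(
        lemma_freq=compute_lemma_freq(db),
        form_freq=compute_form_freq(db),
        ngrams=build_ngram_tables(db),
        ambform=ambform,
        amblemma=compute_amblemma(db, ambform, threshold),
        hood=compute_neighborhood(db, neighborhood),
        threshold=threshold,
        neighborhood_params=neighborhood or NeighborhoodParams(),
    )
    db.stats = stats
    return stats


def as_table(db: LexiconDB) -> pd.DataFrame:
    """Render the database and its statistics as one row-per-entry table.

    Computes aggregates first if they are missing.  Raw counts are integers;
    fractional columns are kept at full precision (rounding is an export
    concern).  Trigram features are NA for forms shorter than four letters.
    """
    stats = db.stats if isinstance(db.stats, DerivedStats) else compute_aggregates(db)
    cached = getattr(db, "_table_cache", None)
    if cached is not None and cached[0] is stats:
        return cached[1]
    total = db.total_tokens
    records = []
    ngram_cache: Dict[str, NgramFeatures] = {}
    for e in db.entries.values():
        ng = ngram_cache.get(e.form)
        if ng is None:
            ng = ngram_cache[e.form] = annotate_ngrams(e.form, stats.ngrams)
        lp = (e.lemma, e.pos)
        rec = {
            "lemma": e.lemma,
            "lemmafreq": stats.lemma_freq[lp],
            "rellemmafreq": relative(stats.lemma_freq[lp], total),
            "form": e.form,
            "pos": e.pos,
            "posx": e.posx,
            "frequency": e.frequency,
            "relfrequency": relative(e.frequency, total),
            "len": e.len,
            "feats": e.feats,
        }
        rec.update(e.corefeats.as_dict())
        rec.update(
            bigramfreq=ng.bigramfreq,
            relbigramfreq=ng.relbigramfreq,
            initrigramfreq=ng.initrigramfreq,
            relinitrigramfreq=ng.relinitrigramfreq,
            fintrigramfreq=ng.fintrigramfreq,
            relfintrigramfreq=ng.relfintrigramfreq,
            ambform=stats.ambform[(e.lemma, e.pos, e.form)],
            amblemma=stats.amblemma[lp],
            hood=stats.hood[e.form],
            compound=e.compound,
            proper=e.proper,
        )
        records.append(rec)
    from .export import COLUMNS  # canonical column order

    df = pd.DataFrame.from_records(records, columns=list(COLUMNS))
    db._table_cache = (stats, df)
    return df
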