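"""Deterministic synthetic corpora and built-in worked examples.

Every pipeline stage is testable without downloading a corpus: a
:class:`CorpusSpec` states an exact multiset of (lemma, UPOS, form,
features) readings with multiplicities, :func:`generate_conllu` emits it as
a valid CoNLL-U stream (token order shuffled by seed — aggregation is order
invariant, so the seed never changes any statistic), and
:func:`db_from_spec` builds the equivalent database directly, which is the
practical route for fixtures with multi-million multiplicities.

The built-in fixtures are published worked examples for Finnish:

* ``table1_silmasi`` — the three analyses of *silmäsi* ('your eye(s)'),
  a noun form that is simultaneously plural nominative, singular genitive
  and singular nominative;
* ``table3_voi``   — five readings of the form *voi*: verb *voida* ('to be
  able to'), interjection ('oh'), and noun ('butter');
* ``table4_voi_forms`` — the six most frequent forms of the noun *voi*;
* ``table5_voit``  — ten lemma/word-class readings of the form *voit*,
  illustrating parser noise.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

from .db import LexiconDB
from .conllu import TokenAnalysis
from .features import project_core_features

__all__ = [
    "CorpusSpec",
    "SpecRow",
    "generate_conllu",
    "db_from_spec",
    "builtin_fixture",
    "random_corpus_spec",
    "FIXTURE_NAMES",
]

SpecRow = Tuple[str, str, str, Dict[str, str], int]  # lemma, upos, form, feats, multiplicity


@dataclass
class CorpusSpec:
    """An exact multiset of token readings to emit as a corpus."""

    rows: List[SpecRow] = field(default_factory=list)
    sentence_length: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for row in self.rows:
            if row[4] < 1:
                raise ValueError(f"multiplicity must be >= 1: {row}")

    @property
    def total_tokens(self) -> int:
        return sum(r[4] for r in self.rows)


def _feats_str(feats: Dict[str, str]) -> str:
    if not feats:
        return "_"
    return "|".join(f"{k}={v}" for k, v in sorted(feats.items(), key=lambda kv: kv[0].lower()))


def generate_conllu(spec: CorpusSpec) -> str:
    """Emit the spec as CoNLL-U text; each row appears exactly its
    multiplicity times, in an order shuffled by the spec's seed."""
    tokens = []
    for lemma, upos, form, feats, mult in spec.rows:
        tokens.extend([(lemma, upos, form, feats)] * mult)
    random.Random(spec.seed).shuffle(tokens)

    lines = []
    for start in range(0, len(tokens), spec.sentence_length):
        sentence = tokens[start : start + spec.sentence_length]
        lines.append(f"# sent_id = {start // spec.sentence_length + 1}")
        for i, (lemma, upos, form, feats) in enumerate(sentence, start=1):
            head, deprel = ("0", "root") if i == 1 else ("1", "dep")
            lines.append(
                "\t".join(
                    [str(i), form, lemma, upos, "_", _feats_str(feats), head, deprel, "_", "_"]
                )
            )
        lines.append("")
    return "\n".join(lines) + ("\n" if lines else "")


def db_from_spec(spec: CorpusSpec, language: str = "fi") -> LexiconDB:
    """Aggregate the spec directly, bypassing text generation.

    Identical in outcome to ``aggregate(read_conllu(generate_conllu(spec)))``
    (the same lowercasing, compound handling, token filter and feature
    projection are applied per reading), but O(rows) instead of O(tokens).
    """
    db = LexiconDB(language=language)
    for lemma, upos, form, feats, mult in spec.rows:
        tok = TokenAnalysis(form.lower(), lemma.lower(), upos, feats)
        before = db.total_tokens
        db.ingest([tok])
        if db.total_tokens > before and mult > 1:  # accepted: add the rest
            entry = db.entries[
                (tok.lemma.replace("#", ""), upos, tok.form,
                 project_core_features(feats).serialize())
            ]
            entry.frequency += mult - 1
            db.total_tokens += mult - 1
    return db


_TABLE1 = [
    ("silmä", "NOUN", "silmäsi", {"Case": "Nom", "Number": "Plur"}, 13464),
    ("silmä", "NOUN", "silmäsi", {"Case": "Gen", "Number": "Sing"}, 4600),
    ("silmä", "NOUN", "silmäsi", {"Case": "Nom", "Number": "Sing"}, 1307),
]

_TABLE3 = [
    ("voida", "VERB", "voi",
     {"Number": "Sing", "Person": "3", "Tense": "Pres", "VerbForm": "Fin"}, 7_810_951),
    ("voida", "VERB", "voi",
     {"Number": "Sing", "Person": "0", "Tense": "Pres", "VerbForm": "Fin"}, 4_196_751),
    ("voida", "VERB", "voi", {"Tense": "Pres", "VerbForm": "Fin"}, 3_655_767),
    ("voi", "INTJ", "voi", {}, 750_292),
    ("voi", "NOUN", "voi", {"Case": "Nom", "Number": "Sing"}, 52_296),
]

_TABLE4 = [
    ("voi", "NOUN", "voita", {"Case": "Par", "Number": "Sing"}, 64_719),
    ("voi", "NOUN", "voi", {"Case": "Nom", "Number": "Sing"}, 52_296),
    ("voi", "NOUN", "voin", {"Case": "Gen", "Number": "Sing"}, 17_869),
    ("voi", "NOUN", "voissa", {"Case": "Ine", "Number": "Sing"}, 13_453),
    ("voi", "NOUN", "voilla", {"Case": "Ade", "Number": "Sing"}, 5_347),
    ("voi", "NOUN", "voista", {"Case": "Ela", "Number": "Sing"}, 3_241),
]

_TABLE5 = [
    ("voida", "VERB", "voit", {}, 3_075_975),
    ("voida", "NOUN", "voit", {}, 7_425),
    ("voit", "NOUN", "voit", {}, 4_288),
    ("voi", "NOUN", "voit", {}, 2_700),
    ("voida", "PRON", "voit", {}, 1_711),
    ("voit", "PROPN", "voit", {}, 1_218),
    ("voida", "ADV", "voit", {}, 1_045),
    ("voit", "VERB", "voit", {}, 986),
    ("voit", "ADV", "voit", {}, 786),
    ("voida", "ADJ", "voit", {}, 623),
]

_BUILTIN = {
    "table1_silmasi": _TABLE1,
    "table3_voi": _TABLE3,
    "table4_voi_forms": _TABLE4,
    "table5_voit": _TABLE5,
}

FIXTURE_NAMES = tuple(_BUILTIN)


def builtin_fixture(name: str, seed: int = 0) -> CorpusSpec:
    """A built-in worked-example fixture by name (see module docstring)."""
    try:
        rows = _BUILTIN[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; choose from {', '.join(_BUILTIN)}"
        ) from None
    return CorpusSpec(rows=[tuple(r) for r in rows], seed=seed)


_POS_POOL = ("NOUN", "VERB", "AUX", "ADJ", "ADV", "PROPN", "NUM", "INTJ")
_CASES = ("Nom", "Gen", "Par", "Ine", "Ela", "Ade", "Ess")
_ALPHABET = "aehiklmnoprstuvyäö"


def random_corpus_spec(
    seed: int,
    n_rows: int = 100,
    max_multiplicity: int = 50,
    max_form_len: int = 8,
) -> CorpusSpec:
    """A randomized spec for property tests: plausible Finnish-looking
    strings, small feature inventory, overlapping forms across lemmas."""
    rng = random.Random(seed)

    def word(lo=2, hi=max_form_len):
        return "".join(rng.choice(_ALPHABET) for _ in range(rng.randint(lo, hi)))

    seen = set()
    rows: List[SpecRow] = []
    lemmas = [word(2, 6) for _ in range(max(3, n_rows // 4))]
    forms = [word(2, max_form_len) for _ in range(max(4, n_rows // 2))]
    while len(rows) < n_rows:
        lemma = rng.choice(lemmas)
        pos = rng.choice(_POS_POOL)
        form = rng.choice(forms)
        feats: Dict[str, str] = {}
        if rng.random() < 0.7:
            feats["Case"] = rng.choice(_CASES)
            feats["Number"] = rng.choice(("Sing", "Plur"))
        if rng.random() < 0.2:
            feats["Person[psor]"] = rng.choice(("1", "2", "3"))
        if rng.random() < 0.1:
            feats["Degree"] = "Pos"  # projected away: exercises feature merging
        key = (lemma, pos, form, project_core_features(feats).serialize())
        if key in seen:
            continue
        seen.add(key)
        rows.append((lemma, pos, form, feats, rng.randint(1, max_multiplicity)))
    return CorpusSpec(rows=rows, seed=seed)
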