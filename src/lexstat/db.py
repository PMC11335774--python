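"""The lexicon database: token filtering, frequency aggregation, merging,
pruning, and SQLite persistence.

A database is a collection of rows uniquely keyed by the quadruple
(lemma, word class, surface form, core-feature string): there is exactly one
row per quadruple, carrying the token count observed for that exact reading.
Noise tokens from web-crawled corpora (punctuation runs, digit strings,
kilo-character HTML artifacts) are rejected before aggregation by
:func:`accept_token`; word-class-level noise (PUNCT/SYM/X rows) and
low-frequency rows are removed afterwards by :meth:`LexiconDB.prune`.
All derived statistics must be (re)computed after pruning so that relative
values reflect the data actually stored.
"""

from __future__ import annotations

import json
import re
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Optional, Tuple, Union

from .conllu import TokenAnalysis
from .features import CoreFeatures, project_core_features

__all__ = [
    "LexEntry",
    "LexiconDB",
    "ConfigError",
    "accept_token",
    "aggregate",
    "merge",
    "prune",
    "compute_posx",
    "FINNISH_CHARSET",
    "DEFAULT_EXCLUDED_POS",
    "DEFAULT_COMPOUND_SEPARATOR",
]

#: characters allowed in a Finnish token: letters of the language, digits,
#: internal hyphen and apostrophe.  This is a configuration value per
#: language, expressed as a regex character class body.
FINNISH_CHARSET = r"a-zåäöšž0-9\-'"

#: word classes removed at prune time: punctuation, symbols, and tokens for
#: which no valid word class was found.
DEFAULT_EXCLUDED_POS = frozenset({"PUNCT", "SYM", "X"})

#: Finnish UD marks compound boundaries in the lemma with '#'
DEFAULT_COMPOUND_SEPARATOR = "#"

EntryKey = Tuple[str, str, str, str]  # (lemma, pos, form, feats serialization)


class ConfigError(ValueError):
    """Incompatible databases or invalid configuration."""


def compute_posx(pos: str) -> str:
    """Query-facing word class: auxiliaries fold into VERB, all else identity.

    Certain verbs occur both as main verbs (VERB) and auxiliaries (AUX); a
    user asking for "verbs" almost always wants both, so queries on the word
    class run against this column unless AUX is named explicitly.
    """
    return "VERB" if pos == "AUX" else pos


@dataclass
class LexEntry:
    """One database row: a unique (lemma, pos, form, features) reading."""

    lemma: str
    pos: str
    form: str
    corefeats: CoreFeatures
    frequency: int = 0
    compound: bool = False
    proper: bool = False

    @property
    def posx(self) -> str:
        return compute_posx(self.pos)

    @property
    def len(self) -> int:
        return len(self.form)

    @property
    def feats(self) -> str:
        return self.corefeats.serialize()

    @property
    def key(self) -> EntryKey:
        return (self.lemma, self.pos, self.form, self.feats)


_charset_cache: dict[str, re.Pattern] = {}


def _charset_re(charset: str) -> re.Pattern:
    try:
        return _charset_cache[charset]
    except KeyError:
        pat = re.compile(f"^[{charset}]+$")
        _charset_cache[charset] = pat
        return pat


def _valid_string(s: str, charset: str) -> bool:
    return (
        bool(s)
        and _charset_re(charset).match(s) is not None
        and s[0].isalnum()
        and any(c.isalpha() for c in s)
    )


def accept_token(t: TokenAnalysis, charset_pattern: str = FINNISH_CHARSET) -> bool:
    """Pre-filter applied to every token before aggregation.

    The form must consist only of characters in the language charset, begin
    with an alphanumeric character, contain at least one actual letter, and
    be 2-100 characters long (no one-character Finnish words exist; longer
    strings are crawler artifacts).  The lemma must pass the same
    character-level checks; both must pass for the token to count.
    """
    form = t.form
    if not (2 <= len(form) <= 100):
        return False
    return _valid_string(form, charset_pattern) and _valid_string(t.lemma, charset_pattern)


@dataclass
class LexiconDB:
    """In-memory lexicon keyed by (lemma, pos, form, feats)."""

    entries: Dict[EntryKey, LexEntry] = field(default_factory=dict)
    total_tokens: int = 0
    language: str = "fi"
    applied_minfreq: int = 0
    metadata: dict = field(default_factory=dict)
    #: derived statistics (set by lexstat.stats.compute_aggregates)
    stats: Optional[object] = None

    def __len__(self) -> int:
        return len(self.entries)

    # -- building ---------------------------------------------------------

    def add(
        self,
        lemma: str,
        pos: str,
        form: str,
        corefeats: CoreFeatures,
        count: int = 1,
        *,
        compound: bool = False,
    ) -> LexEntry:
        """UPSERT one reading: create the row or add ``count`` to it."""
        key = (lemma, pos, form, corefeats.serialize())
        entry = self.entries.get(key)
        if entry is None:
            entry = LexEntry(
                lemma=lemma,
                pos=pos,
                form=form,
                corefeats=corefeats,
                compound=compound,
                proper=pos == "PROPN",
            )
            self.entries[key] = entry
        entry.frequency += count
        self.total_tokens += count
        self.stats = None
        return entry

    def ingest(
        self,
        tokens: Iterable[TokenAnalysis],
        charset_pattern: str = FINNISH_CHARSET,
        compound_separator: str = DEFAULT_COMPOUND_SEPARATOR,
    ) -> int:
        """Aggregate a token stream into this database.

        Returns the number of accepted tokens.  The compound flag is set when
        the lemma contains the separator character; the separator is then
        stripped so stored lemmas are plain orthographic strings.
        """
        accepted = 0
        for tok in tokens:
            lemma = tok.lemma
            compound = compound_separator in lemma
            if compound:
                lemma = lemma.replace(compound_separator, "")
                tok = TokenAnalysis(tok.form, lemma, tok.upos, tok.feats)
            if not accept_token(tok, charset_pattern):
                continue
            self.add(
                lemma,
                tok.upos,
                tok.form,
                project_core_features(tok.feats),
                compound=compound,
            )
            accepted += 1
        return accepted

    # -- persistence -------------------------------------------------------

    def save(self, path: Union[str, Path]) -> None:
        """Persist to a single-file SQLite store (lossless round trip)."""
        path = Path(path)
        if path.exists():
            path.unlink()
        con = sqlite3.connect(path)
        try:
            con.execute(
                "CREATE TABLE entries ("
                "lemma TEXT, pos TEXT, form TEXT, feats TEXT, "
                "frequency INTEGER, compound INTEGER, proper INTEGER, "
                "PRIMARY KEY (lemma, pos, form, feats))"
            )
            con.execute("CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT)")
            con.executemany(
                "INSERT INTO entries VALUES (?,?,?,?,?,?,?)",
                (
                    (e.lemma, e.pos, e.form, e.feats, e.frequency,
                     int(e.compound), int(e.proper))
                    for e in self.entries.values()
                ),
            )
            meta = {
                "language": self.language,
                "total_tokens": str(self.total_tokens),
                "applied_minfreq": str(self.applied_minfreq),
                "metadata": json.dumps(self.metadata),
            }
            con.executemany("INSERT INTO meta VALUES (?,?)", meta.items())
            con.commit()
        finally:
            con.close()

    @classmethod
    def load(cls, path: Union[str, Path]) -> "LexiconDB":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"no database at {path}")
        con = sqlite3.connect(path)
        try:
            meta = dict(con.execute("SELECT key, value FROM meta"))
            db = cls(
                language=meta.get("language", "fi"),
                applied_minfreq=int(meta.get("applied_minfreq", 0)),
                metadata=json.loads(meta.get("metadata", "{}")),
            )
            for lemma, pos, form, feats, freq, compound, proper in con.execute(
                "SELECT lemma, pos, form, feats, frequency, compound, proper FROM entries"
            ):
                entry = LexEntry(
                    lemma=lemma,
                    pos=pos,
                    form=form,
                    corefeats=_deserialize_feats(feats),
                    frequency=freq,
                    compound=bool(compound),
                    proper=bool(proper),
                )
                db.entries[entry.key] = entry
            db.total_tokens = int(meta.get("total_tokens", 0))
        finally:
            con.close()
        return db

    # -- transforms --------------------------------------------------------

    def merge(self, other: "LexiconDB") -> "LexiconDB":
        """Combine two partial databases: shared keys sum their frequencies."""
        if self.language != other.language:
            raise ConfigError(
                f"cannot merge databases for languages "
                f"{self.language!r} and {other.language!r}"
            )
        out = LexiconDB(language=self.language, metadata=dict(self.metadata))
        for src in (self, other):
            for e in src.entries.values():
                out.add(e.lemma, e.pos, e.form, e.corefeats, e.frequency,
                        compound=e.compound)
        return out

    def prune(
        self,
        minfreq: int = 0,
        excluded_pos: Iterable[str] = DEFAULT_EXCLUDED_POS,
    ) -> "LexiconDB":
        """Drop rows below ``minfreq`` or with an excluded word class.

        Returns a new database with total_tokens recomputed over the
        survivors and the applied minimum frequency recorded; any derived
        statistics must be recomputed on the result.
        """
        if minfreq < 0:
            raise ConfigError("minfreq must be >= 0")
        excluded = frozenset(excluded_pos)
        out = LexiconDB(
            language=self.language,
            applied_minfreq=max(minfreq, self.applied_minfreq),
            metadata=dict(self.metadata),
        )
        for e in self.entries.values():
            if e.frequency >= minfreq and e.pos not in excluded:
                out.add(e.lemma, e.pos, e.form, e.corefeats, e.frequency,
                        compound=e.compound)
        return out


def _deserialize_feats(feats: str) -> CoreFeatures:
    if feats == "_" or not feats:
        return CoreFeatures()
    mapping = dict(pair.split("=", 1) for pair in feats.split("|"))
    return project_core_features(mapping)


# module-level functional aliases matching the pipeline vocabulary

def aggregate(
    tokens: Iterable[TokenAnalysis],
    charset_pattern: str = FINNISH_CHARSET,
    language: str = "fi",
) -> LexiconDB:
    """Build a fresh database from a token stream (see LexiconDB.ingest)."""
    db = LexiconDB(language=language)
    db.ingest(tokens, charset_pattern)
    return db


def merge(a: LexiconDB, b: LexiconDB) -> LexiconDB:
    return a.merge(b)


def prune(
    db: LexiconDB,
    minfreq: int = 0,
    excluded_pos: Iterable[str] = DEFAULT_EXCLUDED_POS,
) -> LexiconDB:
    return db.prune(minfreq, excluded_pos)
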