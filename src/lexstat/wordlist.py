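"""Wordlist mode: fetch database rows for ready-made word or lemma lists,
and annotate nonwords with N-gram statistics.

Stimulus builders often arrive with a candidate list rather than a free
search: a list of surface forms (or lemmas) to pull norms for, or a list of
pseudowords needing matched bigram/trigram statistics for a lexical-decision
task.  Inputs with no database row are reported explicitly as misses so that
candidates lacking norms are visible.  The returned rows are an ordinary
result table, so they remain filterable with the same query language as the
free search mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, List, Optional, Tuple, Union

import pandas as pd

from .db import LexiconDB
from .stats import NgramFeatures, NgramTables, annotate_ngrams, as_table

__all__ = ["WordlistResult", "load_wordlist", "lookup", "annotate_nonwords"]


@dataclass
class WordlistResult:
    """Rows matched by a wordlist plus the inputs that matched nothing."""

    rows: pd.DataFrame
    misses: List[str] = field(default_factory=list)
    mode: str = "form"


def load_wordlist(stream: Union[IO[str], str, Iterable[str]]) -> List[str]:
    """One token per line; trimmed, lowercased, blank lines dropped,
    order and duplicates preserved."""
    if isinstance(stream, str):
        stream = stream.splitlines()
    out = []
    for line in stream:
        word = line.strip().lower()
        if word:
            out.append(word)
    return out


def lookup(db: LexiconDB, words: List[str], mode: str = "form") -> WordlistResult:
    """All rows whose form (or lemma, per ``mode``) occurs in the list."""
    if mode not in ("form", "lemma"):
        raise ValueError(f"mode must be 'form' or 'lemma', not {mode!r}")
    table = as_table(db)
    wanted = set(words)
    rows = table[table[mode].isin(wanted)]
    rows = rows.sort_values(
        ["frequency", "form"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    found = set(rows[mode])
    misses = [w for w in dict.fromkeys(words) if w not in found]
    return WordlistResult(rows=rows, misses=misses, mode=mode)


def annotate_nonwords(
    strings: List[str], tables: NgramTables
) -> List[Tuple[str, Optional[NgramFeatures], Optional[str]]]:
    """N-gram features for arbitrary letter strings (nonwords included).

    Returns one ``(string, features, error)`` triple per input; a string
    shorter than two characters yields an error message for that item while
    the rest are still processed.  A string that does exist in the database
    gets exactly the stored forms' N-gram math — same tables, same formula.
    """
    out = []
    for s in strings:
        try:
            out.append((s, annotate_ngrams(s, tables), None))
        except ValueError as exc:
            out.append((s, None, str(exc)))
    return out
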