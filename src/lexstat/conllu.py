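"""Reading token streams from CoNLL-U files.

Only the FORM, LEMMA, UPOS and FEATS columns are consumed; syntactic columns
(HEAD, DEPREL, DEPS) are irrelevant to frequency aggregation and are not
validated beyond the 10-column row shape.  Multiword-token range rows
(ID ``4-5``) and empty-node rows (ID ``5.1``) are skipped so that counts are
per running syntactic word.  Forms and lemmas are lowercased on read: the
database stores case-insensitive ("pure") frequencies.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, TextIO, Union

__all__ = ["TokenAnalysis", "ConlluParseError", "read_conllu"]

#: UPOS placeholder for a missing tag
MISSING_UPOS = "_"


class ConlluParseError(ValueError):
    """A malformed CoNLL-U row; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class TokenAnalysis:
    """One parsed syntactic word: surface form, lemma, UPOS and features."""

    form: str
    lemma: str
    upos: str = MISSING_UPOS
    feats: Mapping[str, str] = field(default_factory=dict)


def _parse_feats(col: str) -> dict[str, str]:
    if col in ("_", ""):
        return {}
    out = {}
    for pair in col.split("|"):
        key, _, value = pair.partition("=")
        if key:
            out[key] = value
    return out


def read_conllu(stream: Union[TextIO, str, Iterable[str]]) -> Iterator[TokenAnalysis]:
    """Yield one :class:`TokenAnalysis` per syntactic-word row.

    ``stream`` may be an open text file, a string of CoNLL-U text, or any
    iterable of lines.  Comment lines (``#``) and blank sentence separators
    are ignored; range and empty-node rows are skipped.

    Raises
    ------
    ConlluParseError
        on a row that is neither a comment, blank, nor 10 tab-separated
        columns, identifying the offending line number.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n").rstrip("\r")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 10:
            raise ConlluParseError(
                f"expected 10 tab-separated columns, got {len(cols)}", lineno
            )
        tok_id = cols[0]
        if "-" in tok_id or "." in tok_id:  # range row / empty node
            continue
        form = cols[1].lower()
        lemma = cols[2].lower()
        upos = cols[3] if cols[3] else MISSING_UPOS
        yield TokenAnalysis(form=form, lemma=lemma, upos=upos, feats=_parse_feats(cols[5]))
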