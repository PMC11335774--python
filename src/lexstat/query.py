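"""The AND-conjunctive query mini-language.

Queries are conjunctions of ``key operator value`` parts joined by the word
``and``::

    pos in noun,num and end in sta,na,a and case = nom and len> 5 and len< 9

All input is lowercased before evaluation, so ``case = Ine`` and
``case = ine`` are equivalent.  Operators are ``=``, ``!=``, ``<``, ``>``,
``in`` / ``not in`` (set membership, the only disjunction the language
offers), and bare / ``not``-prefixed flags (``compound``, ``proper``).
There is no OR and no grouping: a query such as ``len< 10 OR len> 20`` is
unsupported by design.

Semantics that matter for stimulus selection:

* rows lacking a morphological feature fail positive predicates on it and
  satisfy negative ones (``posspers not in 1,2,3`` keeps words with no
  possessive suffix at all);
* word-class predicates run against the merged class column posx (so
  ``pos = verb`` matches auxiliaries) except when any value names ``aux``
  explicitly, in which case the original class is used;
* ``start`` / ``end`` / ``mid`` match the form by prefix / suffix /
  substring.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd

from .db import LexiconDB
from .features import FEATURE_QUERY_KEYS
from .stats import as_table

__all__ = [
    "QueryError",
    "EmptyQueryError",
    "UnknownKeyError",
    "QuerySyntaxError",
    "UnsupportedOperatorError",
    "KeySpec",
    "QueryPredicate",
    "Query",
    "DEFAULT_REGISTRY",
    "DEFAULT_MAX_ROWS",
    "tokenize",
    "parse",
    "evaluate",
    "evaluate_table",
    "brute_force_oracle",
]

DEFAULT_MAX_ROWS = 10_000


class QueryError(ValueError):
    pass


class EmptyQueryError(QueryError):
    pass


class UnknownKeyError(QueryError):
    def __init__(self, key: str):
        super().__init__(f"unknown query key: {key!r}")
        self.key = key


class QuerySyntaxError(QueryError):
    def __init__(self, part: str, reason: str = "cannot parse"):
        super().__init__(f"{reason}: {part!r}")
        self.part = part


class UnsupportedOperatorError(QueryError):
    pass


@dataclass(frozen=True)
class KeySpec:
    """How one query key maps onto the result table."""

    kind: str  # text | match | numeric | feature | flag | pos
    column: str
    style: str = "exact"  # exact | prefix | suffix | substring


def _registry() -> Dict[str, KeySpec]:
    reg: Dict[str, KeySpec] = {
        "form": KeySpec("text", "form"),
        "lemma": KeySpec("text", "lemma"),
        "start": KeySpec("match", "form", "prefix"),
        "end": KeySpec("match", "form", "suffix"),
        "mid": KeySpec("match", "form", "substring"),
        "pos": KeySpec("pos", "posx"),
        "compound": KeySpec("flag", "compound"),
        "proper": KeySpec("flag", "proper"),
    }
    for key in (
        "len",
        "frequency",
        "relfrequency",
        "lemmafreq",
        "rellemmafreq",
        "bigramfreq",
        "relbigramfreq",
        "initrigramfreq",
        "relinitrigramfreq",
        "fintrigramfreq",
        "relfintrigramfreq",
        "ambform",
        "amblemma",
        "hood",
    ):
        reg[key] = KeySpec("numeric", key)
    for key in FEATURE_QUERY_KEYS:
        reg[key] = KeySpec("feature", key)
    return reg


#: the canonical key set, table-driven so it can be extended per language
DEFAULT_REGISTRY: Dict[str, KeySpec] = _registry()


@dataclass(frozen=True)
class QueryPredicate:
    key: str
    op: str  # eq | neq | lt | gt | in | not_in | flag | not_flag
    values: tuple = ()


@dataclass
class Query:
    """A conjunction of predicates; evaluation order is irrelevant."""

    predicates: List[QueryPredicate] = field(default_factory=list)
    text: str = ""


_AND_SPLIT = re.compile(r"\s+and\s+")
_OR_WORD = re.compile(r"(?:^|\s)or(?:\s|$)")
_CMP_PART = re.compile(r"^([a-z][a-z0-9]*)\s*(!=|=|<|>)\s*(.*)$")
_IN_PART = re.compile(r"^([a-z][a-z0-9]*)\s+(not\s+in|in)\s+(.*)$")


def tokenize(query_text: str) -> List[str]:
    """Lowercase the query and split it into parts on the word ``and``.

    Operator symbols may abut their key or value (``len> 5`` is valid, as is
    ``len>5``); the split itself only cares about the standalone ``and``.
    """
    text = query_text.lower().strip()
    if not text:
        raise EmptyQueryError("empty query")
    parts = [p.strip() for p in _AND_SPLIT.split(text)]
    if any(not p for p in parts):
        raise QuerySyntaxError(query_text, "empty query part")
    return parts


def _parse_values(raw: str, part: str) -> List[str]:
    values = [v.strip() for v in raw.split(",")]
    if any(not v for v in values):
        raise QuerySyntaxError(part, "empty value")
    return values


def _coerce_numeric(values: Sequence[str], part: str) -> tuple:
    out = []
    for v in values:
        try:
            out.append(float(v))
        except ValueError:
            raise QuerySyntaxError(part, f"expected a number, got {v!r}") from None
    return tuple(out)


def parse(query_text: str, registry: Optional[Dict[str, KeySpec]] = None) -> Query:
    """Compile query text into a :class:`Query` of typed predicates."""
    registry = registry if registry is not None else DEFAULT_REGISTRY
    predicates = []
    for part in tokenize(query_text):
        if _OR_WORD.search(part):
            raise UnsupportedOperatorError(
                "OR is not supported; use 'key in v1,v2' for set membership"
            )
        predicates.append(_parse_part(part, registry))
    return Query(predicates=predicates, text=query_text)


def _parse_part(part: str, registry: Dict[str, KeySpec]) -> QueryPredicate:
    # bare / negated flags: "compound", "not compound"
    flag_key = part[4:].strip() if part.startswith("not ") else part
    spec = registry.get(flag_key)
    if spec is not None and spec.kind == "flag":
        return QueryPredicate(flag_key, "not_flag" if part.startswith("not ") else "flag")

    m = _IN_PART.match(part)
    if m:
        key, op_word, raw = m.groups()
        op = "not_in" if op_word.startswith("not") else "in"
        values = _parse_values(raw, part)
    else:
        m = _CMP_PART.match(part)
        if not m:
            raise QuerySyntaxError(part)
        key, sym, raw = m.groups()
        if not raw.strip():
            raise QuerySyntaxError(part, "missing value")
        op = {"=": "eq", "!=": "neq", "<": "lt", ">": "gt"}[sym]
        values = [raw.strip()]

    spec = registry.get(key)
    if spec is None:
        raise UnknownKeyError(key)
    if spec.kind == "flag":
        raise QuerySyntaxError(part, f"{key!r} is a flag, use it bare or with 'not'")
    if spec.kind == "numeric":
        values = _coerce_numeric(values, part)
    elif op in ("lt", "gt"):
        raise QuerySyntaxError(part, f"{key!r} does not support < or >")
    return QueryPredicate(key, op, tuple(values))


# --------------------------------------------------------------------------
# vectorized evaluation

def _match_series(base: pd.Series, value: str, style: str) -> pd.Series:
    if style == "prefix":
        return base.str.startswith(value)
    if style == "suffix":
        return base.str.endswith(value)
    return base.str.contains(value, regex=False)


def _predicate_mask(
    table: pd.DataFrame, pred: QueryPredicate, registry: Dict[str, KeySpec]
) -> pd.Series:
    spec = registry[pred.key]
    if spec.kind == "flag":
        col = table[spec.column].astype(bool)
        return col if pred.op == "flag" else ~col

    if spec.kind == "numeric":
        s = table[spec.column]
        v = pred.values
        if pred.op == "eq":
            return s == v[0]
        if pred.op == "neq":
            return ~(s == v[0])
        if pred.op == "lt":
            return s < v[0]
        if pred.op == "gt":
            return s > v[0]
        if pred.op == "in":
            return s.isin(v)
        return ~s.isin(v)  # not_in

    if spec.kind == "match":
        masks = [_match_series(table[spec.column], v, spec.style) for v in pred.values]
        any_match = masks[0]
        for m in masks[1:]:
            any_match = any_match | m
        return any_match if pred.op in ("eq", "in") else ~any_match

    if spec.kind == "pos":
        column = "pos" if "aux" in pred.values else spec.column
        s = table[column].str.lower()
    else:  # text or feature; features are stored TitleCased, forms lowercased
        s = table[spec.column]
        if spec.kind == "feature":
            s = s.str.lower()

    if pred.op == "eq":
        return s == pred.values[0]
    if pred.op == "neq":
        return ~(s == pred.values[0])
    if pred.op == "in":
        return s.isin(pred.values)
    if pred.op == "not_in":
        return ~s.isin(pred.values)
    raise QuerySyntaxError(pred.key, f"operator {pred.op!r} invalid here")


def evaluate_table(
    table: pd.DataFrame,
    q: Query,
    max_rows: int = DEFAULT_MAX_ROWS,
    registry: Optional[Dict[str, KeySpec]] = None,
) -> pd.DataFrame:
    """Run a compiled query against a result table (any row source)."""
    registry = registry if registry is not None else DEFAULT_REGISTRY
    mask = pd.Series(True, index=table.index)
    for pred in q.predicates:
        mask &= _predicate_mask(table, pred, registry)
    result = table[mask]
    result = result.sort_values(
        ["frequency", "form"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return result.head(max_rows)


def evaluate(
    db: LexiconDB,
    q: Union[Query, str],
    max_rows: int = DEFAULT_MAX_ROWS,
    registry: Optional[Dict[str, KeySpec]] = None,
) -> pd.DataFrame:
    """Run a query (text or compiled) against a database."""
    if isinstance(q, str):
        q = parse(q, registry)
    return evaluate_table(as_table(db), q, max_rows, registry)


# --------------------------------------------------------------------------
# independent row-by-row oracle (used to cross-check the vectorized path)

def _row_matches(row: dict, pred: QueryPredicate, registry: Dict[str, KeySpec]) -> bool:
    spec = registry[pred.key]
    if spec.kind == "flag":
        return bool(row[spec.column]) == (pred.op == "flag")
    if spec.kind == "numeric":
        x = row[spec.column]
        missing = x is None or (isinstance(x, float) and x != x)
        if pred.op == "neq":
            return missing or x != pred.values[0]
        if pred.op == "not_in":
            return missing or x not in pred.values
        if missing:
            return False
        return {
            "eq": x == pred.values[0],
            "lt": x < pred.values[0],
            "gt": x > pred.values[0],
            "in": x in pred.values,
        }[pred.op]
    if spec.kind == "match":
        form = row[spec.column]
        fns = {
            "prefix": form.startswith,
            "suffix": form.endswith,
            "substring": form.__contains__,
        }
        hit = any(fns[spec.style](v) for v in pred.values)
        return hit if pred.op in ("eq", "in") else not hit
    if spec.kind == "pos":
        column = "pos" if "aux" in pred.values else spec.column
        x = row[column].lower()
    else:
        x = row[spec.column]
        if spec.kind == "feature":
            x = None if x is None else x.lower()
    if pred.op == "eq":
        return x is not None and x == pred.values[0]
    if pred.op == "neq":
        return x is None or x != pred.values[0]
    if pred.op == "in":
        return x is not None and x in pred.values
    return x is None or x not in pred.values  # not_in


def brute_force_oracle(
    db: LexiconDB,
    q: Union[Query, str],
    table: Optional[pd.DataFrame] = None,
) -> List[dict]:
    """Evaluate by direct row-by-row inspection; no vectorization, no
    truncation, no ordering guarantees.  Must equal :func:`evaluate` as a
    set on any database it is feasible to run on.  ``table`` may supply a
    precomputed row source to avoid rebuilding it per query."""
    if isinstance(q, str):
        q = parse(q)
    rows = (as_table(db) if table is None else table).to_dict("records")
    out = []
    for row in rows:
        row = {
            k: (None if isinstance(v, float) and v != v else v) for k, v in row.items()
        }
        if all(_row_matches(row, pred, DEFAULT_REGISTRY) for pred in q.predicates):
            out.append(row)
    return out
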