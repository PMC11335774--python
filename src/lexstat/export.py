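"""Delimited export of result tables.

Column names follow the query-language key names (frequency, relfrequency,
lemmafreq, ambform, amblemma, feats, ...) so exported files are directly
comparable with published norm tables.  Fractional columns (relative
frequencies and ambiguity scores) are rounded to a configurable precision
at export time only; raw counts are written as integers.
"""

from __future__ import annotations

import csv
from typing import IO, Iterable, Mapping, Union

import pandas as pd

__all__ = ["COLUMNS", "INT_COLUMNS", "FLOAT_COLUMNS", "export_rows", "render_cell"]

#: canonical column order: lemmas, forms, frequencies, features
COLUMNS = (
    "lemma",
    "lemmafreq",
    "rellemmafreq",
    "form",
    "pos",
    "posx",
    "frequency",
    "relfrequency",
    "len",
    "feats",
    "case",
    "number",
    "person",
    "verbform",
    "mood",
    "tense",
    "voice",
    "clitic",
    "derivation",
    "posspers",
    "possnum",
    "bigramfreq",
    "relbigramfreq",
    "initrigramfreq",
    "relinitrigramfreq",
    "fintrigramfreq",
    "relfintrigramfreq",
    "ambform",
    "amblemma",
    "hood",
    "compound",
    "proper",
)

INT_COLUMNS = frozenset(
    {"lemmafreq", "frequency", "len", "initrigramfreq", "fintrigramfreq", "hood"}
)
FLOAT_COLUMNS = frozenset(
    {
        "rellemmafreq",
        "relfrequency",
        "bigramfreq",
        "relbigramfreq",
        "relinitrigramfreq",
        "relfintrigramfreq",
        "ambform",
        "amblemma",
    }
)

_DELIMITERS = {"csv": ",", "tsv": "\t"}


def render_cell(column: str, value, precision: int = 3) -> str:
    """One table cell as text: ints as ints, floats at fixed precision,
    missing values (trigram features of short forms) as empty cells."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    if column in INT_COLUMNS:
        return str(int(value))
    if column in FLOAT_COLUMNS:
        return f"{value:.{precision}f}"
    if isinstance(value, bool):
        return "1" if value else "0"
    return str(value)


def export_rows(
    rows: Union[pd.DataFrame, Iterable[Mapping]],
    fmt: str,
    sink: IO[str],
    precision: int = 3,
) -> None:
    """Write rows as RFC-4180 CSV or as TSV (tabs forbidden inside fields).

    An empty row set still writes the header line.
    """
    if fmt not in _DELIMITERS:
        raise ValueError(f"unsupported export format {fmt!r} (use csv or tsv)")
    if isinstance(rows, pd.DataFrame):
        rows = rows.to_dict("records")
    delim = _DELIMITERS[fmt]
    writer = csv.writer(sink, delimiter=delim, lineterminator="\n", quoting=csv.QUOTE_MINIMAL)
    writer.writerow(COLUMNS)
    for row in rows:
        cells = [render_cell(col, row.get(col), precision) for col in COLUMNS]
        if fmt == "tsv":
            for cell in cells:
                if "\t" in cell:
                    raise ValueError("literal tab inside a TSV field")
        writer.writerow(cells)
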