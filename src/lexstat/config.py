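"""INI-file configuration.

Precedence is command-line flag > INI value > built-in default.  The schema:

.. code-block:: ini

    [database]
    path = /path/to/lexicon.db
    language = fi

    [build]
    min_freq = 10
    charset = a-zåäöšž0-9\\-'

    [query]
    max_rows = 10000
    precision = 3

    [neighborhood]
    autofreq = 10000
    minfreq = 100

    [logging]
    history_file = lexstat_history.log
    enabled = true
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Optional, Union

from .db import FINNISH_CHARSET
from .query import DEFAULT_MAX_ROWS
from .stats import DEFAULT_AMBIGUITY_THRESHOLD

__all__ = ["AppConfig", "load_config"]


@dataclass
class AppConfig:
    database_path: Optional[str] = None
    language: str = "fi"
    min_freq: int = 0
    charset: str = FINNISH_CHARSET
    max_rows: int = DEFAULT_MAX_ROWS
    precision: int = 3
    autofreq: int = 10_000
    hood_minfreq: int = 100
    ambiguity_threshold: float = DEFAULT_AMBIGUITY_THRESHOLD
    history_file: Optional[str] = None
    history_enabled: bool = True

    def __post_init__(self) -> None:
        if self.max_rows < 1:
            raise ValueError("max_rows must be >= 1")
        if self.precision < 0:
            raise ValueError("precision must be >= 0")

    def override(self, **kwargs) -> "AppConfig":
        """A copy with any non-None keyword overriding the current value."""
        values = {f.name: getattr(self, f.name) for f in fields(self)}
        values.update({k: v for k, v in kwargs.items() if v is not None})
        return AppConfig(**values)


_SCHEMA = {
    ("database", "path"): ("database_path", str),
    ("database", "language"): ("language", str),
    ("build", "min_freq"): ("min_freq", int),
    ("build", "charset"): ("charset", str),
    ("query", "max_rows"): ("max_rows", int),
    ("query", "precision"): ("precision", int),
    ("query", "ambiguity_threshold"): ("ambiguity_threshold", float),
    ("neighborhood", "autofreq"): ("autofreq", int),
    ("neighborhood", "minfreq"): ("hood_minfreq", int),
    ("logging", "history_file"): ("history_file", str),
}


def load_config(path: Optional[Union[str, Path]] = None) -> AppConfig:
    """Read an INI file into an :class:`AppConfig`; absent keys keep their
    built-in defaults.  ``path=None`` returns pure defaults."""
    cfg = AppConfig()
    if path is None:
        return cfg
    parser = configparser.ConfigParser()
    read = parser.read(path)
    if not read:
        raise FileNotFoundError(f"configuration file not found: {path}")
    kwargs = {}
    for (section, option), (attr, conv) in _SCHEMA.items():
        if parser.has_option(section, option):
            kwargs[attr] = conv(parser.get(section, option))
    if parser.has_option("logging", "enabled"):
        kwargs["history_enabled"] = parser.getboolean("logging", "enabled")
    return cfg.override(**kwargs)
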