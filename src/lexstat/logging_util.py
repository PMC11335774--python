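"""Query history logging.

Each executed query appends one timestamped line to a plain-text history
file.  Logging is best-effort by contract: a missing or unwritable history
path never aborts the query that triggered it.
"""

from __future__ import annotations

from datetime import datetime
from typing import Optional

__all__ = ["log_query"]


def log_query(
    query_text: str,
    row_count: int,
    elapsed: float,
    history_file: Optional[str],
    enabled: bool = True,
) -> None:
    """Append ``timestamp <TAB> query <TAB> rows <TAB> seconds`` to the
    history file; silently a no-op when disabled, unconfigured, or failing."""
    if not enabled or not history_file:
        return
    try:
        with open(history_file, "a", encoding="utf-8") as fh:
            fh.write(
                f"{datetime.now().isoformat(timespec='seconds')}\t"
                f"{query_text}\t{row_count}\t{elapsed:.3f}\n"
            )
    except OSError:
        pass
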