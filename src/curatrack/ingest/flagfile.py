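"""Tab-delimited flag-file adaptor.

External analysis pipelines deliver batches of problems as flat files
keyed by annotation ids (e.g. a list of dubious splice sites). The
dialect is fixed: a header line naming the five columns, ``#`` comment
lines skipped, one flag request per data row::

    target_entity_id  category  priority  source_name  comment

Unknown target ids pass through untouched — matching them against the
store (possibly retroactively) is the workflow module's concern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List

from ..errors import InvariantError, ParseError
from ..model import PRIORITY_MAX, PRIORITY_MIN, clamp_priority

__all__ = ["FlagRequest", "COLUMNS", "read_flag_file", "write_flag_file"]

log = logging.getLogger(__name__)

COLUMNS = ("target_entity_id", "category", "priority", "source_name", "comment")


@dataclass(frozen=True)
class FlagRequest:
    """A request to open (or escalate) one flag."""

    target_entity_id: str
    category: str
    priority: int
    source_name: str
    comment: str = ""

    def __post_init__(self):
        if not self.category:
            raise InvariantError("flag category must be non-empty")


def read_flag_file(path_or_text: str) -> List[FlagRequest]:
    """Parse a tab-delimited flag file into :class:`FlagRequest` s.

    Priorities outside 0–5 are clamped with a logged warning. An empty
    file (header only, or nothing at all) yields an empty list. A row
    with the wrong column count raises :class:`ParseError` with its line
    number.
    """
    text = str(path_or_text)
    if "\t" not in text and "\n" not in text:
        with open(text) as fh:
            text = fh.read()
    requests: List[FlagRequest] = []
    header_seen = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if not header_seen:
            if tuple(c.strip() for c in cols) != COLUMNS:
                raise ParseError(
                    f"expected header {list(COLUMNS)}, got {cols}", lineno)
            header_seen = True
            continue
        if len(cols) != len(COLUMNS):
            raise ParseError(
                f"expected {len(COLUMNS)} tab-separated columns, got {len(cols)}", lineno)
        target, category, priority_text, source, comment = (c.strip() for c in cols)
        try:
            priority = int(priority_text)
        except ValueError:
            raise ParseError(f"non-integer priority {priority_text!r}", lineno)
        clamped = clamp_priority(priority)
        if clamped != priority:
            log.warning("line %d: priority %d clamped to [%d, %d]",
                        lineno, priority, PRIORITY_MIN, PRIORITY_MAX)
        if not category:
            raise ParseError("empty category", lineno)
        requests.append(FlagRequest(target, category, clamped, source, comment))
    return requests


def write_flag_file(requests) -> str:
    lines = ["\t".join(COLUMNS)]
    for r in requests:
        lines.append("\t".join([r.target_entity_id, r.category, str(r.priority),
                                r.source_name, r.comment]))
    return "\n".join(lines) + "\n"
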