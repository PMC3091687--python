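"""Core data model for tracked genome annotation.

The tracked unit is a three-level hierarchy — genomic *locus*, its
*transcripts*, and their *subfeatures* (exons/CDS) — each carrying a genomic
interval, a controlled status tag and an urgency priority. Coordinates are
1-based fully closed throughout (GFF3 convention); conversion to 0-based
half-open happens only at the BED boundary in :mod:`curatrack.reports`.

All state changes anywhere in the package are recorded as append-only
:class:`HistoryEvent` rows; nothing in the public API can rewrite history.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import ClassVar, Optional, Tuple

from .errors import InvariantError, QueryError

__all__ = [
    "LEVELS",
    "STRANDS",
    "HISTORY_ACTIONS",
    "PRIORITY_MIN",
    "PRIORITY_MAX",
    "GenomicInterval",
    "AnnotationEntity",
    "StatusVocabulary",
    "HistoryEvent",
    "interval_overlap",
    "clamp_priority",
    "parse_region",
]

LEVELS: Tuple[str, ...] = ("locus", "transcript", "subfeature")
STRANDS: Tuple[str, ...] = ("+", "-", ".")

#: Controlled actions recorded in the history log.
HISTORY_ACTIONS: Tuple[str, ...] = (
    "created",
    "updated",
    "status_changed",
    "priority_changed",
    "flag_opened",
    "flag_resolved",
    "flag_auto_resolved",
    "comment_added",
    "verify_changed",
)

PRIORITY_MIN = 0
PRIORITY_MAX = 5


def clamp_priority(value: int) -> int:
    """Clamp a priority to the 0–5 ordinal scale (0 = no open issue)."""
    return max(PRIORITY_MIN, min(PRIORITY_MAX, int(value)))


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based, fully-closed interval on a named sequence.

    ``start == end`` denotes a single base. ``strand`` is ``+``, ``-`` or
    ``.`` (unstranded); overlap arithmetic is strand-blind — strand policy
    is applied by callers.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise InvariantError("interval chrom must be non-empty")
        if self.start < 1:
            raise InvariantError(f"interval start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise InvariantError(
                f"interval end ({self.end}) must be >= start ({self.start})"
            )
        if self.strand not in STRANDS:
            raise InvariantError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, other: "GenomicInterval") -> bool:
        """True if ``other`` lies fully within this interval (same chrom)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:
        s = f"{self.chrom}:{self.start}-{self.end}"
        return s if self.strand == "." else f"{s}({self.strand})"


def interval_overlap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two closed intervals (0 if chroms differ).

    Strand is ignored; with inclusive coordinates an identical interval
    overlaps itself by its full length.
    """
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


_REGION_RE = re.compile(r"^([^:]+):(\d+)-(\d+)(?:\(([+.\-])\))?$")


def parse_region(text: str) -> GenomicInterval:
    """Parse ``chrom:start-end`` (optionally ``(strand)``) into an interval.

    Raises :class:`QueryError` on malformed input — this is the entry point
    for user-supplied region filters.
    """
    m = _REGION_RE.match(text.strip())
    if not m:
        raise QueryError(f"malformed region {text!r}; expected chrom:start-end")
    chrom, start, end, strand = m.groups()
    try:
        return GenomicInterval(chrom, int(start), int(end), strand or ".")
    except InvariantError as exc:
        raise QueryError(str(exc)) from exc


@dataclass
class AnnotationEntity:
    """One tracked annotation unit: a locus, transcript or subfeature.

    ``parent_id`` links a transcript to its locus and a subfeature to its
    transcript. An empty ``parent_id`` is legal at any level (flat,
    degenerate configurations where transcripts are not grouped into gene
    loci are supported); when a parent is set, the store enforces level
    ordering and interval containment on the same chrom and strand.

    ``priority`` is an ordinal 0–5 (0 = no open issue, 5 = most urgent) and
    is kept equal to the maximum priority over the entity's open flags.
    ``verify`` marks selection for an experimental verification pipeline.
    """

    entity_id: str
    level: str
    interval: GenomicInterval
    parent_id: str = ""
    biotype: str = ""
    description: str = ""
    status: str = "new"
    priority: int = 0
    verify: bool = False

    def __post_init__(self):
        if not self.entity_id:
            raise InvariantError("entity_id must be non-empty")
        if self.level not in LEVELS:
            raise InvariantError(f"level must be one of {LEVELS}, got {self.level!r}")
        if self.level == "locus" and self.parent_id:
            raise InvariantError(f"locus {self.entity_id} may not have a parent")
        if not (PRIORITY_MIN <= self.priority <= PRIORITY_MAX):
            raise InvariantError(
                f"priority must be in [{PRIORITY_MIN}, {PRIORITY_MAX}], got {self.priority}"
            )

    def with_interval(self, interval: GenomicInterval) -> "AnnotationEntity":
        return replace(self, interval=interval)


@dataclass(frozen=True)
class StatusVocabulary:
    """Ordered set of controlled status tags an entity may carry."""

    tags: Tuple[str, ...]

    #: Tags every configuration must provide.
    REQUIRED: ClassVar[Tuple[str, ...]] = (
        "new",
        "updated",
        "rejected",
        "experimentally_verified",
    )

    def __post_init__(self):
        if not self.tags:
            raise InvariantError("status vocabulary must be non-empty")
        if len(set(self.tags)) != len(self.tags):
            raise InvariantError("status vocabulary contains duplicate tags")
        missing = set(self.REQUIRED) - set(self.tags)
        if missing:
            raise InvariantError(
                f"status vocabulary missing required tags: {sorted(missing)}"
            )

    @classmethod
    def default(cls) -> "StatusVocabulary":
        return cls(tags=cls.REQUIRED)

    def __contains__(self, tag: str) -> bool:
        return tag in self.tags


@dataclass(frozen=True)
class HistoryEvent:
    """Immutable record of one state change.

    Events are append-only: the store exposes no update or delete for them,
    and ``event_id`` increases strictly with insertion order.
    """

    event_id: int
    timestamp: str
    actor: str
    target_id: str
    action: str
    before: str = ""
    after: str = ""
    comment: str = ""
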