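"""Progress statistics and file export.

Statistics aggregate the flag table by chromosome, category or resolution
term; every grouping conserves the global counts, and the four state
counts always sum to the number of flags ever created — this is what
makes the tracker usable as a project-progress monitor.

Export writes high-priority and verification-selected entities as BED
(0-based half-open, score = priority x 200 clamped to 1000) or GFF3
(round-trippable through the ingest reader). Output is deterministic:
identical store state yields byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional

from .errors import FormatError, QueryError
from .ingest.gff3 import write_gff3
from .model import GenomicInterval

__all__ = [
    "StatsSummary",
    "stats",
    "global_stats",
    "format_stats_table",
    "stats_to_tsv",
    "stats_to_json",
    "export_entities",
]

GROUPINGS = ("chromosome", "category", "resolution_term")
_STATES = ("open", "accepted", "declined", "auto_resolved")

#: Group label for open flags under the resolution_term grouping and for
#: flags whose target cannot be placed on a chromosome.
OPEN_GROUP = "(open)"
UNPLACED_GROUP = "(unplaced)"


@dataclass
class StatsSummary:
    """Counts for one group value (a chromosome, category or term)."""

    group_key: str
    open: int = 0
    accepted: int = 0
    declined: int = 0
    auto_resolved: int = 0
    entities_with_open_flags: int = 0

    @property
    def total(self) -> int:
        return self.open + self.accepted + self.declined + self.auto_resolved

    @property
    def counts(self) -> Dict[str, int]:
        return {s: getattr(self, s) for s in _STATES}


def _flag_chromosome(store, flag) -> str:
    entity = store.get_entity(flag.target_entity_id)
    if entity is not None:
        return entity.interval.chrom
    # synthetic region keys carry their own coordinates: novel:chrom:start-end
    parts = flag.target_entity_id.split(":")
    if len(parts) == 3 and parts[0] == "novel":
        return parts[1]
    return UNPLACED_GROUP


def stats(store, group_by: str = "category") -> List[StatsSummary]:
    """One summary per observed group value, sorted by group key.

    ``group_by`` is one of ``chromosome``, ``category`` or
    ``resolution_term``. An empty store yields an empty list.
    """
    if group_by not in GROUPINGS:
        raise QueryError(f"group_by must be one of {GROUPINGS}, got {group_by!r}")
    summaries: Dict[str, StatsSummary] = {}
    open_entities: Dict[str, set] = {}
    for flag in store.all_flags():
        if group_by == "chromosome":
            key = _flag_chromosome(store, flag)
        elif group_by == "category":
            key = flag.category
        else:
            key = flag.resolution_term if flag.state != "open" else OPEN_GROUP
        summary = summaries.setdefault(key, StatsSummary(group_key=key))
        setattr(summary, flag.state, getattr(summary, flag.state) + 1)
        if flag.state == "open" and not flag.unmatched:
            open_entities.setdefault(key, set()).add(flag.target_entity_id)
    for key, summary in summaries.items():
        summary.entities_with_open_flags = len(open_entities.get(key, ()))
    return [summaries[k] for k in sorted(summaries)]


def global_stats(store) -> StatsSummary:
    """The all-flags summary (group key ``all``)."""
    total = StatsSummary(group_key="all")
    open_entities = set()
    for flag in store.all_flags():
        setattr(total, flag.state, getattr(total, flag.state) + 1)
        if flag.state == "open" and not flag.unmatched:
            open_entities.add(flag.target_entity_id)
    total.entities_with_open_flags = len(open_entities)
    return total


def format_stats_table(summaries: List[StatsSummary]) -> str:
    headers = ("group", "open", "accepted", "declined", "auto_resolved",
               "total", "entities_open")
    rows = [headers] + [
        (s.group_key, str(s.open), str(s.accepted), str(s.declined),
         str(s.auto_resolved), str(s.total), str(s.entities_with_open_flags))
        for s in summaries
    ]
    widths = [max(len(r[i]) for r in rows) for i in range(len(headers))]
    lines = ["  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip()
             for row in rows]
    return "\n".join(lines) + "\n"


def stats_to_tsv(summaries: List[StatsSummary]) -> str:
    lines = ["\t".join(("group", "open", "accepted", "declined", "auto_resolved",
                        "total", "entities_open"))]
    for s in summaries:
        lines.append("\t".join(map(str, (s.group_key, s.open, s.accepted, s.declined,
                                         s.auto_resolved, s.total,
                                         s.entities_with_open_flags))))
    return "\n".join(lines) + "\n"


def stats_to_json(summaries: List[StatsSummary]) -> str:
    return json.dumps([
        {"group_key": s.group_key, **s.counts, "total": s.total,
         "entities_with_open_flags": s.entities_with_open_flags}
        for s in summaries
    ], indent=2)


def _select(store, min_priority: Optional[int], verify_only: bool,
            region: Optional[GenomicInterval]):
    entities = store.find_entities(region=region)
    if min_priority is not None:
        entities = [e for e in entities if e.priority >= min_priority]
    if verify_only:
        entities = [e for e in entities if e.verify]
    return entities


def export_entities(store, fmt: str, min_priority: Optional[int] = None,
                    verify_only: bool = False,
                    region: Optional[GenomicInterval] = None) -> str:
    """Export selected entities as BED or GFF3 text.

    BED uses 0-based half-open coordinates, ``name`` = entity id and
    ``score`` = priority x 200 clamped to 1000 (so a browser's score
    shading tracks curation urgency). GFF3 output round-trips through
    :func:`curatrack.ingest.read_gff3`. Both orderings are deterministic
    (chrom, start, entity_id), so identical stores export identical bytes.
    """
    fmt_norm = fmt.strip().upper()
    if fmt_norm not in ("BED", "GFF3"):
        raise FormatError(f"unsupported export format {fmt!r}; use BED or GFF3")
    entities = _select(store, min_priority, verify_only, region)
    if fmt_norm == "GFF3":
        return write_gff3(entities)
    lines = []
    for e in entities:
        iv = e.interval
        score = min(e.priority * 200, 1000)
        lines.append("\t".join([iv.chrom, str(iv.start - 1), str(iv.end),
                                e.entity_id, str(score), iv.strand]))
    return "\n".join(lines) + ("\n" if lines else "")
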