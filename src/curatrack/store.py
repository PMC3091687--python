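"""Single-file SQLite store behind every tracked entity, flag and event.

The schema mirrors the data model: ``entities``, ``flags``, ``history``
(append-only), plus a per-source update-cycle counter and a registry of
configured sources. All writes go through :meth:`AnnotationStore.transaction`
so multi-step operations (an ingest update cycle, a bulk resolution) are
atomic. The schema is versioned via a ``schema_version`` table.

Coordinates are stored 1-based closed, in columns ``start``/``stop``
(``end`` is an SQL keyword).
"""

from __future__ import annotations

import json
import sqlite3
from contextlib import contextmanager
from datetime import datetime, timezone
from typing import Iterable, List, Optional, Sequence, Tuple

from .errors import (
    EntityNotFoundError,
    HierarchyError,
    InvariantError,
    QueryError,
)
from .model import (
    LEVELS,
    AnnotationEntity,
    GenomicInterval,
    HistoryEvent,
    StatusVocabulary,
    clamp_priority,
)
from .workflow import Flag, FlagKey

SCHEMA_VERSION = 1

_SCHEMA = """
CREATE TABLE schema_version (version INTEGER NOT NULL);

CREATE TABLE entities (
    entity_id   TEXT PRIMARY KEY,
    level       TEXT NOT NULL CHECK (level IN ('locus','transcript','subfeature')),
    parent_id   TEXT NOT NULL DEFAULT '',
    chrom       TEXT NOT NULL,
    start       INTEGER NOT NULL,
    stop        INTEGER NOT NULL,
    strand      TEXT NOT NULL DEFAULT '.',
    biotype     TEXT NOT NULL DEFAULT '',
    description TEXT NOT NULL DEFAULT '',
    status      TEXT NOT NULL,
    priority    INTEGER NOT NULL DEFAULT 0,
    verify      INTEGER NOT NULL DEFAULT 0
);
CREATE INDEX idx_entities_region ON entities (chrom, start, stop);
CREATE INDEX idx_entities_parent ON entities (parent_id);

CREATE TABLE flags (
    flag_id          INTEGER PRIMARY KEY AUTOINCREMENT,
    target_entity_id TEXT NOT NULL,
    category         TEXT NOT NULL,
    source_name      TEXT NOT NULL,
    priority         INTEGER NOT NULL,
    state            TEXT NOT NULL DEFAULT 'open'
                     CHECK (state IN ('open','accepted','declined','auto_resolved')),
    resolution_term  TEXT NOT NULL DEFAULT '',
    opened_at        TEXT NOT NULL,
    resolved_at      TEXT,
    opened_by        TEXT NOT NULL,
    resolved_by      TEXT,
    detail           TEXT NOT NULL DEFAULT '',
    unmatched        INTEGER NOT NULL DEFAULT 0,
    auto_resolvable  INTEGER NOT NULL DEFAULT 0
);
-- at most one OPEN flag per (target, category, source) key
CREATE UNIQUE INDEX idx_open_flag_key
    ON flags (target_entity_id, category, source_name) WHERE state = 'open';
CREATE INDEX idx_flags_target ON flags (target_entity_id);

CREATE TABLE history (
    event_id  INTEGER PRIMARY KEY AUTOINCREMENT,
    timestamp TEXT NOT NULL,
    actor     TEXT NOT NULL,
    target_id TEXT NOT NULL,
    action    TEXT NOT NULL,
    before    TEXT NOT NULL DEFAULT '',
    after     TEXT NOT NULL DEFAULT '',
    comment   TEXT NOT NULL DEFAULT ''
);

CREATE TABLE source_cycles (
    source_name TEXT PRIMARY KEY,
    cycle_id    INTEGER NOT NULL
);

CREATE TABLE sources (
    source_name   TEXT PRIMARY KEY,
    kind          TEXT NOT NULL,
    locator       TEXT NOT NULL DEFAULT '',
    window_size   INTEGER NOT NULL DEFAULT 10000,
    enabled       INTEGER NOT NULL DEFAULT 1,
    schema_strict INTEGER NOT NULL DEFAULT 0
);
"""

_LEVEL_PARENT = {"transcript": "locus", "subfeature": "transcript"}


def _now() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="microseconds")


def _row_to_entity(row: sqlite3.Row) -> AnnotationEntity:
    return AnnotationEntity(
        entity_id=row["entity_id"],
        level=row["level"],
        interval=GenomicInterval(row["chrom"], row["start"], row["stop"], row["strand"]),
        parent_id=row["parent_id"],
        biotype=row["biotype"],
        description=row["description"],
        status=row["status"],
        priority=row["priority"],
        verify=bool(row["verify"]),
    )


def _row_to_flag(row: sqlite3.Row) -> Flag:
    return Flag(
        flag_id=row["flag_id"],
        target_entity_id=row["target_entity_id"],
        category=row["category"],
        source_name=row["source_name"],
        priority=row["priority"],
        state=row["state"],
        resolution_term=row["resolution_term"],
        opened_at=row["opened_at"],
        resolved_at=row["resolved_at"],
        opened_by=row["opened_by"],
        resolved_by=row["resolved_by"],
        detail=row["detail"],
        unmatched=bool(row["unmatched"]),
        auto_resolvable=bool(row["auto_resolvable"]),
    )


class AnnotationStore:
    """The persistent annotation-tracking store.

    Parameters
    ----------
    path:
        SQLite file path, or ``":memory:"`` for an ephemeral store.
    status_vocabulary:
        Controlled status tags; defaults to the built-in minimum set.
    """

    def __init__(self, path: str = ":memory:",
                 status_vocabulary: Optional[StatusVocabulary] = None):
        self.path = path
        self.status_vocabulary = status_vocabulary or StatusVocabulary.default()
        self.conn = sqlite3.connect(path, isolation_level=None)
        self.conn.row_factory = sqlite3.Row
        self.conn.execute("PRAGMA foreign_keys = ON")
        self._tx_depth = 0
        tables = {r[0] for r in self.conn.execute(
            "SELECT name FROM sqlite_master WHERE type='table'")}
        if "schema_version" not in tables:
            self.conn.executescript(_SCHEMA)
            self.conn.execute("INSERT INTO schema_version VALUES (?)", (SCHEMA_VERSION,))
        else:
            (version,) = self.conn.execute("SELECT version FROM schema_version").fetchone()
            if version != SCHEMA_VERSION:
                raise InvariantError(
                    f"store schema version {version} != supported {SCHEMA_VERSION}")

    def close(self):
        self.conn.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    # ------------------------------------------------------------------ tx

    @contextmanager
    def transaction(self):
        """Re-entrant write transaction; the outermost level commits."""
        if self._tx_depth == 0:
            self.conn.execute("BEGIN IMMEDIATE")
        self._tx_depth += 1
        try:
            yield
        except BaseException:
            self._tx_depth -= 1
            if self._tx_depth == 0:
                self.conn.execute("ROLLBACK")
            raise
        else:
            self._tx_depth -= 1
            if self._tx_depth == 0:
                self.conn.execute("COMMIT")

    # -------------------------------------------------------------- history

    def _emit(self, actor: str, target_id: str, action: str,
              before: str = "", after: str = "", comment: str = "") -> None:
        self.conn.execute(
            "INSERT INTO history (timestamp, actor, target_id, action, before, after, comment)"
            " VALUES (?,?,?,?,?,?,?)",
            (_now(), actor, target_id, action, before, after, comment),
        )

    def history(self, target_id: Optional[str] = None) -> List[HistoryEvent]:
        """All history events (optionally for one target), oldest first."""
        if target_id is None:
            rows = self.conn.execute("SELECT * FROM history ORDER BY event_id")
        else:
            rows = self.conn.execute(
                "SELECT * FROM history WHERE target_id=? ORDER BY event_id", (target_id,))
        return [HistoryEvent(r["event_id"], r["timestamp"], r["actor"], r["target_id"],
                             r["action"], r["before"], r["after"], r["comment"])
                for r in rows]

    def add_comment(self, target_id: str, comment: str, actor: str) -> None:
        """Attach a free-text comment to an entity's or flag's history."""
        with self.transaction():
            self._emit(actor, target_id, "comment_added", comment=comment)

    # ------------------------------------------------------------- entities

    def _check_parent(self, entity: AnnotationEntity) -> None:
        if not entity.parent_id:
            return
        row = self.conn.execute(
            "SELECT * FROM entities WHERE entity_id=?", (entity.parent_id,)).fetchone()
        if row is None:
            raise HierarchyError(
                f"parent {entity.parent_id!r} of {entity.entity_id!r} does not exist")
        expected = _LEVEL_PARENT.get(entity.level)
        if row["level"] != expected:
            raise HierarchyError(
                f"{entity.level} {entity.entity_id!r} requires a {expected} parent, "
                f"got {row['level']} {entity.parent_id!r}")
        parent_iv = GenomicInterval(row["chrom"], row["start"], row["stop"], row["strand"])
        if not parent_iv.contains(entity.interval):
            raise InvariantError(
                f"{entity.entity_id!r} interval {entity.interval} lies outside "
                f"parent {entity.parent_id!r} interval {parent_iv}")
        if entity.interval.strand != parent_iv.strand:
            raise InvariantError(
                f"{entity.entity_id!r} strand {entity.interval.strand!r} differs "
                f"from parent strand {parent_iv.strand!r}")

    def upsert_entity(self, entity: AnnotationEntity, actor: str = "system") -> AnnotationEntity:
        """Insert a new entity (status forced to ``new``) or update the
        mutable fields of an existing one.

        Each changed field emits one ``updated`` history event carrying the
        serialised before/after values; any change also moves the entity's
        status to ``updated`` (part of the same operation, no extra event).
        An identical re-upsert emits nothing.
        """
        with self.transaction():
            self._check_parent(entity)
            row = self.conn.execute(
                "SELECT * FROM entities WHERE entity_id=?", (entity.entity_id,)).fetchone()
            if row is None:
                iv = entity.interval
                self.conn.execute(
                    "INSERT INTO entities (entity_id, level, parent_id, chrom, start, stop,"
                    " strand, biotype, description, status, priority, verify)"
                    " VALUES (?,?,?,?,?,?,?,?,?,?,?,?)",
                    (entity.entity_id, entity.level, entity.parent_id, iv.chrom, iv.start,
                     iv.end, iv.strand, entity.biotype, entity.description, "new",
                     0, 0),
                )
                self._emit(actor, entity.entity_id, "created",
                           after=json.dumps({"level": entity.level, "interval": str(iv)}))
                self._attach_unmatched_flags(entity.entity_id, actor)
                return self.get_entity(entity.entity_id)

            old = _row_to_entity(row)
            changes = []
            if old.interval != entity.interval:
                changes.append(("interval", str(old.interval), str(entity.interval)))
            if old.parent_id != entity.parent_id:
                changes.append(("parent_id", old.parent_id, entity.parent_id))
            if old.biotype != entity.biotype:
                changes.append(("biotype", old.biotype, entity.biotype))
            if old.description != entity.description:
                changes.append(("description", old.description, entity.description))
            if not changes:
                return old
            iv = entity.interval
            self.conn.execute(
                "UPDATE entities SET parent_id=?, chrom=?, start=?, stop=?, strand=?,"
                " biotype=?, description=?, status=? WHERE entity_id=?",
                (entity.parent_id, iv.chrom, iv.start, iv.end, iv.strand,
                 entity.biotype, entity.description, "updated", entity.entity_id),
            )
            for field_name, before, after in changes:
                self._emit(actor, entity.entity_id, "updated",
                           before=json.dumps({field_name: before}),
                           after=json.dumps({field_name: after}))
            return self.get_entity(entity.entity_id)

    def _attach_unmatched_flags(self, entity_id: str, actor: str) -> None:
        rows = self.conn.execute(
            "SELECT flag_id, priority FROM flags WHERE target_entity_id=?"
            " AND state='open' AND unmatched=1", (entity_id,)).fetchall()
        if not rows:
            return
        self.conn.execute(
            "UPDATE flags SET unmatched=0 WHERE target_entity_id=? AND state='open'"
            " AND unmatched=1", (entity_id,))
        self.raise_entity_priority(entity_id, max(r["priority"] for r in rows), actor)

    def get_entity(self, entity_id: str) -> Optional[AnnotationEntity]:
        row = self.conn.execute(
            "SELECT * FROM entities WHERE entity_id=?", (entity_id,)).fetchone()
        return None if row is None else _row_to_entity(row)

    def set_status(self, entity_id: str, status: str, actor: str) -> None:
        """Explicit controlled status change (e.g. to experimentally_verified)."""
        if status not in self.status_vocabulary:
            raise InvariantError(
                f"status {status!r} not in vocabulary {self.status_vocabulary.tags}")
        e = self.get_entity(entity_id)
        if e is None:
            raise EntityNotFoundError(f"unknown entity id {entity_id!r}")
        if e.status == status:
            return
        with self.transaction():
            self.conn.execute("UPDATE entities SET status=? WHERE entity_id=?",
                              (status, entity_id))
            self._emit(actor, entity_id, "status_changed", before=e.status, after=status)

    def raise_entity_priority(self, entity_id: str, priority: int, actor: str) -> None:
        """Monotone raise: entity priority becomes max(current, priority)."""
        e = self.get_entity(entity_id)
        if e is None:
            return
        priority = clamp_priority(priority)
        if priority > e.priority:
            with self.transaction():
                self.conn.execute("UPDATE entities SET priority=? WHERE entity_id=?",
                                  (priority, entity_id))
                self._emit(actor, entity_id, "priority_changed",
                           before=str(e.priority), after=str(priority))

    def recompute_entity_priority(self, entity_id: str, actor: str) -> None:
        """Set priority to the max over the entity's open flags (0 if none)."""
        e = self.get_entity(entity_id)
        if e is None:
            return
        (target,) = self.conn.execute(
            "SELECT COALESCE(MAX(priority), 0) FROM flags"
            " WHERE target_entity_id=? AND state='open' AND unmatched=0",
            (entity_id,)).fetchone()
        if target != e.priority:
            with self.transaction():
                self.conn.execute("UPDATE entities SET priority=? WHERE entity_id=?",
                                  (target, entity_id))
                self._emit(actor, entity_id, "priority_changed",
                           before=str(e.priority), after=str(target))

    def set_entity_verify(self, entity_id: str, value: bool, actor: str) -> None:
        with self.transaction():
            self.conn.execute("UPDATE entities SET verify=? WHERE entity_id=?",
                              (1 if value else 0, entity_id))
            self._emit(actor, entity_id, "verify_changed",
                       before=str(not value), after=str(bool(value)))

    def verify_entities(self) -> List[AnnotationEntity]:
        rows = self.conn.execute(
            "SELECT * FROM entities WHERE verify=1 ORDER BY chrom, start, entity_id")
        return [_row_to_entity(r) for r in rows]

    # --------------------------------------------------------------- queries

    def find_entities(
        self,
        region: Optional[GenomicInterval] = None,
        level: Optional[str] = None,
        status: Optional[str] = None,
        flag_category: Optional[str] = None,
        keyword: Optional[str] = None,
        min_priority: Optional[int] = None,
        same_strand: bool = False,
    ) -> List[AnnotationEntity]:
        """Filtered entity listing; all given predicates are conjoined.

        Region matching is any-overlap (>= 1 base) and strand-blind unless
        ``same_strand`` is set (which requires a stranded ``region``).
        ``keyword`` matches case-insensitively against entity_id and
        description. Output is totally ordered by (chrom, start, entity_id).
        """
        clauses, params = [], []
        if region is not None:
            if not isinstance(region, GenomicInterval):
                raise QueryError(f"region must be a GenomicInterval, got {type(region)}")
            clauses.append("chrom=? AND start<=? AND stop>=?")
            params += [region.chrom, region.end, region.start]
            if same_strand:
                if region.strand == ".":
                    raise QueryError("same_strand filter requires a stranded region")
                clauses.append("strand=?")
                params.append(region.strand)
        elif same_strand:
            raise QueryError("same_strand filter requires a region")
        if level is not None:
            if level not in LEVELS:
                raise QueryError(f"unknown level {level!r}")
            clauses.append("level=?")
            params.append(level)
        if status is not None:
            clauses.append("status=?")
            params.append(status)
        if min_priority is not None:
            clauses.append("priority>=?")
            params.append(int(min_priority))
        if flag_category is not None:
            clauses.append(
                "EXISTS (SELECT 1 FROM flags f WHERE f.target_entity_id=entities.entity_id"
                " AND f.state='open' AND f.unmatched=0 AND f.category=?)")
            params.append(flag_category)
        if keyword is not None:
            clauses.append(
                "(instr(lower(entity_id), lower(?)) > 0"
                " OR instr(lower(description), lower(?)) > 0)")
            params += [keyword, keyword]
        where = (" WHERE " + " AND ".join(clauses)) if clauses else ""
        rows = self.conn.execute(
            f"SELECT * FROM entities{where} ORDER BY chrom, start, entity_id", params)
        return [_row_to_entity(r) for r in rows]

    def all_entities(self) -> List[AnnotationEntity]:
        return self.find_entities()

    def children(self, parent_id: str) -> List[AnnotationEntity]:
        rows = self.conn.execute(
            "SELECT * FROM entities WHERE parent_id=? ORDER BY chrom, start, entity_id",
            (parent_id,))
        return [_row_to_entity(r) for r in rows]

    def overlapping(self, interval: GenomicInterval,
                    level: Optional[str] = None) -> List[AnnotationEntity]:
        """Entities overlapping ``interval`` by >= 1 base (strand-blind)."""
        sql = "SELECT * FROM entities WHERE chrom=? AND start<=? AND stop>=?"
        params = [interval.chrom, interval.end, interval.start]
        if level is not None:
            sql += " AND level=?"
            params.append(level)
        rows = self.conn.execute(sql + " ORDER BY chrom, start, entity_id", params)
        return [_row_to_entity(r) for r in rows]

    def entity_count(self) -> int:
        (n,) = self.conn.execute("SELECT COUNT(*) FROM entities").fetchone()
        return n

    def audit_hierarchy(self) -> List[str]:
        """Store-wide containment/hierarchy audit; returns violations."""
        problems = []
        for e in self.all_entities():
            if not e.parent_id:
                continue
            parent = self.get_entity(e.parent_id)
            if parent is None:
                problems.append(f"{e.entity_id}: parent {e.parent_id} missing")
                continue
            if parent.level != _LEVEL_PARENT.get(e.level):
                problems.append(
                    f"{e.entity_id}: {e.level} under {parent.level} {parent.entity_id}")
            if not parent.interval.contains(e.interval):
                problems.append(f"{e.entity_id}: interval outside parent {e.parent_id}")
            elif e.interval.strand != parent.interval.strand:
                problems.append(f"{e.entity_id}: strand differs from parent {e.parent_id}")
        return problems

    def audit_flags(self) -> List[str]:
        """Store-wide flag invariants: one open flag per key, terms set on
        resolved flags, entity priority >= max over open matched flags
        (a lower bound, because update cycles are priority-monotone:
        auto-resolution never lowers an entity's urgency)."""
        problems = []
        rows = self.conn.execute(
            "SELECT target_entity_id, category, source_name, COUNT(*) AS n FROM flags"
            " WHERE state='open' GROUP BY 1,2,3 HAVING n > 1").fetchall()
        for r in rows:
            problems.append(
                f"{r['n']} open flags for key ({r['target_entity_id']},"
                f" {r['category']}, {r['source_name']})")
        rows = self.conn.execute(
            "SELECT flag_id FROM flags WHERE state != 'open' AND resolution_term=''")
        problems += [f"flag {r['flag_id']} resolved without a term" for r in rows]
        for e in self.all_entities():
            (expected,) = self.conn.execute(
                "SELECT COALESCE(MAX(priority), 0) FROM flags"
                " WHERE target_entity_id=? AND state='open' AND unmatched=0",
                (e.entity_id,)).fetchone()
            if e.priority < expected:
                problems.append(
                    f"{e.entity_id}: priority {e.priority} < max open flag {expected}")
        return problems

    # ----------------------------------------------------------------- flags

    def insert_flag(self, *, target_entity_id: str, category: str, source_name: str,
                    priority: int, detail: str, actor: str,
                    unmatched: bool, auto_resolvable: bool) -> Flag:
        with self.transaction():
            cur = self.conn.execute(
                "INSERT INTO flags (target_entity_id, category, source_name, priority,"
                " state, opened_at, opened_by, detail, unmatched, auto_resolvable)"
                " VALUES (?,?,?,?,'open',?,?,?,?,?)",
                (target_entity_id, category, source_name, clamp_priority(priority),
                 _now(), actor, detail, 1 if unmatched else 0,
                 1 if auto_resolvable else 0),
            )
            flag_id = cur.lastrowid
            self._emit(actor, f"flag:{flag_id}", "flag_opened",
                       after=json.dumps({"target": target_entity_id,
                                         "category": category,
                                         "source": source_name,
                                         "priority": clamp_priority(priority)}))
            return self.get_flag(flag_id)

    def get_flag(self, flag_id: int) -> Optional[Flag]:
        row = self.conn.execute("SELECT * FROM flags WHERE flag_id=?", (flag_id,)).fetchone()
        return None if row is None else _row_to_flag(row)

    def find_open_flag(self, key: FlagKey) -> Optional[Flag]:
        row = self.conn.execute(
            "SELECT * FROM flags WHERE target_entity_id=? AND category=?"
            " AND source_name=? AND state='open'", key).fetchone()
        return None if row is None else _row_to_flag(row)

    def open_flags(self, source_name: Optional[str] = None,
                   target_entity_id: Optional[str] = None,
                   auto_resolvable: Optional[bool] = None) -> List[Flag]:
        sql, params = "SELECT * FROM flags WHERE state='open'", []
        if source_name is not None:
            sql += " AND source_name=?"
            params.append(source_name)
        if target_entity_id is not None:
            sql += " AND target_entity_id=?"
            params.append(target_entity_id)
        if auto_resolvable is not None:
            sql += " AND auto_resolvable=?"
            params.append(1 if auto_resolvable else 0)
        rows = self.conn.execute(sql + " ORDER BY flag_id", params)
        return [_row_to_flag(r) for r in rows]

    def all_flags(self) -> List[Flag]:
        rows = self.conn.execute("SELECT * FROM flags ORDER BY flag_id")
        return [_row_to_flag(r) for r in rows]

    def set_flag_priority(self, flag_id: int, priority: int, actor: str) -> None:
        flag = self.get_flag(flag_id)
        priority = clamp_priority(priority)
        if flag is None or flag.priority == priority:
            return
        with self.transaction():
            self.conn.execute("UPDATE flags SET priority=? WHERE flag_id=?",
                              (priority, flag_id))
            self._emit(actor, f"flag:{flag_id}", "priority_changed",
                       before=str(flag.priority), after=str(priority))

    def close_flag(self, flag_id: int, *, state: str, term: str, actor: str,
                   action: str, comment: str = "") -> None:
        flag = self.get_flag(flag_id)
        if flag is None or flag.state != "open":
            raise InvariantError(f"flag {flag_id} is not open")
        with self.transaction():
            self.conn.execute(
                "UPDATE flags SET state=?, resolution_term=?, resolved_at=?, resolved_by=?"
                " WHERE flag_id=?",
                (state, term, _now(), actor, flag_id))
            self._emit(actor, f"flag:{flag_id}", action,
                       before="open", after=state, comment=comment)

    # ---------------------------------------------------------- sources/cycles

    def register_source(self, config) -> None:
        """Register (or update) a configured source."""
        with self.transaction():
            self.conn.execute(
                "INSERT INTO sources (source_name, kind, locator, window_size, enabled,"
                " schema_strict) VALUES (?,?,?,?,?,?)"
                " ON CONFLICT(source_name) DO UPDATE SET kind=excluded.kind,"
                " locator=excluded.locator, window_size=excluded.window_size,"
                " enabled=excluded.enabled, schema_strict=excluded.schema_strict",
                (config.source_name, config.kind, config.locator, config.window_size,
                 1 if config.enabled else 0, 1 if config.schema_strict else 0))

    def source_registered(self, source_name: str) -> bool:
        row = self.conn.execute(
            "SELECT 1 FROM sources WHERE source_name=?", (source_name,)).fetchone()
        return row is not None

    def next_cycle_id(self, source_name: str) -> int:
        with self.transaction():
            row = self.conn.execute(
                "SELECT cycle_id FROM source_cycles WHERE source_name=?",
                (source_name,)).fetchone()
            nxt = (row["cycle_id"] + 1) if row else 1
            self.conn.execute(
                "INSERT INTO source_cycles (source_name, cycle_id) VALUES (?,?)"
                " ON CONFLICT(source_name) DO UPDATE SET cycle_id=excluded.cycle_id",
                (source_name, nxt))
            return nxt

    # ------------------------------------------------------------- snapshots

    def table_rows(self, table: str) -> List[Tuple]:
        """All rows of a table as plain tuples (for byte-level comparison
        of store states in audits)."""
        if table not in ("entities", "flags", "history", "sources", "source_cycles"):
            raise QueryError(f"unknown table {table!r}")
        return [tuple(r) for r in self.conn.execute(f"SELECT * FROM {table} ORDER BY 1")]
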