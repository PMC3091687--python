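"""Flag lifecycle: opening, manual resolution with controlled terms,
verification selection, and the invariants that make flags auditable.

A flag is a categorised, prioritised problem attached to an annotation
entity. Its key is ``(target_entity_id, category, source_name)``; at most
one *open* flag may exist per key — re-raising an open problem escalates
its priority instead of duplicating it. The only legal transitions are::

    open -> accepted       (manual, accept-polarity term)
    open -> declined       (manual, decline-polarity term)
    open -> auto_resolved  (conflict engine, reserved term "auto_resolved")

Resolved flags are immutable; correcting a mistaken resolution means
opening a new flag, which preserves history fidelity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

from .errors import (
    EntityNotFoundError,
    InvariantError,
    StateError,
    VocabularyError,
)
from .model import clamp_priority

__all__ = [
    "FLAG_STATES",
    "AUTO_RESOLVED_TERM",
    "Flag",
    "FlagKey",
    "ResolutionTerm",
    "ResolutionVocabulary",
    "open_flag",
    "resolve_flag",
    "resolve_flags_bulk",
    "set_verify",
    "list_verify",
]

FLAG_STATES = ("open", "accepted", "declined", "auto_resolved")

#: Reserved resolution term used when the conflict engine closes a flag
#: because its conflict was not re-triggered by the source's next update.
AUTO_RESOLVED_TERM = "auto_resolved"

FlagKey = Tuple[str, str, str]  # (target_entity_id, category, source_name)


@dataclass(frozen=True)
class Flag:
    """One tracked problem. ``unmatched`` marks flags whose target id was
    unknown when the flag was filed (they attach retroactively when the
    entity appears); ``auto_resolvable`` marks flags opened by the conflict
    engine, the only ones auto-resolution may ever close."""

    flag_id: int
    target_entity_id: str
    category: str
    source_name: str
    priority: int
    state: str = "open"
    resolution_term: str = ""
    opened_at: str = ""
    resolved_at: Optional[str] = None
    opened_by: str = ""
    resolved_by: Optional[str] = None
    detail: str = ""
    unmatched: bool = False
    auto_resolvable: bool = False

    @property
    def key(self) -> FlagKey:
        return (self.target_entity_id, self.category, self.source_name)

    @property
    def is_open(self) -> bool:
        return self.state == "open"


@dataclass(frozen=True)
class ResolutionTerm:
    """A controlled resolution term. ``categories`` lists the flag
    categories it applies to; ``("*",)`` means any category."""

    term: str
    polarity: str  # "accept" | "decline"
    categories: Tuple[str, ...]

    def __post_init__(self):
        if self.polarity not in ("accept", "decline"):
            raise InvariantError(f"polarity must be accept/decline, got {self.polarity!r}")
        if not self.term:
            raise InvariantError("resolution term must be non-empty")
        if self.term == AUTO_RESOLVED_TERM:
            raise InvariantError(f"{AUTO_RESOLVED_TERM!r} is reserved for the engine")
        if not self.categories:
            raise InvariantError(f"term {self.term!r} must apply to >= 1 category")

    def applies_to(self, category: str) -> bool:
        return "*" in self.categories or category in self.categories


_DEFAULT_TERMS = (
    ResolutionTerm("annotated_splicing_corrected", "accept", ("splice_mismatch", "splice")),
    ResolutionTerm("splice_suggestion_rejected", "decline", ("splice_mismatch", "splice")),
    ResolutionTerm("boundary_corrected", "accept", ("boundary_mismatch",)),
    ResolutionTerm("new_locus_annotated", "accept", ("novel_locus",)),
    ResolutionTerm("description_updated", "accept", ("description_mismatch",)),
    ResolutionTerm("reference_restored", "accept", ("reference_missing",)),
    ResolutionTerm("annotation_updated", "accept", ("*",)),
    ResolutionTerm("external_data_rejected", "decline", ("*",)),
)


@dataclass(frozen=True)
class ResolutionVocabulary:
    """The controlled terms annotators resolve flags with.

    Validation guarantees every explicitly-named category has at least one
    accept and one decline term (wildcard terms count for every category),
    so no flag can ever be stuck without a legal resolution.
    """

    terms: Tuple[ResolutionTerm, ...] = _DEFAULT_TERMS

    def __post_init__(self):
        names = [t.term for t in self.terms]
        if len(set(names)) != len(names):
            raise InvariantError("resolution vocabulary contains duplicate terms")
        categories = set()
        for t in self.terms:
            categories.update(c for c in t.categories if c != "*")
        for cat in sorted(categories):
            pols = {t.polarity for t in self.terms if t.applies_to(cat)}
            if pols != {"accept", "decline"}:
                raise InvariantError(
                    f"category {cat!r} needs >= 1 accept and >= 1 decline term"
                )

    @classmethod
    def default(cls) -> "ResolutionVocabulary":
        return cls()

    def lookup(self, term: str) -> Optional[ResolutionTerm]:
        for t in self.terms:
            if t.term == term:
                return t
        return None

    def applicable(self, category: str) -> List[ResolutionTerm]:
        return [t for t in self.terms if t.applies_to(category)]


def open_flag(store, request, actor: str, *, auto_resolvable: bool = False) -> Flag:
    """Open a flag (or escalate the open flag with the same key).

    If an open flag with key ``(target, category, source)`` already exists
    its priority is raised to the maximum of the two and no new flag is
    created. The target entity's priority is raised to match. Unknown
    target ids are allowed: the flag is held as *unmatched* and attaches
    retroactively when the entity is inserted.
    """
    priority = clamp_priority(request.priority)
    key = (request.target_entity_id, request.category, request.source_name)
    with store.transaction():
        existing = store.find_open_flag(key)
        if existing is not None:
            if priority > existing.priority:
                store.set_flag_priority(existing.flag_id, priority, actor)
                if not existing.unmatched:
                    store.raise_entity_priority(existing.target_entity_id, priority, actor)
                return store.get_flag(existing.flag_id)
            return existing
        matched = store.get_entity(request.target_entity_id) is not None
        flag = store.insert_flag(
            target_entity_id=request.target_entity_id,
            category=request.category,
            source_name=request.source_name,
            priority=priority,
            detail=getattr(request, "comment", "") or "",
            actor=actor,
            unmatched=not matched,
            auto_resolvable=auto_resolvable,
        )
        if matched:
            store.raise_entity_priority(request.target_entity_id, priority, actor)
        return flag


def _validate_resolution(store, flag_id: int, term: str, vocabulary: ResolutionVocabulary):
    flag = store.get_flag(flag_id)
    if flag is None:
        raise EntityNotFoundError(f"no flag with id {flag_id}")
    if flag.state != "open":
        raise StateError(f"flag {flag_id} is already {flag.state}")
    t = vocabulary.lookup(term)
    if t is None or not t.applies_to(flag.category):
        applicable = [x.term for x in vocabulary.applicable(flag.category)]
        raise VocabularyError(
            f"term {term!r} is not applicable to category {flag.category!r}; "
            f"applicable terms: {', '.join(applicable)}",
            applicable=applicable,
        )
    return flag, t


def resolve_flag(
    store,
    flag_id: int,
    term: str,
    actor: str,
    comment: str = "",
    vocabulary: Optional[ResolutionVocabulary] = None,
) -> Flag:
    """Resolve an open flag with a controlled term.

    The term's polarity decides the final state (accepted/declined). The
    target entity's priority is recomputed as the maximum over its
    remaining open flags (0 if none).
    """
    vocab = vocabulary or ResolutionVocabulary.default()
    flag, t = _validate_resolution(store, flag_id, term, vocab)
    state = "accepted" if t.polarity == "accept" else "declined"
    with store.transaction():
        store.close_flag(flag_id, state=state, term=term, actor=actor,
                         action="flag_resolved", comment=comment)
        if not flag.unmatched:
            store.recompute_entity_priority(flag.target_entity_id, actor)
        return store.get_flag(flag_id)


def resolve_flags_bulk(
    store,
    flag_ids: Sequence[int],
    term: str,
    actor: str,
    comment: str = "",
    vocabulary: Optional[ResolutionVocabulary] = None,
) -> List[Flag]:
    """Resolve several flags with one term, all-or-nothing.

    Every flag is validated (open, term applicable) before anything is
    written; one bad flag rejects the whole batch and leaves the store
    unchanged. An empty batch is a no-op and emits no events.
    """
    vocab = vocabulary or ResolutionVocabulary.default()
    validated = [_validate_resolution(store, fid, term, vocab) for fid in flag_ids]
    resolved: List[Flag] = []
    with store.transaction():
        for flag, t in validated:
            state = "accepted" if t.polarity == "accept" else "declined"
            store.close_flag(flag.flag_id, state=state, term=term, actor=actor,
                             action="flag_resolved", comment=comment)
            if not flag.unmatched:
                store.recompute_entity_priority(flag.target_entity_id, actor)
            resolved.append(store.get_flag(flag.flag_id))
    return resolved


def set_verify(store, entity_ids: Iterable[str], value: bool, actor: str) -> int:
    """Mark/unmark entities for the experimental verification pipeline.

    Returns the number of entities whose marker actually changed (setting
    the same value twice is an idempotent no-op). Unknown ids raise.
    """
    ids = list(entity_ids)
    entities = []
    for eid in ids:
        e = store.get_entity(eid)
        if e is None:
            raise EntityNotFoundError(f"unknown entity id {eid!r}")
        entities.append(e)
    changed = 0
    with store.transaction():
        for e in entities:
            if e.verify != bool(value):
                store.set_entity_verify(e.entity_id, bool(value), actor)
                changed += 1
    return changed


def list_verify(store):
    """Entities currently selected for verification, in genomic order."""
    return store.verify_entities()
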