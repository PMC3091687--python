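"""Conflict detection between incoming evidence and stored annotation.

Comparisons are purely coordinate- and description-level (no sequence is
ever touched). Each detected disagreement maps to a *flag key*
``(target, category, source)``; keys already open are *retriggered*
rather than duplicated, and open engine flags of a source whose conflict
is not seen again in the next complete update are closed automatically.

Categories and default priorities (all configurable per rule):

==================== ======== ==============================================
category             priority meaning
==================== ======== ==============================================
reference_missing    4        evidence refers to an id absent from the store
splice_mismatch      3        exon evidence matches no annotated exon
novel_locus          3        evidence in an annotation-free region
boundary_mismatch    2        transcript evidence shares no annotated endpoint
description_mismatch 1        normalised note differs from stored description
==================== ======== ==============================================
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .errors import ConfigError, InvariantError
from .ingest.base import SourceFeature
from .ingest.flagfile import FlagRequest
from .model import AnnotationEntity, GenomicInterval, interval_overlap
from .workflow import AUTO_RESOLVED_TERM, FlagKey, open_flag

__all__ = [
    "ConflictRule",
    "Conflict",
    "ConflictReport",
    "DEFAULT_RULES",
    "EXON_TYPES",
    "default_rules",
    "compare_positional",
    "compare_referential",
    "run_update_cycle",
    "novel_region_id",
    "normalise_text",
]

log = logging.getLogger(__name__)

#: Feature types treated as exon-level evidence (splice-site comparison).
EXON_TYPES = {"exon", "cds", "coding_exon"}


@dataclass(frozen=True)
class ConflictRule:
    """Detection rule for one category: the priority flags open at,
    rule-specific parameters (``tolerance`` in bases for coordinate
    categories), and whether the engine may auto-resolve its flags."""

    category: str
    priority: int
    parameters: Tuple[Tuple[str, int], ...] = ()
    auto_resolvable: bool = True

    def __post_init__(self):
        if not (0 <= self.priority <= 5):
            raise InvariantError(f"rule priority must be 0-5, got {self.priority}")

    @property
    def params(self) -> Dict[str, int]:
        return dict(self.parameters)

    def tolerance(self) -> int:
        return self.params.get("tolerance", 0)


def default_rules(tolerance: int = 0) -> Dict[str, ConflictRule]:
    """The default rule set; boundary tolerance is 0 bases unless raised."""
    tol = (("tolerance", tolerance),)
    return {
        "reference_missing": ConflictRule("reference_missing", 4),
        "splice_mismatch": ConflictRule("splice_mismatch", 3, tol),
        "novel_locus": ConflictRule("novel_locus", 3),
        "boundary_mismatch": ConflictRule("boundary_mismatch", 2, tol),
        "description_mismatch": ConflictRule("description_mismatch", 1),
    }


DEFAULT_RULES = default_rules()


@dataclass(frozen=True)
class Conflict:
    category: str
    target_id: str
    detail: str


@dataclass
class ConflictReport:
    """Outcome of one update cycle for one source."""

    source_name: str
    cycle_id: int
    opened: List[FlagKey] = field(default_factory=list)
    retriggered: List[FlagKey] = field(default_factory=list)
    auto_resolved: List[FlagKey] = field(default_factory=list)
    entities_touched: int = 0
    failures: List[Dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "source_name": self.source_name,
            "cycle_id": self.cycle_id,
            "opened": [list(k) for k in self.opened],
            "retriggered": [list(k) for k in self.retriggered],
            "auto_resolved": [list(k) for k in self.auto_resolved],
            "entities_touched": self.entities_touched,
            "failures": self.failures,
        }, indent=2)


def novel_region_id(interval: GenomicInterval) -> str:
    """Synthetic flag-target id for evidence in an annotation-free region."""
    return f"novel:{interval.chrom}:{interval.start}-{interval.end}"


def normalise_text(text: str) -> str:
    """Case-fold and collapse whitespace before exact comparison."""
    return " ".join(text.split()).casefold()


def _best_by_overlap(candidates: Sequence[AnnotationEntity],
                     interval: GenomicInterval) -> AnnotationEntity:
    # maximal overlap length, ties broken by entity_id (lexicographic)
    return min(candidates,
               key=lambda e: (-interval_overlap(e.interval, interval), e.entity_id))


def _endpoints_match(a: GenomicInterval, b: GenomicInterval, tol: int) -> Tuple[bool, bool]:
    return (abs(a.start - b.start) <= tol, abs(a.end - b.end) <= tol)


def _exon_matches_any(feature: SourceFeature,
                      transcripts: Sequence[AnnotationEntity],
                      store, tol: int) -> bool:
    for t in transcripts:
        for sub in store.children(t.entity_id):
            s_ok, e_ok = _endpoints_match(feature.interval, sub.interval, tol)
            if s_ok and e_ok:
                return True
    return False


def compare_positional(feature: SourceFeature, store,
                       rules: Optional[Dict[str, ConflictRule]] = None) -> List[Conflict]:
    """Compare purely positional evidence against the stored annotation.

    * no overlapping locus (strand-blind) -> ``novel_locus``;
    * exon-typed feature whose boundaries match no stored subfeature of
      any overlapping transcript (both endpoints within tolerance) ->
      ``splice_mismatch`` against the best-overlapping transcript;
    * other feature sharing no endpoint with any overlapping transcript ->
      ``boundary_mismatch`` against the best-overlapping transcript;
    * an exact (within-tolerance) match -> no conflict.
    """
    rules = rules or DEFAULT_RULES
    iv = feature.interval
    loci = store.overlapping(iv, level="locus")
    if not loci:
        return [Conflict("novel_locus", novel_region_id(iv),
                         f"{feature.feature_id} at {iv} overlaps no annotated locus")]
    transcripts = store.overlapping(iv, level="transcript")
    if not transcripts:
        # inside a locus but outside every transcript span: report against
        # the best-overlapping locus (novel_locus is reserved for fully
        # annotation-free regions, which this is not)
        best = _best_by_overlap(loci, iv)
        return [Conflict("boundary_mismatch", best.entity_id,
                         f"{feature.feature_id} at {iv} lies in locus"
                         f" {best.entity_id} but within no transcript span")]
    if feature.type.lower() in EXON_TYPES:
        tol = rules["splice_mismatch"].tolerance()
        if _exon_matches_any(feature, transcripts, store, tol):
            return []
        best = _best_by_overlap(transcripts, iv)
        return [Conflict("splice_mismatch", best.entity_id,
                         f"exon evidence {feature.feature_id} at {iv} matches no"
                         f" annotated exon boundary of {best.entity_id}")]
    tol = rules["boundary_mismatch"].tolerance()
    for t in transcripts:
        s_ok, e_ok = _endpoints_match(iv, t.interval, tol)
        if s_ok or e_ok:
            return []
    best = _best_by_overlap(transcripts, iv)
    return [Conflict("boundary_mismatch", best.entity_id,
                     f"{feature.feature_id} at {iv} shares no endpoint with"
                     f" {best.entity_id} ({best.interval})")]


def compare_referential(feature: SourceFeature, store,
                        rules: Optional[Dict[str, ConflictRule]] = None) -> List[Conflict]:
    """Compare evidence that refers to a stored entity by id.

    ``reference_missing`` if the id is absent; otherwise the coordinate
    check is pinned to the referenced entity, and the note (if any) is
    compared to the stored description after normalisation (case-fold,
    collapsed whitespace).
    """
    rules = rules or DEFAULT_RULES
    target = store.get_entity(feature.target_entity_id)
    if target is None:
        return [Conflict("reference_missing", feature.target_entity_id,
                         f"{feature.feature_id} refers to unknown id"
                         f" {feature.target_entity_id!r}")]
    conflicts: List[Conflict] = []
    iv = feature.interval
    if feature.type.lower() in EXON_TYPES:
        tol = rules["splice_mismatch"].tolerance()
        subs = store.children(target.entity_id)
        if not any(all(_endpoints_match(iv, s.interval, tol)) for s in subs):
            conflicts.append(Conflict(
                "splice_mismatch", target.entity_id,
                f"exon evidence {feature.feature_id} at {iv} matches no exon of"
                f" referenced {target.entity_id}"))
    else:
        tol = rules["boundary_mismatch"].tolerance()
        s_ok, e_ok = _endpoints_match(iv, target.interval, tol)
        if iv.chrom != target.interval.chrom or not (s_ok or e_ok):
            conflicts.append(Conflict(
                "boundary_mismatch", target.entity_id,
                f"{feature.feature_id} at {iv} shares no endpoint with referenced"
                f" {target.entity_id} ({target.interval})"))
    if feature.note and normalise_text(feature.note) != normalise_text(target.description):
        conflicts.append(Conflict(
            "description_mismatch", target.entity_id,
            f"{feature.feature_id} note differs from stored description"
            f" of {target.entity_id}"))
    return conflicts


def _dedup_batch(features: Sequence[SourceFeature]) -> List[SourceFeature]:
    seen, unique = set(), []
    for f in features:
        key = (f.feature_id, f.interval.chrom, f.interval.start,
               f.interval.end, f.type)
        if key in seen:
            log.warning("duplicate feature %r in batch; keeping first occurrence",
                        f.feature_id)
            continue
        seen.add(key)
        unique.append(f)
    return unique


def run_update_cycle(store, source_name: str, features: Sequence[SourceFeature],
                     rules: Optional[Dict[str, ConflictRule]] = None,
                     failures: Sequence[Dict] = (),
                     actor: str = "system") -> ConflictReport:
    """One atomic update cycle for one source.

    Every feature is compared (positional or referential); each conflict
    maps to a flag key. New keys open flags at the rule's priority (which
    also raises the target entity's priority, never lowering it); keys
    already open are marked retriggered. Open engine flags of this source
    whose key was neither opened nor retriggered — and whose category's
    rule permits it — are closed with the reserved term ``auto_resolved``.
    Auto-resolution is skipped entirely when ``failures`` is non-empty:
    partial data must never masquerade as a resolved conflict.
    """
    rules = rules or DEFAULT_RULES
    if not store.source_registered(source_name):
        raise ConfigError(f"source {source_name!r} is not registered with the store")
    for f in features:
        if f.source_name != source_name:
            raise ConfigError(
                f"feature {f.feature_id!r} belongs to source {f.source_name!r},"
                f" not {source_name!r}")
    batch = _dedup_batch(features)
    failures = list(failures)

    with store.transaction():
        cycle_id = store.next_cycle_id(source_name)
        report = ConflictReport(source_name=source_name, cycle_id=cycle_id,
                                failures=failures)
        seen_keys: Dict[FlagKey, Conflict] = {}
        for f in batch:
            if f.target_entity_id:
                conflicts = compare_referential(f, store, rules)
            else:
                conflicts = compare_positional(f, store, rules)
            for c in conflicts:
                key: FlagKey = (c.target_id, c.category, source_name)
                if key in seen_keys:
                    continue
                seen_keys[key] = c
                rule = rules.get(c.category)
                priority = rule.priority if rule else 1
                existing = store.find_open_flag(key)
                if existing is not None:
                    report.retriggered.append(key)
                else:
                    open_flag(store,
                              FlagRequest(c.target_id, c.category, priority,
                                          source_name, c.detail),
                              actor=actor, auto_resolvable=True)
                    report.opened.append(key)
        if not failures:
            for flag in store.open_flags(source_name=source_name, auto_resolvable=True):
                if flag.key in seen_keys:
                    continue
                rule = rules.get(flag.category)
                if rule is not None and not rule.auto_resolvable:
                    continue
                store.close_flag(flag.flag_id, state="auto_resolved",
                                 term=AUTO_RESOLVED_TERM, actor=actor,
                                 action="flag_auto_resolved",
                                 comment=f"not re-triggered by {source_name}"
                                         f" cycle {cycle_id}")
                # priorities are monotone within a cycle: auto-resolution
                # closes the flag but leaves the entity's urgency for a
                # curator (or manual resolution) to lower
                report.auto_resolved.append(flag.key)
        touched = {key[0] for key in (report.opened + report.retriggered
                                      + report.auto_resolved)
                   if store.get_entity(key[0]) is not None}
        report.entities_touched = len(touched)
    return report
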