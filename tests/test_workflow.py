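import random

import pytest

from curatrack.errors import (
    EntityNotFoundError,
    InvariantError,
    StateError,
    VocabularyError,
)
from curatrack.ingest.flagfile import FlagRequest, read_flag_file
from curatrack.model import AnnotationEntity, GenomicInterval
from curatrack.store import AnnotationStore
from curatrack.workflow import (
    ResolutionTerm,
    ResolutionVocabulary,
    list_verify,
    open_flag,
    resolve_flag,
    resolve_flags_bulk,
    set_verify,
)


@pytest.fixture
def store():
    s = AnnotationStore()
    iv = lambda a, b: GenomicInterval("chr1", a, b, "+")
    s.upsert_entity(AnnotationEntity("L1", "locus", iv(1000, 9000)))
    s.upsert_entity(AnnotationEntity("T1", "transcript", iv(1000, 5000),
                                     parent_id="L1"))
    s.upsert_entity(AnnotationEntity("T2", "transcript", iv(6000, 9000),
                                     parent_id="L1"))
    yield s
    s.close()


def _req(target="T1", category="splice", priority=3, source="analysisX"):
    return FlagRequest(target, category, priority, source, "")


class TestOpenFlag:
    def test_new_flag_raises_entity_priority(self, store):
        flag = open_flag(store, _req(), "sys")
        assert flag.state == "open" and flag.priority == 3
        assert store.get_entity("T1").priority == 3

    def test_reopen_same_key_escalates_instead_of_duplicating(self, store):
        first = open_flag(store, _req(priority=3), "sys")
        second = open_flag(store, _req(priority=5), "sys")
        assert second.flag_id == first.flag_id
        assert second.priority == 5
        assert store.get_entity("T1").priority == 5
        assert len(store.open_flags()) == 1

    def test_reopen_with_lower_priority_is_noop(self, store):
        open_flag(store, _req(priority=4), "sys")
        n_events = len(store.history())
        flag = open_flag(store, _req(priority=2), "sys")
        assert flag.priority == 4
        assert len(store.history()) == n_events

    def test_flag_file_batch(self, store):
        header = "target_entity_id\tcategory\tpriority\tsource_name\tcomment"
        text = (f"{header}\n"
                "T1\tsplice\t3\tpipe\tweak donor\n"
                "T2\tsplice\t2\tpipe\t\n"
                "GHOST\tsplice\t1\tpipe\tid not imported yet\n")
        requests = read_flag_file(text)
        events_before = len(store.history())
        flags = [open_flag(store, r, "sys") for r in requests]
        assert len(flags) == 3
        assert flags[2].unmatched
        assert len(store.history()) >= events_before + 3


class TestResolveFlag:
    def test_accept_with_named_splice_term(self, store):
        flag = open_flag(store, _req(category="splice_mismatch"), "sys")
        resolved = resolve_flag(store, flag.flag_id,
                                "annotated_splicing_corrected", "annotator1",
                                comment="splice sites updated")
        assert resolved.state == "accepted"
        assert resolved.resolution_term == "annotated_splicing_corrected"
        assert resolved.resolved_by == "annotator1"

    def test_decline_polarity(self, store):
        flag = open_flag(store, _req(category="splice_mismatch"), "sys")
        resolved = resolve_flag(store, flag.flag_id, "splice_suggestion_rejected",
                                "annotator1")
        assert resolved.state == "declined"

    def test_term_of_wrong_category_lists_applicable(self, store):
        flag = open_flag(store, _req(category="novel_locus", target="T2"), "sys")
        with pytest.raises(VocabularyError) as exc:
            resolve_flag(store, flag.flag_id, "annotated_splicing_corrected", "a1")
        assert "new_locus_annotated" in exc.value.applicable

    def test_double_resolution_is_state_error(self, store):
        flag = open_flag(store, _req(category="splice_mismatch"), "sys")
        resolve_flag(store, flag.flag_id, "annotated_splicing_corrected", "a1")
        with pytest.raises(StateError):
            resolve_flag(store, flag.flag_id, "splice_suggestion_rejected", "a1")

    def test_priority_returns_to_zero_with_no_open_flags(self, store):
        flag = open_flag(store, _req(), "sys")
        assert store.get_entity("T1").priority == 3
        resolve_flag(store, flag.flag_id, "annotation_updated", "a1")
        assert store.get_entity("T1").priority == 0

    def test_priority_recomputed_over_remaining_flags(self, store):
        low = open_flag(store, _req(category="splice", priority=2), "sys")
        open_flag(store, _req(category="boundary_mismatch", priority=5), "sys")
        assert store.get_entity("T1").priority == 5
        resolve_flag(store, low.flag_id, "annotation_updated", "a1")
        assert store.get_entity("T1").priority == 5


class TestBulkResolve:
    def test_combined_resolution_is_atomic(self, store):
        a = open_flag(store, _req(target="T1", category="splice_mismatch"), "sys")
        b = open_flag(store, _req(target="T2", category="splice_mismatch"), "sys")
        resolved = resolve_flags_bulk(store, [a.flag_id, b.flag_id],
                                      "annotated_splicing_corrected", "a1")
        assert [f.state for f in resolved] == ["accepted", "accepted"]

    def test_one_bad_flag_rejects_whole_batch(self, store):
        a = open_flag(store, _req(target="T1", category="splice_mismatch"), "sys")
        b = open_flag(store, _req(target="T2", category="splice_mismatch"), "sys")
        resolve_flag(store, b.flag_id, "annotated_splicing_corrected", "a1")
        flags_before = store.table_rows("flags")
        events_before = len(store.history())
        with pytest.raises(StateError):
            resolve_flags_bulk(store, [a.flag_id, b.flag_id],
                               "annotated_splicing_corrected", "a1")
        assert store.table_rows("flags") == flags_before
        assert len(store.history()) == events_before

    def test_empty_batch_is_noop(self, store):
        events_before = len(store.history())
        assert resolve_flags_bulk(store, [], "annotation_updated", "a1") == []
        assert len(store.history()) == events_before


class TestVerifySelection:
    def test_mark_and_list(self, store):
        assert set_verify(store, ["T1", "T2"], True, "a1") == 2
        assert [e.entity_id for e in list_verify(store)] == ["T1", "T2"]

    def test_idempotent_marking(self, store):
        set_verify(store, ["T1"], True, "a1")
        assert set_verify(store, ["T1"], True, "a1") == 0
        assert set_verify(store, ["T1"], False, "a1") == 1

    def test_unknown_id_rejected_without_partial_effect(self, store):
        with pytest.raises(EntityNotFoundError):
            set_verify(store, ["T1", "NOPE"], True, "a1")
        assert list_verify(store) == []

    def test_list_on_empty_store(self):
        with AnnotationStore() as empty:
            assert list_verify(empty) == []


class TestVocabulary:
    def test_default_includes_required_splice_accept_term(self):
        vocab = ResolutionVocabulary.default()
        term = vocab.lookup("annotated_splicing_corrected")
        assert term is not None and term.polarity == "accept"
        assert term.applies_to("splice_mismatch")

    def test_every_category_has_both_polarities(self):
        vocab = ResolutionVocabulary.default()
        categories = {c for t in vocab.terms for c in t.categories if c != "*"}
        for cat in categories:
            polarities = {t.polarity for t in vocab.applicable(cat)}
            assert polarities == {"accept", "decline"}

    def test_category_without_decline_rejected(self):
        with pytest.raises(InvariantError):
            ResolutionVocabulary((
                ResolutionTerm("fixed", "accept", ("splice_mismatch",)),))

    def test_reserved_term_rejected(self):
        with pytest.raises(InvariantError):
            ResolutionTerm("auto_resolved", "accept", ("*",))


class TestStateMachine:
    def test_only_legal_transitions_occur(self, store):
        """Random open/resolve sequences: every observed transition is
        open->accepted, open->declined or (none) -- and resolved flags are
        immutable."""
        rng = random.Random(99)
        vocab = ResolutionVocabulary.default()
        states = {}
        for _ in range(150):
            action = rng.random()
            if action < 0.5:
                req = _req(target=rng.choice(["T1", "T2"]),
                           category=rng.choice(["splice_mismatch", "novel_locus"]),
                           priority=rng.randint(1, 5))
                flag = open_flag(store, req, "sys")
                prev = states.get(flag.flag_id)
                assert prev in (None, "open")
                states[flag.flag_id] = "open"
            else:
                open_now = store.open_flags()
                if not open_now:
                    continue
                flag = rng.choice(open_now)
                term = rng.choice(vocab.applicable(flag.category))
                resolved = resolve_flag(store, flag.flag_id, term.term, "a1",
                                        vocabulary=vocab)
                assert states[flag.flag_id] == "open"
                assert resolved.state in ("accepted", "declined")
                states[flag.flag_id] = resolved.state
        # store-wide audit: one open flag per key, resolved flags carry terms
        assert store.audit_flags() == []
        for f in store.all_flags():
            if f.state != "open":
                assert f.resolution_term
                with pytest.raises(StateError):
                    resolve_flag(store, f.flag_id, "annotation_updated", "a1")
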