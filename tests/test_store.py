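import json
import random

import pytest

from helpers import brute_force_find, random_query, random_store

from curatrack.errors import (
    EntityNotFoundError,
    HierarchyError,
    InvariantError,
    QueryError,
)
from curatrack.ingest.flagfile import FlagRequest
from curatrack.model import AnnotationEntity, GenomicInterval
from curatrack.store import AnnotationStore
from curatrack.workflow import open_flag


def _locus(eid="L1", start=1000, end=9000, chrom="chr1", strand="+"):
    return AnnotationEntity(eid, "locus", GenomicInterval(chrom, start, end, strand))


def _transcript(eid="T1", parent="L1", start=1000, end=5000, chrom="chr1", strand="+"):
    return AnnotationEntity(eid, "transcript",
                            GenomicInterval(chrom, start, end, strand), parent_id=parent)


@pytest.fixture
def store():
    with AnnotationStore() as s:
        yield s


class TestUpsert:
    def test_insert_emits_created_and_forces_new_status(self, store):
        store.upsert_entity(_locus(), actor="alice")
        store.upsert_entity(_transcript(), actor="alice")
        events = store.history()
        assert [e.action for e in events] == ["created", "created"]
        assert store.get_entity("T1").status == "new"

    def test_identical_reupsert_is_silent(self, store):
        store.upsert_entity(_locus())
        store.upsert_entity(_transcript())
        n = len(store.history())
        store.upsert_entity(_transcript())
        assert len(store.history()) == n
        assert store.get_entity("T1").status == "new"

    def test_coordinate_change_yields_one_event_and_updated_status(self, store):
        store.upsert_entity(_locus())
        store.upsert_entity(_transcript())
        n = len(store.history())
        store.upsert_entity(_transcript(end=5600), actor="bob")
        events = store.history()
        assert len(events) == n + 1
        last = events[-1]
        assert last.action == "updated" and last.actor == "bob"
        assert json.loads(last.before) == {"interval": "chr1:1000-5000(+)"}
        assert json.loads(last.after) == {"interval": "chr1:1000-5600(+)"}
        assert store.get_entity("T1").status == "updated"

    def test_each_changed_field_yields_one_event(self, store):
        store.upsert_entity(_locus())
        store.upsert_entity(_transcript())
        n = len(store.history())
        changed = AnnotationEntity("T1", "transcript",
                                   GenomicInterval("chr1", 1000, 5600, "+"),
                                   parent_id="L1", biotype="lincRNA",
                                   description="revised")
        store.upsert_entity(changed)
        assert len(store.history()) == n + 3  # interval, biotype, description

    def test_unknown_parent_rejected(self, store):
        with pytest.raises(HierarchyError):
            store.upsert_entity(_transcript(parent="NOPE"))

    def test_child_outside_parent_rejected(self, store):
        store.upsert_entity(_locus())
        with pytest.raises(InvariantError):
            store.upsert_entity(_transcript(end=9500))

    def test_strand_mismatch_rejected(self, store):
        store.upsert_entity(_locus())
        with pytest.raises(InvariantError):
            store.upsert_entity(_transcript(strand="-"))

    def test_wrong_parent_level_rejected(self, store):
        store.upsert_entity(_locus())
        sub = AnnotationEntity("S1", "subfeature",
                               GenomicInterval("chr1", 1000, 1100, "+"),
                               parent_id="L1")
        with pytest.raises(HierarchyError):
            store.upsert_entity(sub)

    def test_failed_upsert_rolls_back(self, store):
        store.upsert_entity(_locus())
        with pytest.raises(InvariantError):
            store.upsert_entity(_transcript(end=9500))
        assert store.entity_count() == 1
        assert len(store.history()) == 1


class TestFindEntities:
    def _populate(self, store):
        store.upsert_entity(_locus("L1", 1000, 9000))
        store.upsert_entity(_locus("L2", 20000, 30000))
        store.upsert_entity(_locus("L3", 500, 4000, chrom="chr3"))
        store.upsert_entity(_transcript("T1", "L1", 1000, 5000))
        store.upsert_entity(_transcript("T2", "L3", 600, 3000, chrom="chr3"))

    def test_empty_query_returns_all_sorted(self, store):
        self._populate(store)
        got = store.find_entities()
        assert [e.entity_id for e in got] == ["L1", "T1", "L2", "L3", "T2"]

    def test_region_and_flag_category_conjunction(self, store):
        self._populate(store)
        open_flag(store, FlagRequest("T2", "splice", 3, "pipeline", ""), "sys")
        open_flag(store, FlagRequest("T1", "splice", 3, "pipeline", ""), "sys")
        chr3 = GenomicInterval("chr3", 1, 5_000_000)
        got = store.find_entities(region=chr3, flag_category="splice")
        assert [e.entity_id for e in got] == ["T2"]

    def test_min_priority_without_flags_is_empty(self, store):
        self._populate(store)
        assert store.find_entities(min_priority=5) == []

    def test_keyword_matches_id_and_description_case_insensitive(self, store):
        store.upsert_entity(AnnotationEntity(
            "GENE-A", "locus", GenomicInterval("chr1", 1, 10),
            description="putative Kinase"))
        assert [e.entity_id for e in store.find_entities(keyword="gene-a")] == ["GENE-A"]
        assert [e.entity_id for e in store.find_entities(keyword="KINASE")] == ["GENE-A"]
        assert store.find_entities(keyword="phosphatase") == []

    def test_malformed_queries_rejected(self, store):
        with pytest.raises(QueryError):
            store.find_entities(region="chr1:1-10")  # not a GenomicInterval
        with pytest.raises(QueryError):
            store.find_entities(level="gene")
        with pytest.raises(QueryError):
            store.find_entities(same_strand=True)  # needs a region

    def test_same_strand_filter(self, store):
        store.upsert_entity(_locus("P", 100, 200, strand="+"))
        store.upsert_entity(_locus("M", 100, 200, strand="-"))
        region = GenomicInterval("chr1", 1, 1000, "+")
        assert [e.entity_id for e in store.find_entities(region=region)] == ["M", "P"]
        got = store.find_entities(region=region, same_strand=True)
        assert [e.entity_id for e in got] == ["P"]

    def test_matches_brute_force_scan_on_random_stores(self):
        rng = random.Random(2024)
        for _ in range(12):
            with random_store(rng, max_loci=40) as store:
                for _ in range(6):
                    query = random_query(rng)
                    fast = store.find_entities(**query)
                    slow = brute_force_find(store, **query)
                    assert fast == slow


class TestHistory:
    def test_append_only_prefix_property(self, store):
        store.upsert_entity(_locus())
        snapshot = store.history()
        store.upsert_entity(_transcript())
        open_flag(store, FlagRequest("T1", "splice", 2, "src", ""), "sys")
        store.set_status("T1", "rejected", "alice")
        current = store.history()
        assert current[: len(snapshot)] == snapshot
        ids = [e.event_id for e in current]
        assert ids == sorted(ids) and len(set(ids)) == len(ids)

    def test_comment_added(self, store):
        store.upsert_entity(_locus())
        store.add_comment("L1", "looks truncated at the 5' end", "alice")
        last = store.history("L1")[-1]
        assert last.action == "comment_added"
        assert last.comment == "looks truncated at the 5' end"


class TestFlagsPlumbing:
    def test_unmatched_flag_attaches_on_insert(self, store):
        flag = open_flag(store, FlagRequest("FUTURE", "splice", 4, "src", ""), "sys")
        assert flag.unmatched
        store.upsert_entity(_locus("FUTURE", 100, 200))
        assert not store.get_flag(flag.flag_id).unmatched
        assert store.get_entity("FUTURE").priority == 4

    def test_status_vocabulary_enforced(self, store):
        store.upsert_entity(_locus())
        with pytest.raises(InvariantError):
            store.set_status("L1", "nonsense_tag", "alice")
        with pytest.raises(EntityNotFoundError):
            store.set_status("NOPE", "updated", "alice")

    def test_table_rows_guard(self, store):
        with pytest.raises(QueryError):
            store.table_rows("sqlite_master")


def test_hierarchy_audit_clean_on_generated_annotation(loaded_store):
    assert loaded_store.audit_hierarchy() == []
    assert loaded_store.audit_flags() == []
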