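import pytest

from curatrack.conflicts import (
    compare_positional,
    compare_referential,
    default_rules,
    normalise_text,
    run_update_cycle,
)
from curatrack.errors import ConfigError
from curatrack.ingest import SourceConfig, SourceFeature, load_entities
from curatrack.ingest.flagfile import FlagRequest
from curatrack.model import AnnotationEntity, GenomicInterval
from curatrack.store import AnnotationStore
from curatrack.synthetic import generate_evidence, repair_evidence
from curatrack.workflow import open_flag


def _feature(start, end, fid="f1", chrom="chr1", ftype="exon", source="src",
             note="", target=""):
    return SourceFeature(source_name=source, feature_id=fid,
                         interval=GenomicInterval(chrom, start, end),
                         type=ftype, note=note, target_entity_id=target)


@pytest.fixture
def annotated_store():
    """L1 (chr1:1000-5000) with T1 (1000-3000, exons 1000-1200 / 2000-2200 /
    2800-3000) and T2 (4000-5000, exon 4000-5000)."""
    store = AnnotationStore()
    iv = lambda s, e: GenomicInterval("chr1", s, e, "+")
    store.upsert_entity(AnnotationEntity("L1", "locus", iv(1000, 5000)))
    store.upsert_entity(AnnotationEntity("T1", "transcript", iv(1000, 3000),
                                         parent_id="L1",
                                         description="Protein coding model one"))
    for i, (s, e) in enumerate([(1000, 1200), (2000, 2200), (2800, 3000)]):
        store.upsert_entity(AnnotationEntity(f"T1.E{i+1}", "subfeature", iv(s, e),
                                             parent_id="T1", biotype="exon"))
    store.upsert_entity(AnnotationEntity("T2", "transcript", iv(4000, 5000),
                                         parent_id="L1"))
    store.upsert_entity(AnnotationEntity("T2.E1", "subfeature", iv(4000, 5000),
                                         parent_id="T2", biotype="exon"))
    store.register_source(SourceConfig("src", "das"))
    yield store
    store.close()


class TestComparePositional:
    def test_exact_exon_match_is_clean(self, annotated_store):
        assert compare_positional(_feature(2000, 2200), annotated_store) == []

    def test_annotation_free_region_is_novel_locus(self, annotated_store):
        (c,) = compare_positional(_feature(100_000, 100_500, ftype="transcript"),
                                  annotated_store)
        assert c.category == "novel_locus"
        assert c.target_id == "novel:chr1:100000-100500"

    def test_shifted_exon_is_splice_mismatch_naming_transcript(self, annotated_store):
        (c,) = compare_positional(_feature(2007, 2207), annotated_store)
        assert c.category == "splice_mismatch"
        assert c.target_id == "T1"

    def test_tolerance_absorbs_small_shift(self, annotated_store):
        rules = default_rules(tolerance=10)
        assert compare_positional(_feature(2007, 2207), annotated_store, rules) == []
        # but not a larger one
        assert compare_positional(_feature(2020, 2220), annotated_store, rules)

    def test_exon_matching_any_overlapping_isoform_is_clean(self, annotated_store):
        # matches T2's exon exactly; T1 does not overlap it at all
        assert compare_positional(_feature(4000, 5000), annotated_store) == []

    def test_transcript_sharing_one_endpoint_is_clean(self, annotated_store):
        f = _feature(1000, 3555, ftype="transcript")
        assert compare_positional(f, annotated_store) == []

    def test_transcript_sharing_no_endpoint_is_boundary_mismatch(self, annotated_store):
        (c,) = compare_positional(_feature(1100, 3100, ftype="transcript"),
                                  annotated_store)
        assert c.category == "boundary_mismatch"
        assert c.target_id == "T1"

    def test_feature_in_locus_but_outside_transcripts(self, annotated_store):
        (c,) = compare_positional(_feature(3300, 3400), annotated_store)
        assert c.category == "boundary_mismatch"
        assert c.target_id == "L1"


class TestCompareReferential:
    def test_identical_reference_is_clean(self, annotated_store):
        f = _feature(1000, 3000, ftype="transcript", target="T1",
                     note="Protein coding model one")
        assert compare_referential(f, annotated_store) == []

    def test_missing_reference(self, annotated_store):
        (c,) = compare_referential(
            _feature(1000, 3000, ftype="transcript", target="T_GONE"),
            annotated_store)
        assert (c.category, c.target_id) == ("reference_missing", "T_GONE")

    def test_case_difference_absorbed_by_normalisation(self, annotated_store):
        f = _feature(1000, 3000, ftype="transcript", target="T1",
                     note="PROTEIN   coding\tmodel one")
        assert compare_referential(f, annotated_store) == []

    def test_real_description_difference_flagged(self, annotated_store):
        f = _feature(1000, 3000, ftype="transcript", target="T1",
                     note="actually a pseudogene")
        (c,) = compare_referential(f, annotated_store)
        assert (c.category, c.target_id) == ("description_mismatch", "T1")

    def test_coordinate_check_pinned_to_referenced_entity(self, annotated_store):
        # coordinates identical to T2, but the reference names T1
        f = _feature(4000, 5000, ftype="transcript", target="T1")
        (c,) = compare_referential(f, annotated_store)
        assert (c.category, c.target_id) == ("boundary_mismatch", "T1")


def test_normalise_text():
    assert normalise_text("  A  B\t\nc ") == "a b c"


class TestUpdateCycle:
    def test_unknown_source_is_config_error(self, annotated_store):
        with pytest.raises(ConfigError):
            run_update_cycle(annotated_store, "never_registered", [])

    def test_feature_from_wrong_source_rejected(self, annotated_store):
        with pytest.raises(ConfigError):
            run_update_cycle(annotated_store, "src",
                             [_feature(1, 10, source="other")])

    def test_duplicate_features_deduplicated(self, annotated_store):
        f = _feature(100_000, 100_100, ftype="transcript")
        report = run_update_cycle(annotated_store, "src", [f, f])
        assert len(report.opened) == 1

    def test_cycle_ids_increase_per_source(self, annotated_store):
        r1 = run_update_cycle(annotated_store, "src", [])
        r2 = run_update_cycle(annotated_store, "src", [])
        assert (r1.cycle_id, r2.cycle_id) == (1, 2)

    def test_no_conflict_cycle_auto_resolves_stale_flags(self, annotated_store):
        run_update_cycle(annotated_store, "src", [_feature(2007, 2207)])
        assert len(annotated_store.open_flags()) == 1
        report = run_update_cycle(annotated_store, "src", [_feature(2000, 2200)])
        assert report.opened == [] and len(report.auto_resolved) == 1
        flag = annotated_store.all_flags()[0]
        assert flag.state == "auto_resolved"
        assert flag.resolution_term == "auto_resolved"

    def test_partial_data_never_auto_resolves(self, annotated_store):
        run_update_cycle(annotated_store, "src", [_feature(2007, 2207)])
        failures = [{"window": ("chr1", 1, 10000), "error": "timeout"}]
        report = run_update_cycle(annotated_store, "src", [], failures=failures)
        assert report.auto_resolved == []
        assert len(annotated_store.open_flags()) == 1

    def test_manual_flags_never_auto_resolved(self, annotated_store):
        open_flag(annotated_store, FlagRequest("T1", "splice", 3, "src",
                                               "from a flag file"), "curator")
        report = run_update_cycle(annotated_store, "src", [])
        assert report.auto_resolved == []
        assert len(annotated_store.open_flags()) == 1

    def test_rule_with_auto_resolution_disabled(self, annotated_store):
        rules = default_rules()
        rules["splice_mismatch"] = rules["splice_mismatch"].__class__(
            "splice_mismatch", 3, (("tolerance", 0),), auto_resolvable=False)
        run_update_cycle(annotated_store, "src", [_feature(2007, 2207)], rules=rules)
        report = run_update_cycle(annotated_store, "src", [], rules=rules)
        assert report.auto_resolved == []

    def test_entity_priority_raised_to_rule_priority(self, annotated_store):
        run_update_cycle(annotated_store, "src", [_feature(2007, 2207)])
        assert annotated_store.get_entity("T1").priority == 3  # splice default

    def test_report_serialises_to_json(self, annotated_store):
        import json
        report = run_update_cycle(annotated_store, "src", [_feature(2007, 2207)])
        decoded = json.loads(report.to_json())
        assert decoded["opened"] == [["T1", "splice_mismatch", "src"]]
        assert decoded["cycle_id"] == 1


class TestInjectedFixtures:
    def test_opened_flags_equal_ground_truth_all_categories(
            self, loaded_store, small_evidence):
        report = run_update_cycle(loaded_store, small_evidence.source_name,
                                  small_evidence.features)
        assert sorted(report.opened) == sorted(small_evidence.ground_truth)
        categories = {key[1] for key in report.opened}
        assert categories == {"splice_mismatch", "boundary_mismatch",
                              "novel_locus", "description_mismatch",
                              "reference_missing"}

    def test_second_cycle_is_idempotent(self, loaded_store, small_evidence):
        run_update_cycle(loaded_store, small_evidence.source_name,
                         small_evidence.features)
        entities_before = loaded_store.table_rows("entities")
        flags_before = loaded_store.table_rows("flags")
        report = run_update_cycle(loaded_store, small_evidence.source_name,
                                  small_evidence.features)
        assert report.opened == [] and report.auto_resolved == []
        assert sorted(report.retriggered) == sorted(small_evidence.ground_truth)
        assert loaded_store.table_rows("entities") == entities_before
        assert loaded_store.table_rows("flags") == flags_before

    def test_repair_convergence(self, loaded_store, small_evidence):
        run_update_cycle(loaded_store, small_evidence.source_name,
                         small_evidence.features)
        repaired, reverted = repair_evidence(small_evidence, k=4, seed=2)
        report = run_update_cycle(loaded_store, small_evidence.source_name,
                                  repaired.features)
        assert sorted(report.auto_resolved) == sorted(reverted)
        remaining = {f.key for f in loaded_store.open_flags()}
        assert remaining == set(small_evidence.ground_truth) - set(reverted)

    def test_priorities_never_lowered_by_a_cycle(self, loaded_store, small_evidence):
        run_update_cycle(loaded_store, small_evidence.source_name,
                         small_evidence.features)
        before = {e.entity_id: e.priority for e in loaded_store.all_entities()}
        repaired, _ = repair_evidence(small_evidence, k=len(small_evidence.ground_truth))
        run_update_cycle(loaded_store, small_evidence.source_name, repaired.features)
        after = {e.entity_id: e.priority for e in loaded_store.all_entities()}
        assert all(after[eid] >= before[eid] for eid in before)
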