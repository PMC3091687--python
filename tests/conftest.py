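import pytest

from curatrack.ingest import SourceConfig, load_entities
from curatrack.store import AnnotationStore
from curatrack.synthetic import (
    PerturbationSpec,
    generate_annotation,
    generate_evidence,
)

#: A compact dataset exercising every perturbation kind.
SMALL_SPEC = PerturbationSpec(
    seed=11,
    n_loci=16,
    n_splice_shifts=3,
    n_boundary_shifts=2,
    n_novel_loci=2,
    n_description_edits=2,
    n_reference_deletions=1,
)


@pytest.fixture(scope="session")
def small_annotation():
    return generate_annotation(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_evidence(small_annotation):
    return generate_evidence(small_annotation, SMALL_SPEC)


@pytest.fixture
def loaded_store(small_annotation):
    """A fresh in-memory store holding the small reference annotation."""
    store = AnnotationStore()
    load_entities(store, small_annotation.entities)
    store.register_source(SourceConfig(SMALL_SPEC.source_name, "das"))
    yield store
    store.close()
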