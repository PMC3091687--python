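"""Deterministic synthetic-data generator.

Builds a reference annotation (non-overlapping gene loci with 2-4
transcript isoforms of 2-5 exons each, spread over two 5 Mb synthetic
chromosomes), an external-evidence view of it, and a *perturbed* copy of
that view with complete ground-truth conflict labels. Perturbation kinds
mirror the conflict categories:

* **splice shift** — one splice site of one exon moved by 1-20 bases;
* **boundary shift** — a transcript-level feature moved whole;
* **novel locus** — a feature dropped into an annotation-free gap;
* **description edit** — a referential feature's note text changed;
* **reference deletion** — a referential feature re-pointed at a
  retired (non-existent) annotation id.

Perturbation targets are disjoint transcripts and expected flag keys are
unique, so the expected outcome of an update cycle is unambiguous: at
boundary tolerance 0 the cycle must open *exactly* the ground-truth keys.
Expected targets for coordinate perturbations are assigned by the
generator's own brute-force maximal-overlap rule (ties by entity id),
with rejection sampling so a perturbed feature never collides with
another isoform's stored coordinates.

Everything is a pure function of the spec (seed included): the same spec
always yields byte-identical GFF3 and XML. No nucleotide sequence is
ever generated — the tracker works purely on coordinates and text.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .errors import GenerationError, InvariantError
from .ingest.base import SourceFeature
from .ingest.das import write_das
from .ingest.flagfile import FlagRequest, write_flag_file
from .ingest.gff3 import write_gff3
from .model import AnnotationEntity, GenomicInterval, interval_overlap
from .workflow import FlagKey

__all__ = [
    "PerturbationSpec",
    "Annotation",
    "Evidence",
    "Perturbation",
    "generate_annotation",
    "generate_evidence",
    "repair_evidence",
    "make_flag_file",
    "write_fixture_bundle",
]

_BIOTYPES = ("protein_coding", "lincRNA", "pseudogene", "antisense")

# placement geometry (bases)
_GAP_RANGE = (3000, 8000)          # inter-locus gap
_TSS_JITTER = 400                  # transcript start offset within a locus
_EXON_LEN = (80, 600)
_INTRON_LEN = (150, 1500)
_NOVEL_LEN = (400, 1500)
_NOVEL_MARGIN = 500                # clearance between a novel feature and any locus
_CHROM_TAIL = 5000                 # reserved tail at each chromosome end


@dataclass(frozen=True)
class PerturbationSpec:
    """Study conditions for one synthetic dataset.

    Counts are the number of perturbations of each kind;
    ``splice_shift_bases`` is the (min, max) magnitude of a splice-site or
    boundary shift — at least 1 base, since a 0-base shift would be
    undetectable at tolerance 0.
    """

    seed: int = 1
    n_loci: int = 100
    transcripts_per_locus: Tuple[int, int] = (2, 4)
    exons_per_transcript: Tuple[int, int] = (2, 5)
    splice_shift_bases: Tuple[int, int] = (1, 20)
    n_splice_shifts: int = 0
    n_boundary_shifts: int = 0
    n_novel_loci: int = 0
    n_description_edits: int = 0
    n_reference_deletions: int = 0
    chromosomes: Tuple[Tuple[str, int], ...] = (("chr1", 5_000_000),
                                                ("chr2", 5_000_000))
    source_name: str = "external_das"

    def __post_init__(self):
        for name in ("n_loci", "n_splice_shifts", "n_boundary_shifts",
                     "n_novel_loci", "n_description_edits", "n_reference_deletions"):
            if getattr(self, name) < 0:
                raise InvariantError(f"{name} must be >= 0")
        lo, hi = self.splice_shift_bases
        if lo < 1 or hi < lo:
            raise InvariantError("splice shift magnitudes must be >= 1 and ordered")
        for name in ("transcripts_per_locus", "exons_per_transcript"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise InvariantError(f"{name} range must be >= 1 and ordered")
        if len(self.chromosomes) < 2:
            raise InvariantError("need >= 2 chromosomes")


@dataclass
class Annotation:
    """A generated reference annotation plus its placement gaps."""

    spec: PerturbationSpec
    entities: List[AnnotationEntity]
    gaps: Dict[str, List[Tuple[int, int]]]

    @property
    def gff3(self) -> str:
        return write_gff3(self.entities)

    def transcripts(self) -> List[AnnotationEntity]:
        return [e for e in self.entities if e.level == "transcript"]

    def subfeatures_of(self, transcript_id: str) -> List[AnnotationEntity]:
        return [e for e in self.entities
                if e.level == "subfeature" and e.parent_id == transcript_id]


@dataclass(frozen=True)
class Perturbation:
    """One injected conflict: its kind, the flag key an update cycle must
    open for it, the evidence feature it lives in, and the original
    feature to restore on repair (None for inserted novel features)."""

    kind: str
    key: FlagKey
    feature_id: str
    original: Optional[SourceFeature]


@dataclass
class Evidence:
    """A (possibly perturbed) external-evidence view of an annotation."""

    source_name: str
    features: List[SourceFeature]
    perturbations: List[Perturbation] = field(default_factory=list)

    @property
    def ground_truth(self) -> List[FlagKey]:
        """Every flag key an update cycle must open — complete and minimal."""
        return [p.key for p in self.perturbations]

    def to_das_xml(self) -> str:
        return write_das(self.features)


def generate_annotation(spec: PerturbationSpec) -> Annotation:
    """Generate the reference annotation for a spec (deterministic)."""
    rng = random.Random(f"annotation-{spec.seed}")
    chrom_names = [c for c, _ in spec.chromosomes]
    sizes = dict(spec.chromosomes)
    cursors = {c: _CHROM_TAIL for c in chrom_names}
    gaps: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chrom_names}
    entities: List[AnnotationEntity] = []

    for i in range(spec.n_loci):
        chrom = chrom_names[i % len(chrom_names)]
        base = cursors[chrom] + rng.randint(*_GAP_RANGE)
        strand = rng.choice("+-")
        biotype = rng.choice(_BIOTYPES)
        locus_id = f"L{i:04d}"
        n_tr = rng.randint(*spec.transcripts_per_locus)
        transcripts: List[Tuple[str, List[Tuple[int, int]]]] = []
        for j in range(n_tr):
            tid = f"{locus_id}.T{j + 1}"
            pos = base + rng.randint(0, _TSS_JITTER)
            exons = []
            for _ in range(rng.randint(*spec.exons_per_transcript)):
                length = rng.randint(*_EXON_LEN)
                exons.append((pos, pos + length - 1))
                pos += length + rng.randint(*_INTRON_LEN)
            transcripts.append((tid, exons))
        locus_start = min(ex[0][0] for _, ex in transcripts)
        locus_end = max(ex[-1][1] for _, ex in transcripts)
        if locus_end > sizes[chrom] - _CHROM_TAIL:
            raise GenerationError(
                f"cannot place locus {i + 1}/{spec.n_loci}: chromosome {chrom}"
                f" ({sizes[chrom]} bp) is full at {locus_end}")
        if cursors[chrom] > _CHROM_TAIL:
            gaps[chrom].append((cursors[chrom] + 1, locus_start - 1))
        cursors[chrom] = locus_end

        entities.append(AnnotationEntity(
            entity_id=locus_id, level="locus",
            interval=GenomicInterval(chrom, locus_start, locus_end, strand),
            biotype=biotype,
            description=f"{biotype} locus {locus_id} with {n_tr} transcripts"))
        for tid, exons in transcripts:
            entities.append(AnnotationEntity(
                entity_id=tid, level="transcript",
                interval=GenomicInterval(chrom, exons[0][0], exons[-1][1], strand),
                parent_id=locus_id, biotype=biotype,
                description=f"{biotype} transcript {tid} with {len(exons)} exons"))
            for k, (s, e) in enumerate(exons):
                entities.append(AnnotationEntity(
                    entity_id=f"{tid}.E{k + 1}", level="subfeature",
                    interval=GenomicInterval(chrom, s, e, strand),
                    parent_id=tid, biotype="exon"))
    return Annotation(spec=spec, entities=entities, gaps=gaps)


def _baseline_features(annotation: Annotation) -> List[SourceFeature]:
    """The unperturbed evidence view: per transcript, one transcript-level
    feature, one exon feature per subfeature, and one referential feature
    carrying the stored description as its note."""
    source = annotation.spec.source_name
    features: List[SourceFeature] = []
    for t in annotation.transcripts():
        features.append(SourceFeature(
            source_name=source, feature_id=f"{t.entity_id}.t",
            interval=t.interval, type="transcript", label=t.entity_id))
        for k, sub in enumerate(annotation.subfeatures_of(t.entity_id)):
            features.append(SourceFeature(
                source_name=source, feature_id=f"{t.entity_id}.e{k + 1}",
                interval=sub.interval, type="exon", label=t.entity_id))
        features.append(SourceFeature(
            source_name=source, feature_id=f"{t.entity_id}.ref",
            interval=t.interval, type="annotation_ref", label=t.entity_id,
            note=t.description, target_entity_id=t.entity_id))
    return features


def _best_target(transcripts: Sequence[AnnotationEntity],
                 interval: GenomicInterval) -> Optional[AnnotationEntity]:
    """Brute-force maximal-overlap assignment, ties by entity id."""
    overlapping = [t for t in transcripts if interval_overlap(t.interval, interval) > 0]
    if not overlapping:
        return None
    return min(overlapping,
               key=lambda t: (-interval_overlap(t.interval, interval), t.entity_id))


def generate_evidence(annotation: Annotation,
                      spec: Optional[PerturbationSpec] = None) -> Evidence:
    """Perturb the evidence view per the spec; return it with ground truth.

    Raises :class:`GenerationError` when the requested perturbation counts
    exceed the available disjoint targets (transcripts, or inter-locus
    gaps for novel features).
    """
    spec = spec or annotation.spec
    rng = random.Random(f"evidence-{spec.seed}")
    source = spec.source_name
    features = _baseline_features(annotation)
    index_by_id = {f.feature_id: i for i, f in enumerate(features)}
    transcripts = annotation.transcripts()
    subfeature_pairs: Dict[str, set] = {}
    for t in transcripts:
        subfeature_pairs[t.entity_id] = {
            (s.interval.start, s.interval.end)
            for s in annotation.subfeatures_of(t.entity_id)}

    n_targets = (spec.n_splice_shifts + spec.n_boundary_shifts
                 + spec.n_description_edits + spec.n_reference_deletions)
    if n_targets > len(transcripts):
        raise GenerationError(
            f"{n_targets} perturbation targets requested but only"
            f" {len(transcripts)} transcripts available")
    chosen = rng.sample([t.entity_id for t in transcripts], n_targets)
    split = iter(chosen)
    splice_targets = [next(split) for _ in range(spec.n_splice_shifts)]
    boundary_targets = [next(split) for _ in range(spec.n_boundary_shifts)]
    desc_targets = [next(split) for _ in range(spec.n_description_edits)]
    refdel_targets = [next(split) for _ in range(spec.n_reference_deletions)]

    by_id = {t.entity_id: t for t in transcripts}
    perturbations: List[Perturbation] = []
    used_keys: set = set()

    def _overlapping_pairs(interval: GenomicInterval) -> set:
        pairs = set()
        for t in transcripts:
            if interval_overlap(t.interval, interval) > 0:
                pairs |= subfeature_pairs[t.entity_id]
        return pairs

    for tid in splice_targets:
        subs = annotation.subfeatures_of(tid)
        placed = False
        for _ in range(300):
            k = rng.randrange(len(subs))
            iv = subs[k].interval
            delta = rng.randint(*spec.splice_shift_bases) * rng.choice((1, -1))
            if rng.random() < 0.5:
                new = (iv.start + delta, iv.end)
            else:
                new = (iv.start, iv.end + delta)
            if new[0] < 1 or new[1] < new[0]:
                continue
            new_iv = GenomicInterval(iv.chrom, new[0], new[1], iv.strand)
            if (new_iv.start, new_iv.end) in _overlapping_pairs(new_iv):
                continue
            target = _best_target(transcripts, new_iv)
            if target is None:
                continue
            key: FlagKey = (target.entity_id, "splice_mismatch", source)
            if key in used_keys:
                continue
            fid = f"{tid}.e{k + 1}"
            original = features[index_by_id[fid]]
            features[index_by_id[fid]] = replace(original, interval=new_iv)
            perturbations.append(Perturbation("splice", key, fid, original))
            used_keys.add(key)
            placed = True
            break
        if not placed:
            raise GenerationError(f"could not place a splice shift on {tid}")

    for tid in boundary_targets:
        iv = by_id[tid].interval
        placed = False
        for _ in range(300):
            delta = rng.randint(*spec.splice_shift_bases) * rng.choice((1, -1))
            new_iv = GenomicInterval(iv.chrom, iv.start + delta, iv.end + delta,
                                     iv.strand)
            if new_iv.start < 1:
                continue
            shares_endpoint = any(
                interval_overlap(t.interval, new_iv) > 0
                and (t.interval.start == new_iv.start or t.interval.end == new_iv.end)
                for t in transcripts)
            if shares_endpoint:
                continue
            target = _best_target(transcripts, new_iv)
            if target is None:
                continue
            key = (target.entity_id, "boundary_mismatch", source)
            if key in used_keys:
                continue
            fid = f"{tid}.t"
            original = features[index_by_id[fid]]
            features[index_by_id[fid]] = replace(original, interval=new_iv)
            perturbations.append(Perturbation("boundary", key, fid, original))
            used_keys.add(key)
            placed = True
            break
        if not placed:
            raise GenerationError(f"could not place a boundary shift on {tid}")

    for tid in desc_targets:
        fid = f"{tid}.ref"
        original = features[index_by_id[fid]]
        features[index_by_id[fid]] = replace(
            original,
            note=original.note + " [coordinates disputed by external pipeline]")
        key = (tid, "description_mismatch", source)
        perturbations.append(Perturbation("description", key, fid, original))
        used_keys.add(key)

    for tid in refdel_targets:
        fid = f"{tid}.ref"
        original = features[index_by_id[fid]]
        retired = f"{tid}~retired"
        features[index_by_id[fid]] = replace(original, target_entity_id=retired)
        key = (retired, "reference_missing", source)
        perturbations.append(Perturbation("reference_deletion", key, fid, original))
        used_keys.add(key)

    usable_gaps = [
        (chrom, lo, hi)
        for chrom, gap_list in sorted(annotation.gaps.items())
        for lo, hi in gap_list
        if hi - lo + 1 >= _NOVEL_LEN[0] + 2 * _NOVEL_MARGIN
    ]
    if spec.n_novel_loci > len(usable_gaps):
        raise GenerationError(
            f"{spec.n_novel_loci} novel features requested but only"
            f" {len(usable_gaps)} usable inter-locus gaps")
    for i, (chrom, lo, hi) in enumerate(rng.sample(usable_gaps, spec.n_novel_loci)):
        room = hi - _NOVEL_MARGIN - (lo + _NOVEL_MARGIN) + 1
        length = rng.randint(_NOVEL_LEN[0], min(_NOVEL_LEN[1], room))
        start = rng.randint(lo + _NOVEL_MARGIN, hi - _NOVEL_MARGIN - length + 1)
        iv = GenomicInterval(chrom, start, start + length - 1, "+")
        fid = f"novel{i + 1}"
        features.append(SourceFeature(
            source_name=source, feature_id=fid, interval=iv, type="transcript",
            label=fid, note="unannotated transcribed region"))
        key = (f"novel:{chrom}:{iv.start}-{iv.end}", "novel_locus", source)
        perturbations.append(Perturbation("novel", key, fid, None))
        used_keys.add(key)

    return Evidence(source_name=source, features=features,
                    perturbations=perturbations)


def repair_evidence(evidence: Evidence, k: int,
                    seed: int = 0) -> Tuple[Evidence, List[FlagKey]]:
    """Revert ``k`` uniformly chosen perturbations to reference state.

    Returns the repaired evidence (its ground truth shrinks accordingly)
    and the reverted flag keys — the exact set the next update cycle must
    auto-resolve.
    """
    if not 0 <= k <= len(evidence.perturbations):
        raise GenerationError(
            f"k={k} out of range 0..{len(evidence.perturbations)}")
    rng = random.Random(f"repair-{seed}")
    chosen_idx = set(rng.sample(range(len(evidence.perturbations)), k))
    chosen = [evidence.perturbations[i] for i in sorted(chosen_idx)]
    restore = {p.feature_id: p.original for p in chosen if p.original is not None}
    drop = {p.feature_id for p in chosen if p.original is None}
    features = [restore.get(f.feature_id, f) for f in evidence.features
                if f.feature_id not in drop]
    remaining = [p for i, p in enumerate(evidence.perturbations)
                 if i not in chosen_idx]
    repaired = Evidence(source_name=evidence.source_name, features=features,
                        perturbations=remaining)
    return repaired, [p.key for p in chosen]


def make_flag_file(annotation: Annotation, n: int, category: str = "splice",
                   priority: int = 3, source_name: str = "splice_pipeline",
                   seed: int = 0) -> str:
    """A tab-delimited flag file targeting ``n`` random transcripts."""
    rng = random.Random(f"flagfile-{seed}")
    transcripts = annotation.transcripts()
    if n > len(transcripts):
        raise GenerationError(f"{n} flags requested, {len(transcripts)} transcripts")
    targets = rng.sample([t.entity_id for t in transcripts], n)
    requests = [FlagRequest(t, category, priority, source_name,
                            f"dubious {category} call on {t}") for t in targets]
    return write_flag_file(requests)


def write_fixture_bundle(outdir, spec: PerturbationSpec) -> Dict[str, str]:
    """Write annotation GFF3, evidence DAS XML, a flag file and the
    ground-truth JSON sidecar into a directory; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation = generate_annotation(spec)
    evidence = generate_evidence(annotation, spec)
    paths = {
        "annotation": str(outdir / "annotation.gff3"),
        "evidence": str(outdir / "evidence.das.xml"),
        "flags": str(outdir / "flags.tsv"),
        "ground_truth": str(outdir / "ground_truth.json"),
    }
    (outdir / "annotation.gff3").write_text(annotation.gff3)
    (outdir / "evidence.das.xml").write_text(evidence.to_das_xml())
    n_flags = min(3, len(annotation.transcripts()))
    (outdir / "flags.tsv").write_text(make_flag_file(annotation, n_flags,
                                                     seed=spec.seed))
    (outdir / "ground_truth.json").write_text(json.dumps(
        [{"key": list(p.key), "category": p.key[1], "kind": p.kind}
         for p in evidence.perturbations], indent=2) + "\n")
    return paths
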