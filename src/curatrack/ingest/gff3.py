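"""GFF3 adaptor: reference annotation in, tracked hierarchy out (and back).

``gene -> mRNA -> exon/CDS`` Parent relationships are mapped onto the
locus/transcript/subfeature hierarchy. Parsing sits on :mod:`gffutils`;
a cheap line-level pre-validation runs first so syntax errors are
reported with their line number.

Conventions for records the GFF3 itself leaves open:

* records without an ``ID`` attribute get a synthesised id
  ``<source>:<chrom>:<start>-<end>:<type>``;
* exon-level records without a ``Parent`` are attached by containment to
  the unique transcript that contains them, and rejected if that
  transcript is not unique;
* transcript-level records without a ``Parent`` are kept as unparented
  (degenerate flat configurations are supported).
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import gffutils

from ..errors import HierarchyError, InvariantError, ParseError
from ..model import LEVELS, AnnotationEntity, GenomicInterval
from .base import SourceFeature

__all__ = ["read_gff3", "write_gff3", "read_gff3_features", "load_entities"]

LOCUS_TYPES = {"gene", "pseudogene", "ncRNA_gene"}
TRANSCRIPT_TYPES = {
    "mRNA", "transcript", "ncRNA", "lnc_RNA", "pseudogenic_transcript",
    "processed_transcript", "miRNA", "snoRNA", "snRNA", "rRNA", "tRNA",
}
SUBFEATURE_TYPES = {
    "exon", "CDS", "five_prime_UTR", "three_prime_UTR", "UTR", "intron",
    "start_codon", "stop_codon",
}

_LEVEL_RANK = {level: i for i, level in enumerate(LEVELS)}

# GFF3 column-9 reserved characters, percent-encoded on write ('%' first).
_ESCAPES = (("%", "%25"), (";", "%3B"), ("=", "%3D"), ("&", "%26"),
            (",", "%2C"), ("\t", "%09"), ("\n", "%0A"))


def _escape(value: str) -> str:
    for raw, enc in _ESCAPES:
        value = value.replace(raw, enc)
    return value


def _validate_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ParseError(f"expected 9 tab-separated columns, got {len(cols)}", lineno)
        try:
            start, end = int(cols[3]), int(cols[4])
        except ValueError:
            raise ParseError(f"non-integer coordinates {cols[3]!r}/{cols[4]!r}", lineno)
        if start < 1 or end < start:
            raise ParseError(f"invalid coordinate range {start}-{end}", lineno)
        if cols[6] not in ("+", "-", ".", "?"):
            raise ParseError(f"invalid strand {cols[6]!r}", lineno)


def _read_text(path_or_text: str) -> str:
    text = str(path_or_text)
    if "\n" in text or text.startswith("##gff-version"):
        return text
    with open(text) as fh:
        return fh.read()


def _first(attrs, key: str) -> str:
    values = attrs.get(key)
    return values[0] if values else ""


def _classify(featuretype: str, parent_level: Optional[str]) -> str:
    if featuretype in LOCUS_TYPES:
        return "locus"
    if featuretype in TRANSCRIPT_TYPES:
        return "transcript"
    if featuretype in SUBFEATURE_TYPES:
        return "subfeature"
    # unknown SO type: infer from position in the Parent chain
    if parent_level is None:
        return "locus"
    if parent_level == "locus":
        return "transcript"
    return "subfeature"


def read_gff3(path_or_text: str) -> List[AnnotationEntity]:
    """Read a GFF3 file (or literal text) into the entity hierarchy.

    Returns entities sorted parents-first by (chrom, start, level,
    entity_id). Raises :class:`ParseError` with a line number for syntax
    problems, :class:`HierarchyError` for cyclic or unattachable Parent
    links, and :class:`InvariantError` when a child interval escapes its
    parent.
    """
    text = _read_text(path_or_text)
    _validate_lines(text)
    db = gffutils.create_db(text, ":memory:", from_string=True,
                            merge_strategy="create_unique", keep_order=True)
    feats = list(db.all_features())

    # resolve parent links by raw attribute (gffutils ids may be autogenerated)
    by_attr_id: Dict[str, object] = {}
    for f in feats:
        fid = _first(f.attributes, "ID")
        if fid:
            by_attr_id[fid] = f

    parent_of: Dict[str, str] = {}  # gffutils key -> gffutils key
    key_of = {id(f): f.id for f in feats}

    def _gkey(f) -> str:
        return f.id

    for f in feats:
        pid = _first(f.attributes, "Parent")
        if not pid:
            continue
        parent = by_attr_id.get(pid)
        if parent is None:
            raise HierarchyError(f"Parent {pid!r} of {_first(f.attributes, 'ID') or f.id!r}"
                                 " not found in file")
        parent_of[_gkey(f)] = _gkey(parent)

    # cycle detection on the Parent graph
    for f in feats:
        seen: Set[str] = set()
        node = _gkey(f)
        while node in parent_of:
            if node in seen:
                raise HierarchyError(f"cyclic Parent chain involving {node!r}")
            seen.add(node)
            node = parent_of[node]

    by_gkey = {_gkey(f): f for f in feats}
    level_cache: Dict[str, str] = {}

    def _level(f) -> str:
        gk = _gkey(f)
        if gk in level_cache:
            return level_cache[gk]
        pk = parent_of.get(gk)
        parent_level = _level(by_gkey[pk]) if pk else None
        lv = _classify(f.featuretype, parent_level)
        level_cache[gk] = lv
        return lv

    # attach orphan subfeatures by containment to a unique transcript
    transcripts = [f for f in feats if _level(f) == "transcript"]
    for f in feats:
        gk = _gkey(f)
        if gk in parent_of or _level(f) != "subfeature":
            continue
        hosts = [t for t in transcripts
                 if t.seqid == f.seqid and t.start <= f.start and f.end <= t.end]
        if len(hosts) != 1:
            name = _first(f.attributes, "ID") or gk
            raise HierarchyError(
                f"subfeature {name!r} has no Parent and {len(hosts)} containing"
                " transcripts; cannot attach unambiguously")
        parent_of[gk] = _gkey(hosts[0])

    # build entities
    entity_id_of: Dict[str, str] = {}
    for f in feats:
        fid = _first(f.attributes, "ID")
        if not fid:
            fid = f"{f.source}:{f.seqid}:{f.start}-{f.end}:{f.featuretype}"
        entity_id_of[_gkey(f)] = fid
    if len(set(entity_id_of.values())) != len(entity_id_of):
        dupes = sorted({v for v in entity_id_of.values()
                        if list(entity_id_of.values()).count(v) > 1})
        raise ParseError(f"duplicate entity ids in file: {dupes}")

    entities: List[AnnotationEntity] = []
    for f in feats:
        gk = _gkey(f)
        level = _level(f)
        strand = f.strand if f.strand in ("+", "-") else "."
        interval = GenomicInterval(f.seqid, f.start, f.end, strand)
        parent_key = parent_of.get(gk, "")
        parent_id = entity_id_of[parent_key] if parent_key else ""
        biotype = _first(f.attributes, "biotype")
        if not biotype and level == "subfeature":
            biotype = f.featuretype
        entities.append(AnnotationEntity(
            entity_id=entity_id_of[gk],
            level=level,
            interval=interval,
            parent_id=parent_id,
            biotype=biotype,
            description=_first(f.attributes, "description"),
        ))

    # containment check against the parsed parents
    by_id = {e.entity_id: e for e in entities}
    for e in entities:
        if not e.parent_id:
            continue
        parent = by_id[e.parent_id]
        if not parent.interval.contains(e.interval):
            raise InvariantError(
                f"{e.entity_id!r} interval {e.interval} lies outside parent"
                f" {e.parent_id!r} interval {parent.interval}")
        if e.interval.strand != parent.interval.strand:
            raise InvariantError(
                f"{e.entity_id!r} strand differs from parent {e.parent_id!r}")

    entities.sort(key=lambda e: (e.interval.chrom, e.interval.start,
                                 _LEVEL_RANK[e.level], e.entity_id))
    return entities


_WRITE_TYPE = {"locus": "gene", "transcript": "transcript", "subfeature": "exon"}


def write_gff3(entities: Sequence[AnnotationEntity]) -> str:
    """Serialise entities as GFF3, deterministically ordered.

    ``Parent`` is written only when the parent is part of the written set,
    so partial selections remain valid, re-importable documents. Subfeature
    biotypes that are themselves SO feature types (exon, CDS, ...) are
    encoded in column 3; anything else goes into a ``biotype`` attribute.
    """
    written_ids = {e.entity_id for e in entities}
    lines = ["##gff-version 3"]
    ordered = sorted(entities, key=lambda e: (e.interval.chrom, e.interval.start,
                                              _LEVEL_RANK[e.level], e.entity_id))
    for e in ordered:
        if e.level == "subfeature" and e.biotype in SUBFEATURE_TYPES:
            ftype, biotype_attr = e.biotype, ""
        else:
            ftype, biotype_attr = _WRITE_TYPE[e.level], e.biotype
        attrs = [f"ID={_escape(e.entity_id)}"]
        if e.parent_id and e.parent_id in written_ids:
            attrs.append(f"Parent={_escape(e.parent_id)}")
        if biotype_attr:
            attrs.append(f"biotype={_escape(biotype_attr)}")
        if e.description:
            attrs.append(f"description={_escape(e.description)}")
        iv = e.interval
        lines.append("\t".join([
            iv.chrom, "curatrack", ftype, str(iv.start), str(iv.end),
            ".", iv.strand, ".", ";".join(attrs),
        ]))
    return "\n".join(lines) + "\n"


def read_gff3_features(path_or_text: str, source_name: str) -> List[SourceFeature]:
    """Read a GFF3 document as a flat list of evidence features.

    Used for evidence sources that publish GFF3 rather than DAS XML; no
    hierarchy is built. A ``reference`` attribute (or the id part of a
    standard ``Target``) becomes ``target_entity_id``.
    """
    text = _read_text(path_or_text)
    _validate_lines(text)
    features: List[SourceFeature] = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = gffutils.feature.feature_from_line(line)
        fid = _first(f.attributes, "ID")
        if not fid:
            fid = f"{f.source}:{f.seqid}:{f.start}-{f.end}:{f.featuretype}"
        target = _first(f.attributes, "reference")
        if not target:
            target = _first(f.attributes, "Target").split(" ")[0]
        strand = f.strand if f.strand in ("+", "-") else "."
        features.append(SourceFeature(
            source_name=source_name,
            feature_id=fid,
            interval=GenomicInterval(f.seqid, f.start, f.end, strand),
            type=f.featuretype,
            label=_first(f.attributes, "Name"),
            note=_first(f.attributes, "Note"),
            target_entity_id=target,
        ))
    return features


def load_entities(store, entities: Iterable[AnnotationEntity],
                  actor: str = "system") -> int:
    """Upsert a parent-first entity list into a store; returns the count."""
    n = 0
    with store.transaction():
        for e in entities:
            store.upsert_entity(e, actor=actor)
            n += 1
    return n
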