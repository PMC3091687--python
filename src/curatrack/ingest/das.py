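"""Distributed Annotation System (DAS) features-XML adaptor.

Reads and writes the 1.53E features response document
(``DASGFF/GFF/SEGMENT/FEATURE``). Because upstream servers vary in how
faithfully they follow the protocol, a *tight* verification pass
(:func:`verify_source`) itemises every violation of the expected format;
strict sources fail loudly, lenient sources tolerate missing optional
elements.

Orientation uses the DAS convention ``+``/``-``/``0`` on the wire and is
mapped to ``+``/``-``/``.`` internally.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from ..errors import ParseError, VerificationError
from ..model import GenomicInterval
from .base import SourceFeature

__all__ = ["read_das_features", "write_das", "verify_source", "VerificationReport"]

_ORIENT_IN = {"+": "+", "-": "-", "0": ".", ".": "."}
_ORIENT_OUT = {"+": "+", "-": "-", ".": "0"}


@dataclass
class VerificationReport:
    """Outcome of the tight-format check: pass iff zero violations."""

    violations: List[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        if self.passed:
            return "PASS (0 violations)"
        body = "\n".join(f"  - {v}" for v in self.violations)
        return f"FAIL ({len(self.violations)} violations)\n{body}"


def _parse_xml(document: str) -> ET.Element:
    text = str(document)
    if not text.lstrip().startswith("<"):
        with open(text) as fh:
            text = fh.read()
    try:
        return ET.fromstring(text)
    except ET.ParseError as exc:
        raise ParseError(f"not well-formed XML: {exc}") from exc


def _segments(root: ET.Element) -> List[ET.Element]:
    if root.tag != "DASGFF":
        raise ParseError(f"expected DASGFF root element, got {root.tag!r}")
    return [seg for gff in root.findall("GFF") for seg in gff.findall("SEGMENT")]


def verify_source(document: str, schema_strict: bool = True) -> VerificationReport:
    """Itemise every violation of the tight DAS features format.

    Checked per FEATURE: id attribute, TYPE element, integer START/END,
    END >= START, known ORIENTATION. Per SEGMENT: id attribute. All
    failures are report items, never exceptions (malformed XML is the one
    exception — there is nothing to itemise in a document that does not
    parse).
    """
    report = VerificationReport()
    root = _parse_xml(document)
    try:
        segments = _segments(root)
    except ParseError as exc:
        report.violations.append(str(exc))
        return report
    for si, seg in enumerate(segments):
        seg_id = seg.get("id", "")
        seg_name = seg_id or f"SEGMENT[{si}]"
        if not seg_id:
            report.violations.append(f"{seg_name}: missing SEGMENT id attribute")
        for fi, feat in enumerate(seg.findall("FEATURE")):
            fid = feat.get("id", "")
            name = f"{seg_name}/{fid or f'FEATURE[{fi}]'}"
            if not fid:
                report.violations.append(f"{name}: missing FEATURE id attribute")
            if feat.find("TYPE") is None:
                report.violations.append(f"{name}: missing TYPE element")
            start_el, end_el = feat.find("START"), feat.find("END")
            coords = {}
            for label, el in (("START", start_el), ("END", end_el)):
                if el is None or el.text is None:
                    report.violations.append(f"{name}: missing {label} element")
                else:
                    try:
                        coords[label] = int(el.text.strip())
                    except ValueError:
                        report.violations.append(
                            f"{name}: non-integer {label} {el.text.strip()!r}")
            if "START" in coords and "END" in coords and coords["END"] < coords["START"]:
                report.violations.append(
                    f"{name}: END {coords['END']} < START {coords['START']}")
            orient = feat.find("ORIENTATION")
            if orient is None or orient.text is None:
                if schema_strict:
                    report.violations.append(f"{name}: missing ORIENTATION element")
            elif orient.text.strip() not in _ORIENT_IN:
                report.violations.append(
                    f"{name}: unknown ORIENTATION {orient.text.strip()!r}")
    return report


def read_das_features(document: str, source_name: str = "das",
                      schema_strict: bool = False) -> List[SourceFeature]:
    """Parse a DAS 1.53E features document into :class:`SourceFeature` s.

    ``SEGMENT id`` becomes the chromosome; ``START``/``END`` the interval;
    ``ORIENTATION`` the strand; ``TYPE`` the feature type; ``NOTE`` the
    free-text note; a ``TARGET`` element's id attribute becomes
    ``target_entity_id``. With ``schema_strict`` the document must first
    pass :func:`verify_source`.
    """
    if schema_strict:
        report = verify_source(document, schema_strict=True)
        if not report.passed:
            raise VerificationError(
                f"document failed strict verification: {report}",
                violations=report.violations)
    root = _parse_xml(document)
    features: List[SourceFeature] = []
    for seg in _segments(root):
        chrom = seg.get("id", "")
        if not chrom:
            raise VerificationError("SEGMENT without id attribute")
        for fi, feat in enumerate(seg.findall("FEATURE")):
            fid = feat.get("id", "") or f"{chrom}.feature{fi}"
            start_el, end_el = feat.find("START"), feat.find("END")
            if start_el is None or end_el is None or not (start_el.text and end_el.text):
                raise VerificationError(f"feature {fid!r}: missing START/END")
            try:
                start, end = int(start_el.text.strip()), int(end_el.text.strip())
            except ValueError as exc:
                raise VerificationError(f"feature {fid!r}: non-integer coordinates") from exc
            if end < start:
                raise VerificationError(f"feature {fid!r}: END {end} < START {start}")
            orient_el = feat.find("ORIENTATION")
            orient_text = (orient_el.text or "").strip() if orient_el is not None else "."
            strand = _ORIENT_IN.get(orient_text or ".")
            if strand is None:
                raise VerificationError(f"feature {fid!r}: unknown ORIENTATION {orient_text!r}")
            type_el = feat.find("TYPE")
            ftype = (type_el.text or "").strip() if type_el is not None else ""
            if not ftype and type_el is not None:
                ftype = type_el.get("id", "")
            note_el = feat.find("NOTE")
            target_el = feat.find("TARGET")
            features.append(SourceFeature(
                source_name=source_name,
                feature_id=fid,
                interval=GenomicInterval(chrom, start, end, strand),
                type=ftype,
                label=feat.get("label", ""),
                note=(note_el.text or "") if note_el is not None else "",
                target_entity_id=target_el.get("id", "") if target_el is not None else "",
            ))
    return features


def write_das(features: Sequence[SourceFeature],
              segment_bounds: Optional[Dict[str, Tuple[int, int]]] = None) -> str:
    """Serialise features as a DAS 1.53E features response document.

    Features are grouped into one SEGMENT per chromosome (sorted by name;
    input order preserved within a segment). ``segment_bounds`` overrides
    the advertised segment start/stop (default: 1 to max feature end).
    """
    by_chrom: Dict[str, List[SourceFeature]] = {}
    for f in features:
        by_chrom.setdefault(f.interval.chrom, []).append(f)
    root = ET.Element("DASGFF")
    gff = ET.SubElement(root, "GFF", {"version": "1.0", "href": "file://local"})
    for chrom in sorted(by_chrom):
        feats = by_chrom[chrom]
        if segment_bounds and chrom in segment_bounds:
            lo, hi = segment_bounds[chrom]
        else:
            lo, hi = 1, max(f.interval.end for f in feats)
        seg = ET.SubElement(gff, "SEGMENT",
                            {"id": chrom, "start": str(lo), "stop": str(hi),
                             "version": "1.0"})
        for f in feats:
            attrs = {"id": f.feature_id}
            if f.label:
                attrs["label"] = f.label
            fe = ET.SubElement(seg, "FEATURE", attrs)
            ET.SubElement(fe, "TYPE", {"id": f.type}).text = f.type
            ET.SubElement(fe, "METHOD", {"id": f.source_name}).text = f.source_name
            ET.SubElement(fe, "START").text = str(f.interval.start)
            ET.SubElement(fe, "END").text = str(f.interval.end)
            ET.SubElement(fe, "SCORE").text = "-"
            ET.SubElement(fe, "ORIENTATION").text = _ORIENT_OUT[f.interval.strand]
            ET.SubElement(fe, "PHASE").text = "-"
            if f.note:
                ET.SubElement(fe, "NOTE").text = f.note
            if f.target_entity_id:
                ET.SubElement(fe, "TARGET", {"id": f.target_entity_id}).text = (
                    f.target_entity_id)
    ET.indent(root)
    return '<?xml version="1.0" standalone="no"?>\n' + ET.tostring(
        root, encoding="unicode") + "\n"
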