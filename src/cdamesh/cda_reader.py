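"""HL7-CDA document parsing into a section-structured model.

A CDA document is XML composed of coded sections, each with a title, LOINC
or SNOMED codes, and a narrative text block.  Only the narrative is kept —
structured ``entry`` elements are ignored because term identification mines
free text.  The parser accepts both the CDA R2 namespace
(``urn:hl7-org:v3``) and namespace-free XML with the same local element
names; nested sections are flattened depth-first into one ordered list.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

from lxml import etree

__all__ = [
    "SectionCode",
    "CdaSection",
    "CdaDocument",
    "CdaParseError",
    "Finding",
    "parse_cda",
    "validate_cda",
    "serialize_cda",
]

CDA_NS = "urn:hl7-org:v3"

#: OID → code-system label for the systems sections are coded in.
_CODE_SYSTEMS = {
    "2.16.840.1.113883.6.1": "LOINC",
    "2.16.840.1.113883.6.96": "SNOMED",
}
_SYSTEM_OIDS = {v: k for k, v in _CODE_SYSTEMS.items()}


class CdaParseError(Exception):
    pass


@dataclass(frozen=True, order=True)
class SectionCode:
    """A section identifier in a coding system (LOINC or SNOMED)."""

    system: str  # "LOINC" | "SNOMED"
    code: str

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("section code must be non-empty")
        if self.system not in ("LOINC", "SNOMED"):
            raise ValueError(f"unknown code system {self.system!r}")


@dataclass(frozen=True)
class CdaSection:
    title: str
    codes: frozenset[SectionCode]
    text: str
    order_index: int

    def __post_init__(self) -> None:
        if self.order_index < 0:
            raise ValueError("order_index must be >= 0")


@dataclass(frozen=True)
class CdaDocument:
    doc_id: str
    title: str
    sections: tuple[CdaSection, ...]

    def __post_init__(self) -> None:
        indices = [s.order_index for s in self.sections]
        if indices != sorted(indices) or len(set(indices)) != len(indices):
            raise ValueError("sections must carry unique, ordered order_index")


@dataclass(frozen=True)
class Finding:
    """One validation finding (``error`` or ``warning``)."""

    level: str
    message: str
    location: str = ""


def _local(el: etree._Element) -> str:
    return etree.QName(el).localname if isinstance(el.tag, str) else ""


def _narrative_text(text_el: etree._Element) -> str:
    """Flatten a narrative block to plain text.

    Element text is concatenated in document order with single-space
    separators between block-ish elements (paragraphs, list items, table
    cells), then whitespace-normalized.  No characters are invented beyond
    separators.
    """
    parts: list[str] = []
    for chunk in text_el.itertext():
        chunk = chunk.strip()
        if chunk:
            parts.append(chunk)
    return re.sub(r"\s+", " ", " ".join(parts)).strip()


def _section_codes(section_el: etree._Element) -> frozenset[SectionCode]:
    codes: set[SectionCode] = set()
    for child in section_el:
        if _local(child) != "code":
            continue
        code = child.get("code") or (child.text or "").strip()
        if not code:
            continue
        system_attr = child.get("codeSystem") or child.get("system") or ""
        system = _CODE_SYSTEMS.get(system_attr, system_attr.upper())
        if system in ("LOINC", "SNOMED"):
            codes.add(SectionCode(system=system, code=code))
    return frozenset(codes)


def _iter_sections(root: etree._Element):
    """Depth-first, document-order iteration over ``section`` elements."""
    for el in root.iter():
        if _local(el) == "section":
            yield el


def parse_cda(xml: str | Path | bytes | IO) -> CdaDocument:
    """Parse a CDA file/stream into a :class:`CdaDocument`.

    One :class:`CdaSection` per ``section`` element in document order
    (nested sub-sections flattened); raises :class:`CdaParseError` on
    malformed XML.  A document without sections parses to zero sections
    (see :func:`validate_cda` for the warning).
    """
    root = _parse_root(xml)
    doc_id = ""
    title = ""
    for el in root.iter():
        ln = _local(el)
        if ln == "id" and not doc_id:
            doc_id = el.get("extension") or el.get("root") or (el.text or "").strip()
        elif (
            ln == "title"
            and title == ""
            and (el.getparent() is None or _local(el.getparent()) != "section")
        ):
            title = (el.text or "").strip()
        elif ln == "section":
            break  # ids/titles past the first section belong to sections

    sections: list[CdaSection] = []
    for idx, sec in enumerate(_iter_sections(root)):
        sec_title = ""
        text = ""
        for child in sec:
            ln = _local(child)
            if ln == "title" and not sec_title:
                sec_title = (child.text or "").strip()
            elif ln == "text":
                text = _narrative_text(child)
        sections.append(
            CdaSection(
                title=sec_title,
                codes=_section_codes(sec),
                text=text,
                order_index=idx,
            )
        )
    return CdaDocument(doc_id=doc_id, title=title, sections=tuple(sections))


def _parse_root(xml: str | Path | bytes | IO) -> etree._Element:
    try:
        if isinstance(xml, bytes):
            return etree.fromstring(xml)
        if hasattr(xml, "read"):
            return etree.parse(xml).getroot()
        return etree.parse(str(xml)).getroot()
    except etree.XMLSyntaxError as exc:
        raise CdaParseError(f"malformed XML: {exc}") from exc
    except OSError as exc:
        raise CdaParseError(str(exc)) from exc


def validate_cda(xml: str | Path | bytes | IO, strict: bool = False) -> list[Finding]:
    """Validate a stream; findings are returned, never raised.

    Empty report iff the document is well-formed XML, has a CDA root
    element (``ClinicalDocument``, or any root unless ``strict``), and
    contains at least one section with narrative text.
    """
    findings: list[Finding] = []
    try:
        root = _parse_root(xml)
    except CdaParseError as exc:
        return [Finding(level="error", message=str(exc))]

    root_name = _local(root)
    if root_name != "ClinicalDocument":
        level = "error" if strict else "warning"
        findings.append(
            Finding(level=level, message=f"root element is {root_name!r}, "
                    "expected ClinicalDocument", location=root_name)
        )
    doc = parse_cda(etree.tostring(root))
    if not doc.sections:
        findings.append(Finding(level="warning", message="document has no sections"))
    elif not any(s.text for s in doc.sections):
        findings.append(
            Finding(level="warning", message="no section carries narrative text")
        )
    return findings


def serialize_cda(doc: CdaDocument) -> bytes:
    """Serialize a document to CDA R2 XML (fixture writer; round-trips
    through :func:`parse_cda`)."""
    nsmap = {None: CDA_NS}
    root = etree.Element(f"{{{CDA_NS}}}ClinicalDocument", nsmap=nsmap)
    id_el = etree.SubElement(root, f"{{{CDA_NS}}}id")
    id_el.set("extension", doc.doc_id)
    etree.SubElement(root, f"{{{CDA_NS}}}title").text = doc.title
    component = etree.SubElement(root, f"{{{CDA_NS}}}component")
    body = etree.SubElement(component, f"{{{CDA_NS}}}structuredBody")
    for section in doc.sections:
        comp = etree.SubElement(body, f"{{{CDA_NS}}}component")
        sec = etree.SubElement(comp, f"{{{CDA_NS}}}section")
        for code in sorted(section.codes):
            code_el = etree.SubElement(sec, f"{{{CDA_NS}}}code")
            code_el.set("code", code.code)
            code_el.set("codeSystem", _SYSTEM_OIDS[code.system])
        etree.SubElement(sec, f"{{{CDA_NS}}}title").text = section.title
        etree.SubElement(sec, f"{{{CDA_NS}}}text").text = section.text
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )
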