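"""Reading and validating CDISC ODM 1.3.1/1.3.2 study-metadata XML.

:func:`parse_odm` builds the in-memory model from an ODM file, tolerating
unknown elements (they are skipped with a logged warning) and handling the
ODM namespace whether declared as default, prefixed, or absent.

:func:`validate_odm` never raises: it returns a :class:`ValidationReport`
collecting well-formedness, (optional) XSD grammar, and built-in structural
findings.  The official ODM schemas are not redistributed, so grammar
validation runs only when the caller supplies a schema path; the structural
check (required attributes present, all references resolvable, coded values
unique per list) is always available and is the default gate for batch
comparison.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Union

from lxml import etree

from .model import (
    CodeListDef,
    CodeListItemDef,
    ConceptCode,
    ConceptDomain,
    FormDef,
    ItemDef,
    ItemGroupDef,
    MetaDataVersion,
    ODMDocument,
    Study,
    StudyEventDef,
)

__all__ = [
    "OdmParseError",
    "OdmFormatError",
    "ValidationMessage",
    "ValidationReport",
    "parse_odm",
    "validate_odm",
]

log = logging.getLogger(__name__)

SUPPORTED_VERSIONS = ("1.3.1", "1.3.2")

Source = Union[str, os.PathLike, bytes, io.IOBase]


class OdmParseError(ValueError):
    """Input is not well-formed XML (carries line/column when known)."""


class OdmFormatError(ValueError):
    """Input is XML but not an ODM document (root element is not ODM)."""


@dataclass
class ValidationMessage:
    severity: str  # "error" | "warning"
    location: str  # "line:column" or an XPath-like path
    text: str

    def __str__(self) -> str:
        return f"{self.severity.upper()} [{self.location}] {self.text}"


@dataclass
class ValidationReport:
    file_name: str
    well_formed: bool = True
    schema_valid: Optional[bool] = None  # None = not checked
    messages: list[ValidationMessage] = field(default_factory=list)

    @property
    def errors(self) -> list[ValidationMessage]:
        return [m for m in self.messages if m.severity == "error"]

    @property
    def warnings(self) -> list[ValidationMessage]:
        return [m for m in self.messages if m.severity == "warning"]

    @property
    def ok(self) -> bool:
        return self.well_formed and not self.errors

    def error(self, location: str, text: str) -> None:
        self.messages.append(ValidationMessage("error", location, text))

    def warning(self, location: str, text: str) -> None:
        self.messages.append(ValidationMessage("warning", location, text))

    def as_text(self) -> str:
        head = f"{self.file_name}: " + ("OK" if self.ok else "INVALID")
        return "\n".join([head] + [str(m) for m in self.messages])

    def as_json_lines(self) -> str:
        import json

        return "\n".join(
            json.dumps(
                {
                    "file": self.file_name,
                    "severity": m.severity,
                    "location": m.location,
                    "text": m.text,
                }
            )
            for m in self.messages
        )


def _localname(el: etree._Element) -> str:
    return etree.QName(el).localname


def _read_bytes(source: Source) -> tuple[bytes, str]:
    """Return (payload, display name) for a path, bytes, or stream source."""
    if isinstance(source, bytes):
        return source, "<bytes>"
    if isinstance(source, (str, os.PathLike)):
        name = os.fspath(source)
        with open(name, "rb") as fh:
            return fh.read(), os.path.basename(name)
    data = source.read()
    if isinstance(data, str):
        data = data.encode("utf-8")
    return data, getattr(source, "name", "<stream>")


def _parse_tree(source: Source) -> tuple[etree._Element, str]:
    data, name = _read_bytes(source)
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise OdmParseError(f"{name}: not well-formed XML: {exc}") from exc
    if _localname(root) != "ODM":
        raise OdmFormatError(
            f"{name}: root element is {_localname(root)!r}, expected 'ODM'"
        )
    return root, name


def _aliases(el: etree._Element) -> list[ConceptCode]:
    """Direct-child Alias elements only — aliases nested under Question or
    Decode do not contribute to the element's concept domain."""
    out = []
    for child in el:
        if isinstance(child.tag, str) and _localname(child) == "Alias":
            ctx = (child.get("Context") or "").strip()
            code = (child.get("Name") or "").strip()
            if ctx and code:
                out.append(ConceptCode(ctx, code))
    return out


def _concept_domain(el: etree._Element) -> ConceptDomain:
    return ConceptDomain(c.code for c in _aliases(el) if c.is_umls)


def _question_text(el: etree._Element) -> Optional[str]:
    for q in el:
        if isinstance(q.tag, str) and _localname(q) == "Question":
            for t in q:
                if isinstance(t.tag, str) and _localname(t) == "TranslatedText":
                    return (t.text or "").strip() or None
    return None


def _decode_text(cli: etree._Element) -> Optional[str]:
    for d in cli:
        if isinstance(d.tag, str) and _localname(d) == "Decode":
            for t in d:
                if isinstance(t.tag, str) and _localname(t) == "TranslatedText":
                    return (t.text or "").strip() or None
    return None


_KNOWN_MDV_CHILDREN = {
    "Protocol",
    "StudyEventDef",
    "FormDef",
    "ItemGroupDef",
    "ItemDef",
    "CodeList",
    "MeasurementUnitDef",  # parsed tolerantly, ignored by comparison
    "ConditionDef",
    "MethodDef",
}


def parse_odm(source: Source) -> ODMDocument:
    """Parse an ODM study-metadata file into an :class:`ODMDocument`.

    Raises :class:`OdmParseError` for non-XML input and
    :class:`OdmFormatError` when the root element is not ``ODM``.  A declared
    ODMVersion other than 1.3.1/1.3.2 is parsed best-effort with a warning.
    """
    root, name = _parse_tree(source)

    version = (root.get("ODMVersion") or "").strip()
    if version not in SUPPORTED_VERSIONS:
        log.warning(
            "%s: unsupported declared ODMVersion %r (supported: %s); parsing best-effort",
            name,
            version,
            ", ".join(SUPPORTED_VERSIONS),
        )

    doc = ODMDocument(source_name=name, odm_version=version)
    for study_el in root:
        if not isinstance(study_el.tag, str):
            continue
        if _localname(study_el) != "Study":
            log.warning("%s: ignoring unknown ODM child element %r", name, _localname(study_el))
            continue
        doc.studies.append(_parse_study(study_el, name))
    return doc


def _parse_study(study_el: etree._Element, file_name: str) -> Study:
    oid = study_el.get("OID") or ""
    study_name = oid
    mdvs: list[MetaDataVersion] = []
    for child in study_el:
        if not isinstance(child.tag, str):
            continue
        tag = _localname(child)
        if tag == "GlobalVariables":
            for gv in child:
                if isinstance(gv.tag, str) and _localname(gv) == "StudyName":
                    study_name = (gv.text or "").strip() or oid
        elif tag == "MetaDataVersion":
            mdvs.append(_parse_mdv(child, file_name))
        elif tag == "BasicDefinitions":
            pass  # measurement units etc. — tolerated, not modelled
        else:
            log.warning("%s: ignoring unknown Study child element %r", file_name, tag)
    return Study(oid=oid, name=study_name, metadata_versions=mdvs)


def _parse_mdv(mdv_el: etree._Element, file_name: str) -> MetaDataVersion:
    mdv = MetaDataVersion(
        oid=mdv_el.get("OID") or "",
        name=mdv_el.get("Name") or (mdv_el.get("OID") or ""),
    )
    for el in mdv_el:
        if not isinstance(el.tag, str):
            continue
        tag = _localname(el)
        if tag == "StudyEventDef":
            mdv.study_event_defs.append(
                StudyEventDef(
                    oid=el.get("OID") or "",
                    name=el.get("Name") or "",
                    form_refs=_refs(el, "FormRef", "FormOID"),
                )
            )
        elif tag == "FormDef":
            mdv.form_defs.append(
                FormDef(
                    oid=el.get("OID") or "",
                    name=el.get("Name") or "",
                    item_group_refs=_refs(el, "ItemGroupRef", "ItemGroupOID"),
                )
            )
        elif tag == "ItemGroupDef":
            mdv.item_group_defs.append(
                ItemGroupDef(
                    oid=el.get("OID") or "",
                    name=el.get("Name") or "",
                    item_refs=_refs(el, "ItemRef", "ItemOID"),
                )
            )
        elif tag == "ItemDef":
            codelist_oid = None
            for c in el:
                if isinstance(c.tag, str) and _localname(c) == "CodeListRef":
                    codelist_oid = c.get("CodeListOID")
            mdv.item_defs.append(
                ItemDef(
                    oid=el.get("OID") or "",
                    name=el.get("Name") or "",
                    data_type=(el.get("DataType") or "").strip(),
                    concept_domain=_concept_domain(el),
                    codelist_oid=codelist_oid,
                    question_text=_question_text(el),
                )
            )
        elif tag == "CodeList":
            items = []
            for c in el:
                if isinstance(c.tag, str) and _localname(c) == "CodeListItem":
                    items.append(
                        CodeListItemDef(
                            coded_value=c.get("CodedValue") or "",
                            concept_domain=_concept_domain(c),
                            decode_text=_decode_text(c),
                        )
                    )
            mdv.code_lists.append(
                CodeListDef(
                    oid=el.get("OID") or "",
                    name=el.get("Name") or "",
                    data_type=(el.get("DataType") or "").strip(),
                    items=items,
                )
            )
        elif tag in _KNOWN_MDV_CHILDREN:
            pass
        else:
            log.warning("%s: ignoring unknown MetaDataVersion child %r", file_name, tag)
    return mdv


def _refs(el: etree._Element, ref_tag: str, attr: str) -> list[str]:
    out = []
    for c in el:
        if isinstance(c.tag, str) and _localname(c) == ref_tag:
            oid = c.get(attr)
            if oid:
                out.append(oid)
    return out


# ---------------------------------------------------------------------------
# Validation


def validate_odm(source: Source, schema_path: Optional[str] = None) -> ValidationReport:
    """Validate an ODM file; all findings land in the returned report.

    With ``schema_path`` given, full XSD grammar validation is performed via
    lxml; otherwise the built-in structural check runs.
    """
    try:
        data, name = _read_bytes(source)
    except OSError as exc:
        report = ValidationReport(file_name=str(source), well_formed=False)
        report.error("file", f"cannot read input: {exc}")
        return report

    report = ValidationReport(file_name=name)
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        report.well_formed = False
        line = exc.lineno or 1
        col = getattr(exc, "position", (line, 0))[1]
        report.error(f"{line}:{col}", f"not well-formed XML: {exc.msg or exc}")
        return report

    if _localname(root) != "ODM":
        report.error("/", f"root element is {_localname(root)!r}, expected 'ODM'")
        return report

    version = (root.get("ODMVersion") or "").strip()
    if version not in SUPPORTED_VERSIONS:
        report.warning(
            "/ODM@ODMVersion",
            f"unsupported declared version {version!r} "
            f"(supported: {', '.join(SUPPORTED_VERSIONS)})",
        )

    if schema_path is not None:
        schema = etree.XMLSchema(etree.parse(schema_path))
        report.schema_valid = schema.validate(etree.ElementTree(root))
        for err in schema.error_log:
            report.error(f"{err.line}:{err.column}", err.message)
    else:
        _structural_check(root, report)
        report.schema_valid = None

    return report


_REQUIRED_ATTRS = {
    "ItemDef": ("OID", "Name", "DataType"),
    "CodeList": ("OID", "Name", "DataType"),
    "FormDef": ("OID", "Name"),
    "ItemGroupDef": ("OID", "Name"),
    "StudyEventDef": ("OID", "Name"),
}

_REF_TARGETS = {
    "FormRef": ("FormOID", "FormDef"),
    "ItemGroupRef": ("ItemGroupOID", "ItemGroupDef"),
    "ItemRef": ("ItemOID", "ItemDef"),
    "CodeListRef": ("CodeListOID", "CodeList"),
}


def _structural_check(root: etree._Element, report: ValidationReport) -> None:
    """Built-in structural rules: required attributes present, OIDs unique
    per def kind, all references resolvable, coded values unique per list."""
    for study_el in root:
        if not isinstance(study_el.tag, str) or _localname(study_el) != "Study":
            continue
        study_oid = study_el.get("OID") or "?"
        for mdv_el in study_el:
            if not isinstance(mdv_el.tag, str) or _localname(mdv_el) != "MetaDataVersion":
                continue
            _check_mdv(mdv_el, f"Study[{study_oid}]", report)


def _check_mdv(mdv_el: etree._Element, where: str, report: ValidationReport) -> None:
    mdv_oid = mdv_el.get("OID") or "?"
    path = f"{where}/MetaDataVersion[{mdv_oid}]"
    defined: dict[str, set[str]] = {k: set() for k in _REQUIRED_ATTRS}

    for el in mdv_el.iter():
        if not isinstance(el.tag, str):
            continue
        tag = _localname(el)
        if tag in _REQUIRED_ATTRS:
            oid = el.get("OID")
            for attr in _REQUIRED_ATTRS[tag]:
                if not (el.get(attr) or "").strip():
                    report.error(
                        f"{path}/{tag}[{oid or '?'}]",
                        f"{tag} is missing required attribute {attr}",
                    )
            if oid:
                if oid in defined[tag]:
                    report.error(f"{path}/{tag}[{oid}]", f"duplicate {tag} OID {oid!r}")
                defined[tag].add(oid)
        if tag == "CodeList":
            seen: set[str] = set()
            for c in el:
                if isinstance(c.tag, str) and _localname(c) == "CodeListItem":
                    cv = (c.get("CodedValue") or "").strip()
                    if not cv:
                        report.error(
                            f"{path}/CodeList[{el.get('OID') or '?'}]",
                            "CodeListItem is missing required attribute CodedValue",
                        )
                    elif cv in seen:
                        report.error(
                            f"{path}/CodeList[{el.get('OID') or '?'}]",
                            f"duplicated CodedValue {cv!r}",
                        )
                    seen.add(cv)

    for el in mdv_el.iter():
        if not isinstance(el.tag, str):
            continue
        tag = _localname(el)
        if tag in _REF_TARGETS:
            attr, target = _REF_TARGETS[tag]
            oid = (el.get(attr) or "").strip()
            parent = el.getparent()
            ppath = f"{path}/{_localname(parent)}[{parent.get('OID') or '?'}]"
            if not oid:
                report.error(ppath, f"{tag} is missing required attribute {attr}")
            elif oid not in defined[target]:
                report.error(ppath, f"{tag} references undefined {target} OID {oid!r}")
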