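"""In-memory data model for the subset of CDISC ODM study metadata used for
form comparison.

The model mirrors the ODM containment hierarchy (Study -> MetaDataVersion ->
FormDef -> ItemGroupDef -> ItemDef -> CodeList) but keeps only what the
comparison method consumes: names, data types, code lists and the UMLS
concept annotations carried by ``Alias`` elements.  Following ISO/IEC 11179
terminology, the set of concept codes attached to a data element is its
*concept domain*; its data type together with the optional code list is its
*value domain*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

__all__ = [
    "ConceptCode",
    "ConceptDomain",
    "CodeListItemDef",
    "CodeListDef",
    "ItemDef",
    "ItemGroupDef",
    "FormDef",
    "StudyEventDef",
    "MetaDataVersion",
    "Study",
    "ODMDocument",
    "ValueDomain",
    "ResolutionError",
    "value_domain_of",
]

#: ODM data-type tokens accepted for items and code lists.
DATA_TYPES = frozenset(
    {"integer", "float", "text", "string", "date", "time", "datetime", "boolean", "double"}
)

#: Alias contexts treated as UMLS annotations (matched case-insensitively).
UMLS_CONTEXT = "UMLS"


class ResolutionError(KeyError):
    """A *Ref points at an OID that is not defined in its MetaDataVersion."""


@dataclass(frozen=True)
class ConceptCode:
    """A single terminology code attached via an ODM ``Alias`` element.

    ``context`` is the terminology label (the literal ``Context`` attribute,
    e.g. ``"UMLS"``); ``code`` is the code string (a CUI such as
    ``C0150831``).  Both are whitespace-trimmed and must be non-empty.
    """

    context: str
    code: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "context", self.context.strip())
        object.__setattr__(self, "code", self.code.strip())
        if not self.context:
            raise ValueError("ConceptCode.context must be non-empty")
        if not self.code:
            raise ValueError("ConceptCode.code must be non-empty")

    @property
    def is_umls(self) -> bool:
        return self.context.upper() == UMLS_CONTEXT


class ConceptDomain:
    """An unordered, duplicate-free set of concept-code strings.

    Codes are compared whitespace-trimmed and case-sensitively (CUIs are
    canonical uppercase ``C`` + digits).  An empty domain means the data
    element is not semantically coded.  Equality is order-insensitive set
    equality, so ConceptDomain values can serve as grouping keys.
    """

    __slots__ = ("_codes",)

    def __init__(self, codes: Iterable[str] = ()) -> None:
        cleaned = []
        for c in codes:
            c = c.strip()
            if not c:
                raise ValueError("concept codes must be non-empty after trimming")
            cleaned.append(c)
        self._codes: frozenset[str] = frozenset(cleaned)

    @property
    def codes(self) -> frozenset[str]:
        return self._codes

    def add(self, code: str) -> "ConceptDomain":
        """Return a domain with ``code`` included (no-op if already present)."""
        return ConceptDomain(self._codes | {code.strip()})

    @property
    def is_coded(self) -> bool:
        return bool(self._codes)

    def __contains__(self, code: str) -> bool:
        return code.strip() in self._codes

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self._codes))

    def __len__(self) -> int:
        return len(self._codes)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ConceptDomain):
            return self._codes == other._codes
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self._codes)

    def __repr__(self) -> str:
        return f"ConceptDomain({sorted(self._codes)!r})"


@dataclass
class CodeListItemDef:
    """One permissible value of a code list: a coded value, its concept
    codes, and an optional human-readable decode."""

    coded_value: str
    concept_domain: ConceptDomain = field(default_factory=ConceptDomain)
    decode_text: Optional[str] = None

    def __post_init__(self) -> None:
        self.coded_value = self.coded_value.strip()
        if not self.coded_value:
            raise ValueError("CodeListItemDef.coded_value must be non-empty")


@dataclass
class CodeListDef:
    oid: str
    name: str
    data_type: str
    items: list[CodeListItemDef] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for it in self.items:
            if it.coded_value in seen:
                raise ValueError(
                    f"duplicate CodedValue {it.coded_value!r} in code list {self.oid!r}"
                )
            seen.add(it.coded_value)


@dataclass
class ItemDef:
    """A single documentation field: name, ODM data type, concept domain and
    an optional reference to a code list in the same MetaDataVersion."""

    oid: str
    name: str
    data_type: str
    concept_domain: ConceptDomain = field(default_factory=ConceptDomain)
    codelist_oid: Optional[str] = None
    question_text: Optional[str] = None


@dataclass
class ItemGroupDef:
    oid: str
    name: str
    item_refs: list[str] = field(default_factory=list)  # ItemDef OIDs, document order


@dataclass
class FormDef:
    oid: str
    name: str
    item_group_refs: list[str] = field(default_factory=list)


@dataclass
class StudyEventDef:
    oid: str
    name: str
    form_refs: list[str] = field(default_factory=list)


@dataclass
class MetaDataVersion:
    """One metadata version: all defs live here and every *Ref must resolve
    within the same version (a dangling reference is a validation error)."""

    oid: str
    name: str
    study_event_defs: list[StudyEventDef] = field(default_factory=list)
    form_defs: list[FormDef] = field(default_factory=list)
    item_group_defs: list[ItemGroupDef] = field(default_factory=list)
    item_defs: list[ItemDef] = field(default_factory=list)
    code_lists: list[CodeListDef] = field(default_factory=list)

    def form(self, oid: str) -> FormDef:
        return _lookup(self.form_defs, oid, "FormDef")

    def item_group(self, oid: str) -> ItemGroupDef:
        return _lookup(self.item_group_defs, oid, "ItemGroupDef")

    def item(self, oid: str) -> ItemDef:
        return _lookup(self.item_defs, oid, "ItemDef")

    def code_list(self, oid: str) -> CodeListDef:
        return _lookup(self.code_lists, oid, "CodeList")


def _lookup(defs, oid: str, kind: str):
    for d in defs:
        if d.oid == oid:
            return d
    raise ResolutionError(f"{kind} with OID {oid!r} is not defined in this MetaDataVersion")


@dataclass
class Study:
    oid: str
    name: str
    metadata_versions: list[MetaDataVersion] = field(default_factory=list)


@dataclass
class ODMDocument:
    source_name: str
    odm_version: str
    studies: list[Study] = field(default_factory=list)


@dataclass(frozen=True)
class ValueDomain:
    """An item's value domain: its ODM data type plus the optional resolved
    code list.  Derived via :func:`value_domain_of`, never stored on its own."""

    data_type: str
    code_list: Optional[CodeListDef] = None


def value_domain_of(item: ItemDef, version: MetaDataVersion) -> ValueDomain:
    """Resolve ``item``'s value domain within ``version``.

    Raises :class:`ResolutionError` (naming the OID) if the item references a
    code list that is not defined in the version.
    """
    if item.codelist_oid is None:
        return ValueDomain(item.data_type, None)
    return ValueDomain(item.data_type, version.code_list(item.codelist_oid))
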