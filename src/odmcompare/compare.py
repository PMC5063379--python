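"""Pairwise item classification and the all-pairs comparison driver.

Every item occurrence across a form set is resolved to a
:class:`ResolvedItem` (item definition + value domain + provenance) and all
pairs of *coded* items are classified into one of five similarity levels;
items without any semantic annotation are marked NOTCODED and excluded from
pairing.  The decision gates, evaluated in order:

1. unequal concept domains                              -> DIFFERENT
2. code-list concepts do not correspond, or the item
   data types differ                                    -> SIMILAR
3. otherwise the pair is at least                       -> TRANSFORMABLE
   (data can be merged after a value transformation)
4. code-list data types equal and coded values of
   corresponding code-list entries equal                -> MATCHING
   (data can be merged as-is)
5. additionally item names and code-list names equal,
   case-insensitively                                   -> IDENTICAL

Code-list concept correspondence: two absent lists correspond trivially; one
absent list breaks it; two present lists correspond iff the multiset of
per-entry concept-code sets is the same on both sides (multiset, so
duplicated signatures must occur equally often — this is what makes the
entry-to-entry bijection well defined).
"""

from __future__ import annotations

import enum
import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .model import (
    CodeListDef,
    ItemDef,
    MetaDataVersion,
    ODMDocument,
    ValueDomain,
    value_domain_of,
)

__all__ = [
    "Relationship",
    "Provenance",
    "ResolvedItem",
    "CodeListCorrespondence",
    "PairComparison",
    "ComparisonResult",
    "NoStudyMetadataError",
    "UncodedItemError",
    "resolve_items",
    "codelist_correspondence",
    "classify_pair",
    "compare_all",
]


class Relationship(enum.IntEnum):
    """Six-valued, totally ordered similarity classification of an item pair.

    NOTCODED marks items excluded from comparison; the five remaining levels
    order from DIFFERENT (distinct medical concepts) up to IDENTICAL (same
    concept domain, value domain and names).
    """

    NOTCODED = 0
    DIFFERENT = 1
    SIMILAR = 2
    TRANSFORMABLE = 3
    MATCHING = 4
    IDENTICAL = 5

    def __str__(self) -> str:
        return self.name


class NoStudyMetadataError(ValueError):
    """The given documents contain no forms to compare."""


class UncodedItemError(ValueError):
    """classify_pair was called with an item lacking semantic annotation."""


@dataclass(frozen=True)
class Provenance:
    """Where an item occurrence lives: file, study, metadata version, form,
    group, and its 1-based position within the form."""

    file_name: str
    study_name: str
    form_name: str
    group_name: str
    position_in_form: int
    metadata_version: str = ""

    def __post_init__(self) -> None:
        if self.position_in_form < 1:
            raise ValueError("position_in_form must be >= 1")

    @property
    def column_key(self) -> tuple[str, str, str]:
        """(file, study, form) identity used for report columns."""
        return (self.file_name, self.study_name, self.form_name)


@dataclass(frozen=True)
class ResolvedItem:
    """An item occurrence: the same ItemDef referenced twice in one form
    yields two ResolvedItems with distinct positions."""

    item: ItemDef
    value_domain: ValueDomain
    provenance: Provenance

    @property
    def is_coded(self) -> bool:
        return self.item.concept_domain.is_coded


@dataclass(frozen=True)
class CodeListCorrespondence:
    """Outcome of matching two optional code lists entry-by-entry.

    The value/datatype/name flags are meaningful only when
    ``concepts_match``; the bijection pairs entries with equal concept
    signatures (ties broken by ascending coded value)."""

    concepts_match: bool
    bijection: tuple[tuple[str, str], ...] = ()  # (coded_value_a, coded_value_b)
    values_match: bool = False
    datatypes_match: bool = False
    names_match: bool = False


def _names_equal(a: str, b: str) -> bool:
    # case-insensitive, surrounding whitespace trimmed; internal spacing counts
    return a.strip().casefold() == b.strip().casefold()


def codelist_correspondence(
    cl_a: Optional[CodeListDef], cl_b: Optional[CodeListDef]
) -> CodeListCorrespondence:
    """Match two optional code lists as required by gates 2-5.

    Both absent: vacuously true on all flags.  Exactly one absent: concepts
    do not correspond.  Both present: concepts correspond iff the multiset
    of per-entry concept-code sets is identical; entries are then paired
    within each signature by ascending coded value.
    """
    if cl_a is None and cl_b is None:
        return CodeListCorrespondence(
            concepts_match=True, values_match=True, datatypes_match=True, names_match=True
        )
    if cl_a is None or cl_b is None:
        return CodeListCorrespondence(concepts_match=False)

    sig_a = Counter(it.concept_domain for it in cl_a.items)
    sig_b = Counter(it.concept_domain for it in cl_b.items)
    if sig_a != sig_b:
        return CodeListCorrespondence(concepts_match=False)

    bijection: list[tuple[str, str]] = []
    by_sig_a: dict = {}
    by_sig_b: dict = {}
    for it in cl_a.items:
        by_sig_a.setdefault(it.concept_domain, []).append(it.coded_value)
    for it in cl_b.items:
        by_sig_b.setdefault(it.concept_domain, []).append(it.coded_value)
    for sig in by_sig_a:
        for va, vb in zip(sorted(by_sig_a[sig]), sorted(by_sig_b[sig])):
            bijection.append((va, vb))

    values_match = all(va == vb for va, vb in bijection)
    return CodeListCorrespondence(
        concepts_match=True,
        bijection=tuple(bijection),
        values_match=values_match,
        datatypes_match=cl_a.data_type == cl_b.data_type,
        names_match=_names_equal(cl_a.name, cl_b.name),
    )


def classify_pair(a: ResolvedItem, b: ResolvedItem) -> Relationship:
    """Classify a pair of coded item occurrences (gates 1-5 in order).

    Raises :class:`UncodedItemError` if either item has an empty concept
    domain — NOTCODED items must be filtered out before pairing.
    """
    if not a.is_coded or not b.is_coded:
        raise UncodedItemError(
            "classify_pair requires semantically coded items; "
            "NOTCODED items are excluded from comparison"
        )

    if a.item.concept_domain != b.item.concept_domain:
        return Relationship.DIFFERENT

    corr = codelist_correspondence(a.value_domain.code_list, b.value_domain.code_list)
    if not corr.concepts_match or a.item.data_type != b.item.data_type:
        return Relationship.SIMILAR

    if not (corr.datatypes_match and corr.values_match):
        return Relationship.TRANSFORMABLE

    if _names_equal(a.item.name, b.item.name) and corr.names_match:
        return Relationship.IDENTICAL
    return Relationship.MATCHING


@dataclass(frozen=True)
class PairComparison:
    a: ResolvedItem
    b: ResolvedItem
    relationship: Relationship


@dataclass
class ComparisonResult:
    """All pairwise classifications over a form set.

    ``pairs`` covers all C(n,2) unordered pairs of coded items — including
    pairs within one form and within one file; ``counts_by_level`` sums to
    ``len(pairs)``.
    """

    items: list[ResolvedItem]
    not_coded: list[ResolvedItem] = field(default_factory=list)
    pairs: list[PairComparison] = field(default_factory=list)
    counts_by_level: dict[Relationship, int] = field(default_factory=dict)

    @property
    def coded_items(self) -> list[ResolvedItem]:
        return [it for it in self.items if it.is_coded]


def resolve_items(docs: Iterable[ODMDocument]) -> list[ResolvedItem]:
    """Resolve every item occurrence across every (file, study, metadata
    version, form), in document order.

    Forms not referenced by any StudyEvent are still included; an ItemDef
    referenced from several groups (or twice in one group) yields one
    occurrence per reference, with positions numbered per form.
    """
    out: list[ResolvedItem] = []
    for doc in docs:
        for study in doc.studies:
            for mdv in study.metadata_versions:
                for form in mdv.form_defs:
                    position = 0
                    for ig_oid in form.item_group_refs:
                        group = mdv.item_group(ig_oid)
                        for item_oid in group.item_refs:
                            item = mdv.item(item_oid)
                            position += 1
                            out.append(
                                ResolvedItem(
                                    item=item,
                                    value_domain=value_domain_of(item, mdv),
                                    provenance=Provenance(
                                        file_name=doc.source_name,
                                        study_name=study.name,
                                        form_name=form.name,
                                        group_name=group.name,
                                        position_in_form=position,
                                        metadata_version=mdv.name,
                                    ),
                                )
                            )
    return out


def compare_all(docs: Sequence[ODMDocument]) -> ComparisonResult:
    """Classify all pairs of coded item occurrences across the form set."""
    items = resolve_items(docs)
    if not any(mdv.form_defs for d in docs for s in d.studies for mdv in s.metadata_versions):
        raise NoStudyMetadataError("no study metadata: the given documents define no forms")

    coded = [it for it in items if it.is_coded]
    not_coded = [it for it in items if not it.is_coded]

    pairs = [
        PairComparison(a, b, classify_pair(a, b))
        for a, b in itertools.combinations(coded, 2)
    ]
    counts: dict[Relationship, int] = {
        level: 0 for level in Relationship if level is not Relationship.NOTCODED
    }
    for p in pairs:
        counts[p.relationship] += 1
    return ComparisonResult(items=items, not_coded=not_coded, pairs=pairs, counts_by_level=counts)
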