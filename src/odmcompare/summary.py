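"""Content summaries of a form set: the per-group item counts ("Short
Summary") and the per-file structure report showing how ODM definitions
reference each other."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .model import MetaDataVersion, ODMDocument

__all__ = [
    "ShortSummaryRow",
    "StructureNode",
    "StructureReport",
    "short_summary",
    "structure_summary",
    "render_short_summary_text",
    "short_summary_csv_rows",
]

#: sentinel group name for the per-form total row
TOTAL = "Total"


@dataclass(frozen=True)
class ShortSummaryRow:
    """One (file, form, item group) line of the Short Summary.

    ``item_count`` is the number of ItemRefs presented by that group within
    that form — a documentation-effort view, so items referenced from
    several groups count once per referencing group.  Rows whose
    ``item_group_name`` equals :data:`TOTAL` carry the per-form total.
    """

    file_name: str
    form_name: str
    item_group_name: str
    item_count: int

    @property
    def is_total(self) -> bool:
        return self.item_group_name == TOTAL


def short_summary(docs: Iterable[ODMDocument]) -> list[ShortSummaryRow]:
    """One row per (file, form, item group) in document order, plus a total
    row per form.  Forms not referenced by any StudyEvent are included."""
    rows: list[ShortSummaryRow] = []
    for doc in docs:
        for study in doc.studies:
            for mdv in study.metadata_versions:
                for form in mdv.form_defs:
                    total = 0
                    for ig_oid in form.item_group_refs:
                        group = mdv.item_group(ig_oid)
                        n = len(group.item_refs)
                        total += n
                        rows.append(
                            ShortSummaryRow(doc.source_name, form.name, group.name, n)
                        )
                    rows.append(ShortSummaryRow(doc.source_name, form.name, TOTAL, total))
    return rows


def render_short_summary_text(rows: list[ShortSummaryRow]) -> str:
    """Aligned plain-text rendering, grouped by file and form."""
    lines: list[str] = []
    current: tuple[str, str] | None = None
    width = max([len(r.item_group_name) for r in rows], default=10)
    for r in rows:
        key = (r.file_name, r.form_name)
        if key != current:
            if current is not None:
                lines.append("")
            lines.append(f"{r.file_name} — {r.form_name}")
            current = key
        lines.append(f"  {r.item_group_name.ljust(width)}  {r.item_count:>5d}")
    return "\n".join(lines)


def short_summary_csv_rows(rows: list[ShortSummaryRow]) -> list[dict]:
    return [
        {
            "file": r.file_name,
            "form": r.form_name,
            "item_group": r.item_group_name,
            "item_count": r.item_count,
        }
        for r in rows
    ]


@dataclass
class StructureNode:
    """A node of the reference tree FormDef -> ItemGroupDef -> ItemDef ->
    CodeList, with the count of direct children."""

    kind: str
    oid: str
    name: str
    children: list["StructureNode"] = field(default_factory=list)

    @property
    def child_count(self) -> int:
        return len(self.children)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "oid": self.oid,
            "name": self.name,
            "count": self.child_count,
            "children": [c.to_dict() for c in self.children],
        }


@dataclass
class StructureReport:
    """Per-file structure: studies/events/metadata versions echoed, the full
    reference tree with per-node counts, and defs never referenced."""

    file_name: str
    studies: list[dict] = field(default_factory=list)
    trees: list[StructureNode] = field(default_factory=list)
    orphans: list[dict] = field(default_factory=list)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(
            {
                "file": self.file_name,
                "studies": self.studies,
                "forms": [t.to_dict() for t in self.trees],
                "orphans": self.orphans,
            },
            indent=indent,
        )

    def as_text(self) -> str:
        lines = [f"File: {self.file_name}"]
        for s in self.studies:
            lines.append(f"Study {s['oid']} ({s['name']})")
            for mdv in s["metadata_versions"]:
                lines.append(f"  MetaDataVersion {mdv['oid']} ({mdv['name']})")
                for ev in mdv["study_events"]:
                    lines.append(f"    StudyEvent {ev['oid']} ({ev['name']})")
        for t in self.trees:
            _render_node(t, lines, indent=0)
        if self.orphans:
            lines.append("Orphan definitions (never referenced):")
            for o in self.orphans:
                lines.append(f"  {o['kind']} {o['oid']} ({o['name']})")
        return "\n".join(lines)


def _render_node(node: StructureNode, lines: list[str], indent: int) -> None:
    pad = "  " * indent
    lines.append(f"{pad}{node.kind} {node.name} [{node.oid}] ({node.child_count})")
    for c in node.children:
        _render_node(c, lines, indent + 1)


def structure_summary(doc: ODMDocument) -> StructureReport:
    """Build the reference tree and orphan list for one document.

    Pure and idempotent: the same document always yields an identical
    report."""
    report = StructureReport(file_name=doc.source_name)
    for study in doc.studies:
        report.studies.append(
            {
                "oid": study.oid,
                "name": study.name,
                "metadata_versions": [
                    {
                        "oid": mdv.oid,
                        "name": mdv.name,
                        "study_events": [
                            {"oid": ev.oid, "name": ev.name, "form_refs": list(ev.form_refs)}
                            for ev in mdv.study_event_defs
                        ],
                    }
                    for mdv in study.metadata_versions
                ],
            }
        )
        for mdv in study.metadata_versions:
            referenced: set[tuple[str, str]] = set()
            for ev in mdv.study_event_defs:
                for form_oid in ev.form_refs:
                    referenced.add(("FormDef", form_oid))
            # forms not referenced by any event are still summarized, but
            # count as orphans: nothing points at them
            for form in mdv.form_defs:
                report.trees.append(_form_tree(form.oid, mdv, referenced))
            _collect_orphans(mdv, referenced, report.orphans)
    return report


def _form_tree(form_oid: str, mdv: MetaDataVersion, referenced: set) -> StructureNode:
    form = mdv.form(form_oid)
    form_node = StructureNode("Form", form.oid, form.name)
    for ig_oid in form.item_group_refs:
        group = mdv.item_group(ig_oid)
        referenced.add(("ItemGroupDef", group.oid))
        group_node = StructureNode("ItemGroup", group.oid, group.name)
        for item_oid in group.item_refs:
            item = mdv.item(item_oid)
            referenced.add(("ItemDef", item.oid))
            item_node = StructureNode("Item", item.oid, item.name)
            if item.codelist_oid is not None:
                cl = mdv.code_list(item.codelist_oid)
                referenced.add(("CodeList", cl.oid))
                item_node.children.append(StructureNode("CodeList", cl.oid, cl.name))
            group_node.children.append(item_node)
        form_node.children.append(group_node)
    return form_node


def _collect_orphans(mdv: MetaDataVersion, referenced: set, orphans: list[dict]) -> None:
    pools = [
        ("FormDef", mdv.form_defs),
        ("ItemGroupDef", mdv.item_group_defs),
        ("ItemDef", mdv.item_defs),
        ("CodeList", mdv.code_lists),
    ]
    for kind, defs in pools:
        for d in defs:
            if (kind, d.oid) not in referenced:
                orphans.append({"kind": kind, "oid": d.oid, "name": d.name})
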