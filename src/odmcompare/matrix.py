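"""The comparable-items matrix and per-level pair listings, with exports.

Rows of the matrix are groups of coded items sharing one exact concept
domain (a well-defined equivalence: any relationship at SIMILAR or above
requires equal concept domains, and concept-domain equality is transitive).
Columns are the (file, study, form) sources in input order; a cell holds the
number of occurrences of the row's concept in that form — a count above one
corresponds to the "column is split" rendering, where a form carrying a
concept twice gets one mark per occurrence.
"""

from __future__ import annotations

import html as _html
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .compare import ComparisonResult, PairComparison, Relationship, ResolvedItem, classify_pair
from .model import ConceptDomain
from .summary import ShortSummaryRow, short_summary_csv_rows

__all__ = [
    "ConceptGroup",
    "ComparableMatrix",
    "build_matrix",
    "list_pairs_by_level",
    "export_report",
    "matrix_to_frame",
    "pairs_to_frame",
]

#: five coded levels in descending order, as presented in reports
CODED_LEVELS = (
    Relationship.IDENTICAL,
    Relationship.MATCHING,
    Relationship.TRANSFORMABLE,
    Relationship.SIMILAR,
    Relationship.DIFFERENT,
)


@dataclass
class ConceptGroup:
    """Coded items sharing one exact concept domain; ``label`` is the name
    of the first member in (file order, document order)."""

    key: ConceptDomain
    label: str
    members: list[ResolvedItem] = field(default_factory=list)


@dataclass
class ComparableMatrix:
    """rows x columns occurrence matrix of comparable concepts.

    ``cells[i][j]`` counts occurrences of row i's concept in column j's
    form; ``cell_levels[i][j]`` carries the best relationship between the
    row's label item and that cell's items (None for empty cells)."""

    rows: list[ConceptGroup]
    columns: list[tuple[str, str, str]]  # (file, study, form) in input order
    cells: list[list[int]]
    cell_levels: list[list[Optional[Relationship]]]

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.rows), len(self.columns))


def build_matrix(
    result: ComparisonResult, min_level: Relationship = Relationship.SIMILAR
) -> ComparableMatrix:
    """Group coded items by exact concept domain and keep groups with >= 2
    members whose best pairwise level reaches ``min_level``.

    ``min_level`` must be SIMILAR or above (DIFFERENT pairs are never
    "comparable").  Row order follows first appearance; an empty matrix is a
    valid outcome.
    """
    if min_level < Relationship.SIMILAR:
        raise ValueError("min_level must be SIMILAR or above")

    columns: list[tuple[str, str, str]] = []
    for it in result.items:
        key = it.provenance.column_key
        if key not in columns:
            columns.append(key)

    groups: dict[ConceptDomain, ConceptGroup] = {}
    order: list[ConceptDomain] = []
    for it in result.coded_items:
        dom = it.item.concept_domain
        if dom not in groups:
            groups[dom] = ConceptGroup(key=dom, label=it.item.name)
            order.append(dom)
        groups[dom].members.append(it)

    kept: list[ConceptGroup] = []
    for dom in order:
        g = groups[dom]
        if len(g.members) < 2:
            continue
        best = max(
            classify_pair(a, b)
            for i, a in enumerate(g.members)
            for b in g.members[i + 1 :]
        )
        if best >= min_level:
            kept.append(g)

    col_index = {key: j for j, key in enumerate(columns)}
    cells = [[0] * len(columns) for _ in kept]
    cell_levels: list[list[Optional[Relationship]]] = [
        [None] * len(columns) for _ in kept
    ]
    for i, g in enumerate(kept):
        anchor = g.members[0]
        for member in g.members:
            j = col_index[member.provenance.column_key]
            cells[i][j] += 1
            # the group's label item compared to itself is trivially IDENTICAL
            level = (
                Relationship.IDENTICAL
                if member is anchor
                else classify_pair(anchor, member)
            )
            prev = cell_levels[i][j]
            cell_levels[i][j] = level if prev is None else max(prev, level)

    return ComparableMatrix(rows=kept, columns=columns, cells=cells, cell_levels=cell_levels)


def list_pairs_by_level(result: ComparisonResult) -> dict[Relationship, list[PairComparison]]:
    """Pairs grouped by similarity level, in the order reports present them.

    NOTCODED items are not pairs and are listed separately
    (``result.not_coded``)."""
    out: dict[Relationship, list[PairComparison]] = {lv: [] for lv in CODED_LEVELS}
    for p in result.pairs:
        out[p.relationship].append(p)
    return out


# ---------------------------------------------------------------------------
# Tabular renderings


def _column_label(key: tuple[str, str, str]) -> str:
    file_name, study, form = key
    return f"{study} / {form} ({file_name})"


def matrix_to_frame(matrix: ComparableMatrix) -> pd.DataFrame:
    """Matrix as a DataFrame: item, codes, then one integer column per form."""
    data = {
        "item": [g.label for g in matrix.rows],
        "codes": [" ".join(sorted(g.key.codes)) for g in matrix.rows],
    }
    for j, key in enumerate(matrix.columns):
        data[_column_label(key)] = [matrix.cells[i][j] for i in range(len(matrix.rows))]
    return pd.DataFrame(data)


def _item_detail(it: ResolvedItem) -> str:
    codes = " ".join(sorted(it.item.concept_domain.codes))
    return f"{it.item.name} [{it.item.data_type}] {codes}"


def pairs_to_frame(pairs: list[PairComparison]) -> pd.DataFrame:
    rows = []
    for p in pairs:
        rows.append(
            {
                "relationship": str(p.relationship),
                "item_a": p.a.item.name,
                "file_a": p.a.provenance.file_name,
                "form_a": p.a.provenance.form_name,
                "datatype_a": p.a.item.data_type,
                "codes_a": " ".join(sorted(p.a.item.concept_domain.codes)),
                "item_b": p.b.item.name,
                "file_b": p.b.provenance.file_name,
                "form_b": p.b.provenance.form_name,
                "datatype_b": p.b.item.data_type,
                "codes_b": " ".join(sorted(p.b.item.concept_domain.codes)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "relationship",
            "item_a",
            "file_a",
            "form_a",
            "datatype_a",
            "codes_a",
            "item_b",
            "file_b",
            "form_b",
            "datatype_b",
            "codes_b",
        ],
    )


def _notcoded_frame(result: ComparisonResult) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "item": it.item.name,
                "file": it.provenance.file_name,
                "form": it.provenance.form_name,
                "datatype": it.item.data_type,
            }
            for it in result.not_coded
        ],
        columns=["item", "file", "form", "datatype"],
    )


FORMATS = ("csv", "tsv", "html", "xlsx")


def export_report(
    matrix: ComparableMatrix,
    listings: dict[Relationship, list[PairComparison]],
    summary_rows: list[ShortSummaryRow],
    format: str,
    dest: str | Path,
    result: Optional[ComparisonResult] = None,
) -> list[Path]:
    """Write the report sections in the requested format; returns the files
    written.

    csv/tsv: one file per section, matrix cells as integer counts.
    html: a single standalone page with one tab per section, matrix marks
    rendered as repeated "x" with hover details.  xlsx: one sheet per
    section.
    """
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)

    frames: dict[str, pd.DataFrame] = {
        "short_summary": pd.DataFrame(
            short_summary_csv_rows(summary_rows),
            columns=["file", "form", "item_group", "item_count"],
        ),
        "comparable_items": matrix_to_frame(matrix),
    }
    for level in CODED_LEVELS:
        frames[f"pairs_{str(level).lower()}"] = pairs_to_frame(listings.get(level, []))
    if result is not None:
        frames["notcoded"] = _notcoded_frame(result)

    written: list[Path] = []
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        for name, frame in frames.items():
            path = dest / f"{name}.{format}"
            frame.to_csv(path, sep=sep, index=False)
            written.append(path)
    elif format == "xlsx":
        path = dest / "report.xlsx"
        with pd.ExcelWriter(path, engine="openpyxl") as writer:
            for name, frame in frames.items():
                frame.to_excel(writer, sheet_name=name[:31], index=False)
        written.append(path)
    else:
        path = dest / "report.html"
        path.write_text(_render_html(matrix, listings, frames), encoding="utf-8")
        written.append(path)
    return written


_HTML_HEAD = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>Form comparison report</title>
<style>
body { font-family: sans-serif; margin: 1.5em; }
nav a { margin-right: 1em; }
table { border-collapse: collapse; margin: 1em 0; }
th, td { border: 1px solid #999; padding: 0.3em 0.6em; text-align: left; }
td.mark { text-align: center; font-weight: bold; }
</style></head><body>
<nav>%(nav)s</nav>
"""


def _render_html(
    matrix: ComparableMatrix,
    listings: dict[Relationship, list[PairComparison]],
    frames: dict[str, pd.DataFrame],
) -> str:
    sections = ["short_summary", "comparable_items"] + [
        f"pairs_{str(lv).lower()}" for lv in CODED_LEVELS
    ]
    if "notcoded" in frames:
        sections.append("notcoded")
    nav = " | ".join(f'<a href="#{s}">{s.replace("_", " ").title()}</a>' for s in sections)
    parts = [_HTML_HEAD % {"nav": nav}]

    for s in sections:
        parts.append(f'<h2 id="{s}">{s.replace("_", " ").title()}</h2>')
        if s == "comparable_items":
            parts.append(_matrix_html(matrix))
        else:
            parts.append(frames[s].to_html(index=False, border=0))
    parts.append("</body></html>")
    return "\n".join(parts)


def _matrix_html(matrix: ComparableMatrix) -> str:
    """Cells as repeated "x" marks (one per occurrence) with tooltip detail
    per item (name, data type, codes) and the per-cell relationship."""
    head = "".join(
        f"<th>{_html.escape(_column_label(key))}</th>" for key in matrix.columns
    )
    lines = [
        "<table>",
        f"<tr><th>item</th><th>codes</th>{head}</tr>",
    ]
    for i, g in enumerate(matrix.rows):
        codes = _html.escape(" ".join(sorted(g.key.codes)))
        cells = []
        for j, key in enumerate(matrix.columns):
            n = matrix.cells[i][j]
            if n == 0:
                cells.append("<td></td>")
                continue
            level = matrix.cell_levels[i][j]
            detail = "; ".join(
                _item_detail(m) for m in g.members if m.provenance.column_key == key
            )
            title = _html.escape(f"{level}: {detail}")
            cells.append(f'<td class="mark" title="{title}">{"x" * n}</td>')
        lines.append(
            f"<tr><td>{_html.escape(g.label)}</td><td>{codes}</td>{''.join(cells)}</tr>"
        )
    lines.append("</table>")
    return "\n".join(lines)
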