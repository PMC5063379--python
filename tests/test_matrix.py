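"""The comparable-items matrix, per-level listings, and exports."""

import csv

import pytest

from odmcompare.compare import Relationship, classify_pair, compare_all
from odmcompare.matrix import (
    build_matrix,
    export_report,
    list_pairs_by_level,
    matrix_to_frame,
)
from odmcompare.model import (
    ConceptDomain,
    FormDef,
    ItemDef,
    ItemGroupDef,
    MetaDataVersion,
    ODMDocument,
    Study,
)

from .conftest import make_codelist


def _form_doc(file_name, form_name, item_specs):
    """item_specs: list of (name, data_type, codes, codelist|None, repeat)."""
    mdv = MetaDataVersion(oid="MDV.1", name="v1")
    group = ItemGroupDef("IG.1", "Main")
    mdv.item_group_defs.append(group)
    mdv.form_defs.append(FormDef("F.1", form_name, item_group_refs=["IG.1"]))
    for k, (name, dt, codes, cl, repeat) in enumerate(item_specs):
        oid = f"I.{k}"
        mdv.item_defs.append(
            ItemDef(oid, name, dt, ConceptDomain(codes), cl.oid if cl else None)
        )
        if cl is not None:
            mdv.code_lists.append(cl)
        for _ in range(repeat):
            group.item_refs.append(oid)
    return ODMDocument(file_name, "1.3.2", [Study("S.1", form_name, [mdv])])


@pytest.fixture
def chemo_three_forms():
    """Three single-item forms all carrying a concept-identical item."""
    cl = make_codelist(entries=[("1", ["Cyes"]), ("0", ["Cno"])])
    docs = [
        _form_doc(
            f"reg{k}.xml",
            f"Registry {k}",
            [("Chemotherapy", "integer", ("C0013216",), cl, 1)],
        )
        for k in range(1, 4)
    ]
    return compare_all(docs)


class TestBuildMatrix:
    def test_one_row_three_columns_single_marks(self, chemo_three_forms):
        matrix = build_matrix(chemo_three_forms)
        assert matrix.shape == (1, 3)
        assert matrix.cells == [[1, 1, 1]]
        assert matrix.rows[0].label == "Chemotherapy"
        assert matrix.cell_levels[0] == [Relationship.IDENTICAL] * 3

    def test_repeated_occurrence_splits_cell_count(self):
        cl = make_codelist(entries=[("1", ["Cyes"]), ("0", ["Cno"])])
        docs = [
            _form_doc("fin.xml", "Finnish Registry", [("surgery", "integer", ("C0038895",), cl, 2)]),
            _form_doc("a.xml", "Registry A", [("surgery", "integer", ("C0038895",), cl, 1)]),
            _form_doc("b.xml", "Registry B", [("surgery", "integer", ("C0038895",), cl, 1)]),
        ]
        matrix = build_matrix(compare_all(docs))
        assert matrix.cells == [[2, 1, 1]]

    def test_no_concept_overlap_yields_empty_matrix(self):
        docs = [
            _form_doc("a.xml", "A", [("X", "text", ("C1",), None, 1)]),
            _form_doc("b.xml", "B", [("Y", "text", ("C2",), None, 1)]),
        ]
        matrix = build_matrix(compare_all(docs))
        assert matrix.shape[0] == 0

    def test_min_level_filters_rows(self):
        # same concept but different datatypes -> best level SIMILAR
        docs = [
            _form_doc("a.xml", "A", [("X", "integer", ("C1",), None, 1)]),
            _form_doc("b.xml", "B", [("X", "string", ("C1",), None, 1)]),
        ]
        result = compare_all(docs)
        assert build_matrix(result, Relationship.SIMILAR).shape[0] == 1
        assert build_matrix(result, Relationship.TRANSFORMABLE).shape[0] == 0

    def test_min_level_below_similar_rejected(self, chemo_three_forms):
        with pytest.raises(ValueError):
            build_matrix(chemo_three_forms, Relationship.DIFFERENT)

    def test_row_members_all_classify_similar_or_better(self, chemo_three_forms):
        matrix = build_matrix(chemo_three_forms)
        for g in matrix.rows:
            for i, a in enumerate(g.members):
                for b in g.members[i + 1 :]:
                    assert classify_pair(a, b) >= Relationship.SIMILAR


class TestListings:
    def test_sections_sized_by_level(self):
        cl = make_codelist(entries=[("1", ["Cy"]), ("0", ["Cn"])])
        docs = [
            _form_doc(
                "one.xml",
                "One",
                [
                    ("surgery", "integer", ("C0038895",), cl, 2),
                    ("weight", "float", ("C0005910",), None, 1),
                ],
            )
        ]
        listings = list_pairs_by_level(compare_all(docs))
        assert len(listings[Relationship.IDENTICAL]) == 1
        assert len(listings[Relationship.DIFFERENT]) == 2
        assert len(listings[Relationship.SIMILAR]) == 0

    def test_uncoded_only_input_has_empty_listings(self):
        docs = [
            _form_doc("u.xml", "U", [("A", "text", (), None, 1), ("B", "text", (), None, 1)])
        ]
        result = compare_all(docs)
        listings = list_pairs_by_level(result)
        assert all(len(v) == 0 for v in listings.values())
        assert len(result.not_coded) == 2


class TestExport:
    def test_csv_matrix_round_trip(self, chemo_three_forms, tmp_path):
        matrix = build_matrix(chemo_three_forms)
        listings = list_pairs_by_level(chemo_three_forms)
        export_report(matrix, listings, [], "csv", tmp_path, result=chemo_three_forms)
        with open(tmp_path / "comparable_items.csv", newline="") as fh:
            rows = list(csv.reader(fh))
        assert rows[0][:2] == ["item", "codes"]
        assert rows[1][0] == "Chemotherapy"
        counts = [[int(v) for v in row[2:]] for row in rows[1:]]
        assert counts == matrix.cells

    def test_empty_matrix_csv_is_header_only(self, tmp_path):
        docs = [
            _form_doc("a.xml", "A", [("X", "text", ("C1",), None, 1)]),
            _form_doc("b.xml", "B", [("Y", "text", ("C2",), None, 1)]),
        ]
        result = compare_all(docs)
        export_report(build_matrix(result), list_pairs_by_level(result), [], "csv", tmp_path)
        with open(tmp_path / "comparable_items.csv", newline="") as fh:
            rows = list(csv.reader(fh))
        assert len(rows) == 1

    def test_html_renders_one_mark_per_occurrence(self, chemo_three_forms, tmp_path):
        matrix = build_matrix(chemo_three_forms)
        export_report(matrix, list_pairs_by_level(chemo_three_forms), [], "html", tmp_path)
        html = (tmp_path / "report.html").read_text()
        assert html.count('<td class="mark"') == 3
        assert 'title="IDENTICAL' in html  # hover detail carries the level

    def test_xlsx_has_one_sheet_per_section(self, chemo_three_forms, tmp_path):
        import openpyxl

        matrix = build_matrix(chemo_three_forms)
        export_report(matrix, list_pairs_by_level(chemo_three_forms), [], "xlsx", tmp_path)
        wb = openpyxl.load_workbook(tmp_path / "report.xlsx")
        assert "comparable_items" in wb.sheetnames
        assert "pairs_identical" in wb.sheetnames

    def test_unknown_format_rejected(self, chemo_three_forms, tmp_path):
        with pytest.raises(ValueError, match="unknown format"):
            export_report(
                build_matrix(chemo_three_forms), {}, [], "pdf", tmp_path
            )

    def test_items_in_different_rows_are_below_similar(self, tmp_path):
        """Matrix/pair consistency: cross-row pairs never reach SIMILAR."""
        cl = make_codelist(entries=[("1", ["Cy"]), ("0", ["Cn"])])
        docs = [
            _form_doc("a.xml", "A", [("Chemo", "integer", ("C1",), cl, 1),
                                     ("Surgery", "integer", ("C2",), None, 1)]),
            _form_doc("b.xml", "B", [("Chemo", "integer", ("C1",), cl, 1),
                                     ("Surgery", "integer", ("C2",), None, 1)]),
        ]
        result = compare_all(docs)
        matrix = build_matrix(result)
        row_of = {}
        for i, g in enumerate(matrix.rows):
            for m in g.members:
                row_of[id(m)] = i
        for p in result.pairs:
            ra, rb = row_of.get(id(p.a)), row_of.get(id(p.b))
            if ra is not None and rb is not None and ra != rb:
                assert p.relationship < Relationship.SIMILAR
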