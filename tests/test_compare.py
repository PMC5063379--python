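"""The pairwise classification gates and the all-pairs driver."""

import pytest

from odmcompare.compare import (
    NoStudyMetadataError,
    Relationship,
    UncodedItemError,
    classify_pair,
    codelist_correspondence,
    compare_all,
)
from odmcompare.model import (
    CodeListDef,
    CodeListItemDef,
    ConceptDomain,
    FormDef,
    ItemDef,
    ItemGroupDef,
    MetaDataVersion,
    ODMDocument,
    Study,
)
from odmcompare.odm_io import parse_odm

from .conftest import SEX_ODM, make_codelist, make_item


def test_relationship_total_order():
    R = Relationship
    assert R.NOTCODED < R.DIFFERENT < R.SIMILAR < R.TRANSFORMABLE < R.MATCHING < R.IDENTICAL


class TestClassifyPair:
    def test_byte_identical_copies_in_two_files_are_identical(self, sex_odm_bytes, tmp_path):
        a = tmp_path / "a.xml"
        b = tmp_path / "b.xml"
        a.write_bytes(sex_odm_bytes)
        b.write_bytes(sex_odm_bytes)
        result = compare_all([parse_odm(a), parse_odm(b)])
        assert result.counts_by_level[Relationship.IDENTICAL] == 1
        assert len(result.pairs) == 1

    def test_disjoint_concept_domains_are_different(self):
        a = make_item(codes=("C1",))
        b = make_item(codes=("C2",), file_name="b.xml")
        assert classify_pair(a, b) is Relationship.DIFFERENT

    def test_same_concepts_but_shifted_coded_values_are_transformable(self):
        cl_a = make_codelist(entries=[("1", ["Cx1"]), ("2", ["Cx2"])])
        cl_b = make_codelist(oid="CL.2", entries=[("0", ["Cx1"]), ("1", ["Cx2"])])
        a = make_item(codes=("C0150831",), codelist=cl_a)
        b = make_item(codes=("C0150831",), codelist=cl_b, file_name="b.xml")
        assert classify_pair(a, b) is Relationship.TRANSFORMABLE

    def test_item_datatype_mismatch_caps_at_similar(self):
        cl_a = make_codelist(entries=[("1", ["Cx1"]), ("2", ["Cx2"])])
        cl_b = make_codelist(oid="CL.2", entries=[("0", ["Cx1"]), ("1", ["Cx2"])])
        a = make_item(data_type="integer", codes=("C0150831",), codelist=cl_a)
        b = make_item(data_type="string", codes=("C0150831",), codelist=cl_b, file_name="b.xml")
        assert classify_pair(a, b) is Relationship.SIMILAR

    def test_name_case_difference_is_still_identical(self):
        cl = make_codelist()
        a = make_item(name="Sex", codes=("C0150831",), codelist=cl)
        b = make_item(name="SEX", codes=("C0150831",), codelist=cl, file_name="b.xml")
        assert classify_pair(a, b) is Relationship.IDENTICAL

    def test_different_names_with_equal_value_domains_are_matching(self):
        cl = make_codelist()
        a = make_item(name="Sex", codes=("C0150831",), codelist=cl)
        b = make_item(name="Gender", codes=("C0150831",), codelist=cl, file_name="b.xml")
        assert classify_pair(a, b) is Relationship.MATCHING

    def test_codelist_name_difference_blocks_identical(self):
        cl_a = make_codelist(name="Sex")
        cl_b = make_codelist(oid="CL.2", name="Gender codes")
        a = make_item(name="Sex", codes=("C0150831",), codelist=cl_a)
        b = make_item(name="Sex", codes=("C0150831",), codelist=cl_b, file_name="b.xml")
        assert classify_pair(a, b) is Relationship.MATCHING

    def test_one_sided_codelist_caps_at_similar(self):
        a = make_item(codes=("C1",), codelist=make_codelist())
        b = make_item(codes=("C1",), file_name="b.xml")
        assert classify_pair(a, b) is Relationship.SIMILAR

    def test_codelist_datatype_mismatch_caps_at_transformable(self):
        cl_a = make_codelist(data_type="integer")
        cl_b = make_codelist(oid="CL.2", data_type="string")
        a = make_item(codes=("C1",), codelist=cl_a)
        b = make_item(codes=("C1",), codelist=cl_b, file_name="b.xml")
        assert classify_pair(a, b) is Relationship.TRANSFORMABLE

    def test_uncoded_item_is_a_contract_violation(self):
        a = make_item(codes=())
        b = make_item(codes=("C1",), file_name="b.xml")
        with pytest.raises(UncodedItemError):
            classify_pair(a, b)


class TestCodelistCorrespondence:
    def test_both_absent_is_vacuously_true(self):
        corr = codelist_correspondence(None, None)
        assert corr.concepts_match and corr.values_match
        assert corr.datatypes_match and corr.names_match

    def test_list_vs_itself_is_identity_bijection(self):
        cl = make_codelist(entries=[("1", ["Ca"]), ("2", ["Cb"])])
        corr = codelist_correspondence(cl, cl)
        assert corr.concepts_match and corr.values_match
        assert corr.datatypes_match and corr.names_match
        assert sorted(corr.bijection) == [("1", "1"), ("2", "2")]

    def test_different_lengths_break_concept_correspondence(self):
        cl_a = make_codelist(entries=[("1", ["Ca"]), ("2", ["Cb"])])
        cl_b = make_codelist(
            oid="CL.2", entries=[("1", ["Ca"]), ("2", ["Cb"]), ("3", ["Cc"])]
        )
        assert not codelist_correspondence(cl_a, cl_b).concepts_match

    def test_duplicated_signatures_must_occur_equally_often(self):
        cl_a = make_codelist(entries=[("1", ["Ca"]), ("2", ["Ca"])])
        cl_b = make_codelist(oid="CL.2", entries=[("1", ["Ca"]), ("2", ["Cb"])])
        assert not codelist_correspondence(cl_a, cl_b).concepts_match

    def test_tied_signatures_pair_by_ascending_coded_value(self):
        cl_a = make_codelist(entries=[("2", ["Ca"]), ("1", ["Ca"])])
        cl_b = make_codelist(oid="CL.2", entries=[("1", ["Ca"]), ("2", ["Ca"])])
        corr = codelist_correspondence(cl_a, cl_b)
        assert corr.concepts_match
        assert sorted(corr.bijection) == [("1", "1"), ("2", "2")]
        assert corr.values_match

    def test_empty_signatures_correspond_to_each_other(self):
        cl_a = CodeListDef("CL.1", "L", "integer", [CodeListItemDef("1")])
        cl_b = CodeListDef("CL.2", "L", "integer", [CodeListItemDef("1")])
        assert codelist_correspondence(cl_a, cl_b).concepts_match


def _single_form_doc(items_with_cl, name="doc.xml", form="Form 1"):
    """One document, one form, one group; items may repeat."""
    mdv = MetaDataVersion(oid="MDV.1", name="v1")
    group = ItemGroupDef(oid="IG.1", name="Main")
    mdv.item_group_defs.append(group)
    mdv.form_defs.append(FormDef(oid="F.1", name=form, item_group_refs=["IG.1"]))
    seen = set()
    for item, cl in items_with_cl:
        if item.oid not in seen:
            mdv.item_defs.append(item)
            seen.add(item.oid)
        if cl is not None and cl.oid not in {c.oid for c in mdv.code_lists}:
            mdv.code_lists.append(cl)
        group.item_refs.append(item.oid)
    return ODMDocument(name, "1.3.2", [Study("S.1", "Study", [mdv])])


class TestCompareAll:
    def test_repeated_item_plus_unrelated_item(self):
        """A form holding the same surgery item twice plus one unrelated
        coded item yields one IDENTICAL and two DIFFERENT pairs."""
        cl = make_codelist(entries=[("1", ["Cy"]), ("2", ["Cn"])])
        surgery = ItemDef("I.surg", "Surgery", "integer", ConceptDomain(["C0038895"]), "CL.1")
        other = ItemDef("I.other", "Weight", "float", ConceptDomain(["C0005910"]))
        doc = _single_form_doc([(surgery, cl), (surgery, cl), (other, None)])
        result = compare_all([doc])
        assert len(result.pairs) == 3
        assert result.counts_by_level[Relationship.IDENTICAL] == 1
        assert result.counts_by_level[Relationship.DIFFERENT] == 2
        positions = [it.provenance.position_in_form for it in result.items]
        assert positions == [1, 2, 3]

    def test_pairwise_distinct_concepts_and_one_uncoded(self):
        items = [
            (ItemDef(f"I.{k}", f"N{k}", "text", ConceptDomain([f"C{k}"])), None)
            for k in range(4)
        ]
        items.append((ItemDef("I.u", "Uncoded", "text", ConceptDomain()), None))
        result = compare_all([_single_form_doc(items)])
        assert len(result.not_coded) == 1
        assert len(result.pairs) == 6
        assert result.counts_by_level[Relationship.DIFFERENT] == 6

    def test_counts_sum_to_all_pairs(self, sex_odm_bytes, tmp_path):
        p = tmp_path / "a.xml"
        p.write_bytes(sex_odm_bytes)
        result = compare_all([parse_odm(p)])
        n = len(result.coded_items)
        assert sum(result.counts_by_level.values()) == n * (n - 1) // 2

    def test_no_forms_is_an_error(self):
        doc = ODMDocument("x.xml", "1.3.2", [Study("S.1", "S", [MetaDataVersion("M", "m")])])
        with pytest.raises(NoStudyMetadataError):
            compare_all([doc])
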