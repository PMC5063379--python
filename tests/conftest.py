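"""Shared fixtures: the canonical annotated "Sex" item and small helpers
for building item occurrences in memory."""

from __future__ import annotations

import pytest

from odmcompare.compare import Provenance, ResolvedItem
from odmcompare.model import (
    CodeListDef,
    CodeListItemDef,
    ConceptDomain,
    ItemDef,
    ValueDomain,
)

# The canonical demographic item: an integer-typed "Sex" field annotated with
# the UMLS concept C0150831 and a two-entry code list.  The code-list entry
# contents (values 1/2 with male/female decodes and their CUIs) are a
# synthetic completion of the published fragment, which prints only the
# item-level annotation.
SEX_ODM = """<?xml version="1.0" encoding="UTF-8"?>
<ODM xmlns="http://www.cdisc.org/ns/odm/v1.3" FileOID="sex-demo"
     FileType="Snapshot" ODMVersion="1.3.2" CreationDateTime="2016-01-01T00:00:00">
 <Study OID="S.1">
  <GlobalVariables>
   <StudyName>Demographics Demo</StudyName>
   <StudyDescription>Demographics Demo</StudyDescription>
   <ProtocolName>Demographics Demo</ProtocolName>
  </GlobalVariables>
  <MetaDataVersion OID="MDV.1" Name="Version 1">
   <Protocol><StudyEventRef StudyEventOID="SE.1" Mandatory="No"/></Protocol>
   <StudyEventDef OID="SE.1" Name="Baseline" Repeating="No" Type="Common">
    <FormRef FormOID="F.1" Mandatory="No"/>
   </StudyEventDef>
   <FormDef OID="F.1" Name="Demographics" Repeating="No">
    <ItemGroupRef ItemGroupOID="IG.1" Mandatory="No"/>
   </FormDef>
   <ItemGroupDef OID="IG.1" Name="Patient" Repeating="No">
    <ItemRef ItemOID="I.sex" Mandatory="No"/>
   </ItemGroupDef>
   <ItemDef OID="I.sex" Name="Sex" DataType="integer">
    <Question><TranslatedText xml:lang="en">Sex</TranslatedText></Question>
    <CodeListRef CodeListOID="CL.sex"/>
    <Alias Context="UMLS" Name="C0150831"/>
   </ItemDef>
   <CodeList OID="CL.sex" Name="Sex" DataType="integer">
    <CodeListItem CodedValue="1">
     <Decode><TranslatedText xml:lang="en">male</TranslatedText></Decode>
     <Alias Context="UMLS" Name="C0086582"/>
    </CodeListItem>
    <CodeListItem CodedValue="2">
     <Decode><TranslatedText xml:lang="en">female</TranslatedText></Decode>
     <Alias Context="UMLS" Name="C0086287"/>
    </CodeListItem>
   </CodeList>
  </MetaDataVersion>
 </Study>
</ODM>
"""


@pytest.fixture
def sex_odm_bytes() -> bytes:
    return SEX_ODM.encode("utf-8")


@pytest.fixture
def sex_odm_file(tmp_path, sex_odm_bytes):
    path = tmp_path / "sex_demo.xml"
    path.write_bytes(sex_odm_bytes)
    return path


def make_codelist(oid="CL.1", name="List", data_type="integer", entries=None):
    entries = entries or [("1", ["C0000001"]), ("2", ["C0000002"])]
    return CodeListDef(
        oid=oid,
        name=name,
        data_type=data_type,
        items=[
            CodeListItemDef(coded_value=v, concept_domain=ConceptDomain(codes))
            for v, codes in entries
        ],
    )


def make_item(
    name="Item",
    data_type="integer",
    codes=("C0000010",),
    codelist=None,
    file_name="a.xml",
    study="Study A",
    form="Form A",
    group="Main",
    position=1,
    oid="I.1",
):
    """Build a ResolvedItem directly, bypassing XML."""
    item = ItemDef(
        oid=oid,
        name=name,
        data_type=data_type,
        concept_domain=ConceptDomain(codes),
        codelist_oid=codelist.oid if codelist else None,
    )
    return ResolvedItem(
        item=item,
        value_domain=ValueDomain(data_type, codelist),
        provenance=Provenance(
            file_name=file_name,
            study_name=study,
            form_name=form,
            group_name=group,
            position_in_form=position,
        ),
    )
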