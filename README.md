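# odmcompare

Structured comparison of multiple medical documentation forms.

Medical forms — case report forms, registry forms, routine-care
documentation — are described in the CDISC Operational Data Model (ODM)
XML standard, and their data elements can carry semantic annotations:
UMLS concept codes attached via ODM `Alias` elements. Given a set of such
forms, `odmcompare` answers the questions a medical-informatics or
data-management team asks before merging, versioning or reusing data:
which items appear in which forms, which items are the *same* data
element, and which could be made compatible by a value transformation.

The package is aimed at people screening forms for secondary use of
routine clinical data, tracking changes across form versions, and
comparing documentation between institutions.

## The classification model

Following ISO/IEC 11179, each item has a **concept domain** (the set of
UMLS codes annotating it) and a **value domain** (its data type plus
optional code list). Every pair of annotated items is classified into one
of five levels by a fixed sequence of gates; items with no annotation are
marked NOTCODED and excluded from pairing:

| level | meaning | gate |
|---|---|---|
| DIFFERENT | different medical concepts | concept domains differ |
| SIMILAR | same concept, incompatible values | code-list concepts do not correspond, or item data types differ |
| TRANSFORMABLE | data mergeable after a transformation | concepts and data types agree, but code-list data types or coded values differ |
| MATCHING | data mergeable as-is | value domains fully agree |
| IDENTICAL | the same data element | additionally item and code-list names agree (case-insensitively) |

Two code lists "correspond" when the multiset of per-entry concept-code
sets is the same on both sides; corresponding entries are then paired
signature-by-signature to compare their coded values.

Results are rendered as a **Short Summary** (item counts per group and
form), a structure report, per-level pair listings, and a
**comparable-items matrix**: rows are shared concepts, columns are forms,
and a cell holds one mark per occurrence — a form containing a concept
twice gets two marks.

## Worked example

Generate a four-version form-set scenario, then compare it:

```sh
odmcompare synth --preset versions --out fixtures/
odmcompare compare fixtures/*.xml --out report/ --format csv
```

The compare command prints:

```json
{"items": 11, "not_coded": 0, "pairs": {"DIFFERENT": 46, "SIMILAR": 5, "TRANSFORMABLE": 0, "MATCHING": 0, "IDENTICAL": 4}}
```

11 item occurrences yield 55 pairs, of which 4 are IDENTICAL — the total
score item "Gesamtscore", present unchanged in versions 1–3 (3 pairs),
plus one incidental pair — and 5 are SIMILAR: the dystonia item keeps its
concept across all four versions but changes its code list, so its data
would need manual reconciliation. In `report/comparable_items.csv` the
Gesamtscore row reads `1,1,1,0`: present once in each of the first three
versions, absent from the fourth.

Score a System Usability Scale questionnaire (ten rating columns per
row):

```sh
odmcompare sus ratings.csv
```

For the bundled 12-participant evaluation dataset
(`odmcompare.usability.EVALUATION_RESPONSES`) the per-participant scores
range from 40 to 97.5 with mean 74.2.

The same functionality is available as a library:

```python
from odmcompare import parse_odm, compare_all, build_matrix

docs = [parse_odm(p) for p in ["registry_a.xml", "registry_b.xml"]]
result = compare_all(docs)
matrix = build_matrix(result)
```

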