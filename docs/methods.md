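# Methods

## The comparison procedure

`odmcompare` operates on CDISC ODM 1.3.1/1.3.2 study metadata. Each
`ItemDef` (a single documentation field) carries a name, an ODM data
type, an optional `CodeListRef`, and zero or more `Alias` elements; an
alias with `Context="UMLS"` (matched case-insensitively, since real
exports vary in casing) attaches a UMLS concept code. In ISO/IEC 11179
terms, the set of these codes is the item's *concept domain* and the
data type plus optional code list is its *value domain*.

Every occurrence of an item in a form is resolved separately: the same
`ItemDef` referenced twice within one form yields two occurrences with
distinct positions, each participating in the all-pairs comparison. All
C(n,2) unordered pairs of coded occurrences — including pairs within one
form and within one file — are classified by five gates evaluated in
order:

1. concept domains unequal → **DIFFERENT**;
2. code-list concepts fail to correspond, or the item data types differ
   → **SIMILAR**;
3. otherwise at least **TRANSFORMABLE**;
4. code-list data types equal and the coded values of corresponding
   entries equal → **MATCHING**;
5. additionally item names and code-list names equal, case-insensitively
   → **IDENTICAL**.

Occurrences with an empty concept domain are **NOTCODED**: they are
excluded from pairing and listed separately for manual review, because
absence of annotation is missing information, not evidence of
difference.

### Design choices at the genuinely open points

- **Placement of the item data-type check.** The level definitions admit
  two readings of where the item (as opposed to code-list) data type is
  tested. It is placed at the SIMILAR gate: a data-type mismatch caps a
  pair at SIMILAR even when the code lists correspond. This is the only
  placement consistent with both the SIMILAR description ("codes within
  the attached code lists *or the data type* mismatch") and the MATCHING
  requirement that item and code-list data types all agree — under this
  order, the MATCHING item-data-type condition is automatically
  satisfied.
- **Code-list correspondence is multiset equality** of per-entry
  concept-code sets, not set equality: duplicated signatures must occur
  equally often on both sides, which is exactly the condition for an
  entry-to-entry bijection to exist. Within a shared signature, entries
  are paired by ascending coded value — a deterministic, order-
  independent tie-break.
- **Entries without concept codes** carry the empty set as their
  signature, and two empty signatures correspond. This keeps
  correspondence total; the alternative (empty breaks correspondence)
  would silently demote otherwise-matching lists.
- **String normalization.** Names compare case-insensitively with
  surrounding whitespace trimmed (internal whitespace is significant).
  Concept codes and coded values are identifiers/data, so they compare
  case-sensitively after trimming. Data-type tokens compare by exact
  string equality; `float` and `double` are distinct ODM tokens.
- **One alias, one code.** An `Alias` whose `Name` holds several
  delimiter-separated codes is not split; only item-level and
  code-list-item-level aliases contribute (aliases under `Question` or
  `Decode` do not).

The matrix groups coded occurrences by *exact* concept-domain equality.
This is sound because every relationship at SIMILAR or above requires
equal concept domains, and set equality is transitive — so the grouping
is a true partition and the matrix is unambiguous. A row is kept when
the group has at least two members and its best pairwise level reaches
`min_level` (default SIMILAR). Cell counts are occurrences per
(file, study, form) column; the HTML rendering shows one "x" per
occurrence with the precise per-cell level in the tooltip.

## Validation

The built-in structural validator checks well-formedness, the `ODM`
root, required attributes (`OID`/`Name`/`DataType`), OID uniqueness per
definition kind, resolvability of every `*Ref`, and coded-value
uniqueness per code list. Official ODM XSDs are not redistributed (they
are licensed separately); when the caller supplies a schema path, full
grammar validation runs through `lxml.etree.XMLSchema` instead. A
declared `ODMVersion` outside 1.3.1/1.3.2 produces a warning and a
best-effort parse rather than a rejection. In batch comparison, one
invalid file aborts the whole run (exit code 2) unless `--force`
restricts the run to the valid files — comparing against a half-read
form set would produce silently incomplete matrices.

## The synthetic-form generator

Because the classifier's correctness claim is "recovers the planted
relationship", the generator is first-class, tested code. A `SynthSpec`
lists forms and items; an item may anchor to an earlier item with a
planted level, and the generator applies the *minimal edit* that
produces exactly that level (copy for IDENTICAL, renamed copy for
MATCHING, shifted coded values for TRANSFORMABLE, fresh code-list
concepts / changed data type / dropped code list for SIMILAR, fresh
concepts for DIFFERENT, no annotation for NOTCODED). Concept codes are
synthetic CUIs ("C" + 7 digits) drawn without replacement from a seeded
pool, so unrelated items are DIFFERENT by construction and every planted
level is exact, not merely likely. Unachievable plants (IDENTICAL with
differing names, TRANSFORMABLE against a list-free anchor, anchoring to
a NOTCODED item) are rejected before emission.

Defaults: 3 entries per code list, 1–2 concept codes per item, data
types drawn from {integer, text, string, float, date}, a pool of 2000
codes — small-form scales typical of registry CRFs. Emitted XML uses a
fixed namespace, attribute order and timestamp, so identical seeds give
byte-identical files. Randomized test specs use up to 4 forms of up to
6 items: large enough to mix all six levels in one set, small enough
that the test suite's 200-spec recovery sweep runs in seconds.

What the generator does *not* emulate: natural-language item names,
realistic concept co-occurrence, synonymous UMLS codings of one concept
(a known limitation of code-equality comparison generally),
measurement units, and `ClinicalData` payloads. Passing tests therefore
demonstrate that the classifier implements its decision rules exactly,
not that real-world forms are annotated consistently enough for those
rules to find every reusable item.

## SUS scoring

The System Usability Scale aggregates ten 1–5 ratings: odd-numbered
(positively phrased) questions contribute `rating − 1`, even-numbered
ones `5 − rating`, and the sum is scaled by 2.5 onto 0–100, so scores
are multiples of 2.5. The summary mean is rounded half-up to one
decimal (the convention under which the bundled 12-participant
evaluation dataset's mean, 890/12 = 74.1666…, prints as 74.2); the raw
mean is exposed alongside. Ratings outside 1..5 are rejected.

## Numerical and degenerate-input choices

- Comparison and reports are fully deterministic: no timestamps in
  report bodies, stable orderings everywhere (document order for items
  and columns, first-appearance order for matrix rows, ascending coded
  value in bijections).
- An empty matrix, an empty group (0 items), a single coded item (no
  pairs), and an all-uncoded input are all valid, non-error outcomes.
- A document set defining no forms at all raises an explicit "no study
  metadata" error rather than returning an empty result.

## Known limitations

Measurement units are parsed tolerantly but ignored, so two IDENTICAL
items may still store incommensurable values. Cross-terminology
comparison (e.g. UMLS vs. SNOMED CT annotations) is out of scope: codes
from different contexts never match. Concept-graph distance is
deliberately not used — nearby concepts ("headache", "urticaria") are
still different data elements for data-merging purposes. Lexical
similarity of names plays no role in classification; names only
distinguish MATCHING from IDENTICAL.
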