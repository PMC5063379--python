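"""Independent brute-force re-derivation of the pairwise classification
gates, written directly from the textual decision rules and sharing no code
with the implementation under test."""

from collections import Counter

from odmcompare.compare import Relationship


def _signatures(cl):
    return Counter(frozenset(c.strip() for c in e.concept_domain.codes) for e in cl.items)


def _paired_values(cl_a, cl_b):
    by_sig_a, by_sig_b = {}, {}
    for e in cl_a.items:
        by_sig_a.setdefault(frozenset(e.concept_domain.codes), []).append(e.coded_value)
    for e in cl_b.items:
        by_sig_b.setdefault(frozenset(e.concept_domain.codes), []).append(e.coded_value)
    pairs = []
    for sig, vals_a in by_sig_a.items():
        pairs.extend(zip(sorted(vals_a), sorted(by_sig_b[sig])))
    return pairs


def oracle_classify(a, b) -> Relationship:
    """Naive gate-by-gate classification of two coded item occurrences."""
    # gate 1: concept domains must be identical sets of codes
    if set(a.item.concept_domain.codes) != set(b.item.concept_domain.codes):
        return Relationship.DIFFERENT

    cl_a = a.value_domain.code_list
    cl_b = b.value_domain.code_list

    # gate 2: code-list concepts must correspond and item data types agree
    if cl_a is None and cl_b is None:
        concepts_fit = True
    elif cl_a is None or cl_b is None:
        concepts_fit = False
    else:
        concepts_fit = _signatures(cl_a) == _signatures(cl_b)
    if not concepts_fit or a.item.data_type != b.item.data_type:
        return Relationship.SIMILAR

    # gate 4: code-list data types and corresponding coded values must agree
    if cl_a is None:  # both absent (gate 2 passed)
        cl_dt_ok = values_ok = cl_names_ok = True
    else:
        cl_dt_ok = cl_a.data_type == cl_b.data_type
        values_ok = all(va == vb for va, vb in _paired_values(cl_a, cl_b))
        cl_names_ok = cl_a.name.strip().casefold() == cl_b.name.strip().casefold()
    if not (cl_dt_ok and values_ok):
        return Relationship.TRANSFORMABLE

    # gate 5: item names and code-list names equal, case-insensitively
    if a.item.name.strip().casefold() == b.item.name.strip().casefold() and cl_names_ok:
        return Relationship.IDENTICAL
    return Relationship.MATCHING
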