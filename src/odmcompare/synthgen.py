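"""Deterministic generator of ODM fixtures with planted pairwise
relationships.

The generator is the test bed for the comparison engine: a
:class:`SynthSpec` plants, for chosen item pairs, the exact similarity level
the classifier must later recover.  Base items receive globally unique
synthetic concept codes ("C" + 7 digits drawn from a seeded pool), so any
two unrelated items are guaranteed DIFFERENT; derived items are built from
their anchor by the minimal edit that produces the planted level:

IDENTICAL      exact copy (name case may be flipped);
MATCHING       copy with a different item name;
TRANSFORMABLE  copy with shifted coded values in the code list;
SIMILAR        copy with fresh code-list concept codes, a changed item data
               type, or a dropped code list;
DIFFERENT      fresh concept codes;
NOTCODED       no semantic annotation at all.

The same seed and spec always produce byte-identical XML (fixed namespace,
attribute order and timestamp).
"""

from __future__ import annotations

import json
import random
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

from lxml import etree

from .compare import Relationship
from .model import (
    CodeListDef,
    CodeListItemDef,
    ConceptDomain,
    FormDef,
    ItemDef,
    ItemGroupDef,
    MetaDataVersion,
    ODMDocument,
    Study,
    StudyEventDef,
)

__all__ = [
    "ItemSpec",
    "FormSpec",
    "SynthSpec",
    "SynthSpecError",
    "PlantedPair",
    "build_documents",
    "generate",
    "ground_truth",
    "preset",
    "random_spec",
    "load_spec",
    "write_odm",
]

ODM_NS = "http://www.cdisc.org/ns/odm/v1.3"
#: fixed timestamp so emitted bytes are reproducible
_CREATION = "2016-01-01T00:00:00"

PRESETS = ("versions", "routine_vs_trial", "cross_institution")

#: levels that require an anchor item to be planted against
_ANCHORED = (
    Relationship.SIMILAR,
    Relationship.TRANSFORMABLE,
    Relationship.MATCHING,
    Relationship.IDENTICAL,
)


class SynthSpecError(ValueError):
    """The spec asks for an unachievable plant (checked before emission)."""


@dataclass(frozen=True)
class ItemSpec:
    """One planted item.  ``anchor`` names an earlier (form_name, item_index)
    this item relates to; levels above DIFFERENT require one."""

    planted_level: Relationship = Relationship.DIFFERENT
    anchor: Optional[tuple[str, int]] = None
    name: Optional[str] = None


@dataclass(frozen=True)
class FormSpec:
    form_name: str
    items: tuple[ItemSpec, ...] = ()


@dataclass(frozen=True)
class SynthSpec:
    seed: int
    forms: tuple[FormSpec, ...] = ()
    code_pool_size: int = 2000
    entries_per_list: int = 3
    datatypes: tuple[str, ...] = ("integer", "text", "string", "float", "date")


@dataclass(frozen=True)
class PlantedPair:
    """Ground truth: the occurrence at (form_a, index_a) must classify
    against (form_b, index_b) at exactly ``level``."""

    form_a: str
    index_a: int
    form_b: str
    index_b: int
    level: Relationship


class _CodePool:
    """Seeded pool of unique synthetic CUIs."""

    def __init__(self, rng: random.Random, size: int) -> None:
        self._codes = [f"C{n:07d}" for n in rng.sample(range(1, 10**7), size)]
        self._next = 0

    def draw(self) -> str:
        if self._next >= len(self._codes):
            raise SynthSpecError("code pool exhausted; raise code_pool_size")
        code = self._codes[self._next]
        self._next += 1
        return code


def _validate(spec: SynthSpec) -> None:
    seen: dict[str, int] = {}
    by_pos: dict[tuple[str, int], ItemSpec] = {}
    for form in spec.forms:
        if form.form_name in seen:
            raise SynthSpecError(f"duplicate form name {form.form_name!r}")
        for idx, item in enumerate(form.items):
            if item.anchor is not None:
                if item.planted_level is Relationship.NOTCODED:
                    raise SynthSpecError(
                        f"{form.form_name}[{idx}]: NOTCODED items cannot have an anchor"
                    )
                a_form, a_idx = item.anchor
                earlier = seen.get(a_form)
                same_form = a_form == form.form_name and a_idx < idx
                if not same_form and (earlier is None or a_idx >= earlier):
                    raise SynthSpecError(
                        f"{form.form_name}[{idx}]: anchor ({a_form!r}, {a_idx}) "
                        "must refer to an already-built item"
                    )
                target = by_pos[(a_form, a_idx)]
                if target.planted_level is Relationship.NOTCODED:
                    raise SynthSpecError(
                        f"{form.form_name}[{idx}]: cannot anchor to a NOTCODED item"
                    )
            elif item.planted_level in _ANCHORED:
                raise SynthSpecError(
                    f"{form.form_name}[{idx}]: {item.planted_level.name} "
                    "requires an anchor item"
                )
            by_pos[(form.form_name, idx)] = item
        seen[form.form_name] = len(form.items)
    if spec.entries_per_list < 1:
        raise SynthSpecError("entries_per_list must be >= 1")


def _base_item(
    name: str, rng: random.Random, pool: _CodePool, spec: SynthSpec, oid: str, cl_oid: str
) -> tuple[ItemDef, CodeListDef]:
    data_type = rng.choice(spec.datatypes)
    domain = ConceptDomain(pool.draw() for _ in range(rng.choice((1, 1, 2))))
    entries = [
        CodeListItemDef(
            coded_value=str(k + 1),
            concept_domain=ConceptDomain([pool.draw()]),
            decode_text=f"choice {k + 1}",
        )
        for k in range(spec.entries_per_list)
    ]
    cl = CodeListDef(oid=cl_oid, name=name, data_type=data_type, items=entries)
    item = ItemDef(
        oid=oid,
        name=name,
        data_type=data_type,
        concept_domain=domain,
        codelist_oid=cl_oid,
    )
    return item, cl


def _derive(
    anchor_item: ItemDef,
    anchor_cl: Optional[CodeListDef],
    level: Relationship,
    rng: random.Random,
    pool: _CodePool,
    oid: str,
    cl_oid: str,
    name_override: Optional[str],
) -> tuple[ItemDef, Optional[CodeListDef]]:
    """Build an item whose relationship to the anchor is exactly ``level``."""
    if level is Relationship.IDENTICAL:
        name = anchor_item.name if name_override is None else name_override
        if name.casefold() != anchor_item.name.casefold():
            raise SynthSpecError(
                f"IDENTICAL plant with differing names {name!r} vs {anchor_item.name!r}"
            )
        if rng.random() < 0.5:
            name = name.swapcase()
        cl = None if anchor_cl is None else replace(anchor_cl, oid=cl_oid)
        return (
            replace(anchor_item, oid=oid, name=name, codelist_oid=cl_oid if cl else None),
            cl,
        )

    if level is Relationship.MATCHING:
        name = name_override or f"{anchor_item.name} (alt)"
        if name.casefold() == anchor_item.name.casefold():
            raise SynthSpecError(
                f"MATCHING plant requires a different item name, got {name!r}"
            )
        cl = None if anchor_cl is None else replace(anchor_cl, oid=cl_oid)
        return (
            replace(anchor_item, oid=oid, name=name, codelist_oid=cl_oid if cl else None),
            cl,
        )

    if level is Relationship.TRANSFORMABLE:
        if anchor_cl is None:
            raise SynthSpecError("TRANSFORMABLE plant requires an anchor with a code list")
        shifted = [
            replace(e, coded_value=str(int(e.coded_value) - 1))
            if e.coded_value.isdigit()
            else replace(e, coded_value=e.coded_value + "_t")
            for e in anchor_cl.items
        ]
        cl = replace(anchor_cl, oid=cl_oid, items=shifted)
        name = name_override or anchor_item.name
        return replace(anchor_item, oid=oid, name=name, codelist_oid=cl_oid), cl

    if level is Relationship.SIMILAR:
        name = name_override or anchor_item.name
        variants = ["datatype"]
        if anchor_cl is not None:
            variants += ["codelist_concepts", "drop_codelist"]
        variant = rng.choice(variants)
        if variant == "codelist_concepts":
            fresh = [
                replace(e, concept_domain=ConceptDomain([pool.draw()]))
                for e in anchor_cl.items
            ]
            cl = replace(anchor_cl, oid=cl_oid, items=fresh)
            return replace(anchor_item, oid=oid, name=name, codelist_oid=cl_oid), cl
        if variant == "drop_codelist":
            return replace(anchor_item, oid=oid, name=name, codelist_oid=None), None
        other = [t for t in ("integer", "text", "string", "float") if t != anchor_item.data_type]
        cl = None if anchor_cl is None else replace(anchor_cl, oid=cl_oid)
        return (
            replace(
                anchor_item,
                oid=oid,
                name=name,
                data_type=rng.choice(other),
                codelist_oid=cl_oid if cl else None,
            ),
            cl,
        )

    raise SynthSpecError(f"cannot derive an item at level {level.name}")


def build_documents(spec: SynthSpec) -> tuple[list[ODMDocument], list[PlantedPair]]:
    """Materialize the spec: one ODM document per form, plus ground truth."""
    _validate(spec)
    rng = random.Random(spec.seed)
    pool = _CodePool(rng, spec.code_pool_size)

    docs: list[ODMDocument] = []
    built: dict[tuple[str, int], tuple[ItemDef, Optional[CodeListDef]]] = {}
    truth: list[PlantedPair] = []

    for f_idx, form_spec in enumerate(spec.forms, start=1):
        mdv = MetaDataVersion(oid="MDV.1", name="Metadata Version 1")
        group = ItemGroupDef(oid="IG.1", name="Main")
        form = FormDef(oid="F.1", name=form_spec.form_name, item_group_refs=["IG.1"])
        mdv.form_defs.append(form)
        mdv.item_group_defs.append(group)
        mdv.study_event_defs.append(
            StudyEventDef(oid="SE.1", name="Baseline", form_refs=["F.1"])
        )

        for i_idx, item_spec in enumerate(form_spec.items):
            oid = f"I.{i_idx + 1}"
            cl_oid = f"CL.{i_idx + 1}"
            auto_name = item_spec.name or f"Item {f_idx}.{i_idx + 1}"

            if item_spec.planted_level is Relationship.NOTCODED:
                item, cl = (
                    ItemDef(oid=oid, name=auto_name, data_type=rng.choice(spec.datatypes)),
                    None,
                )
            elif item_spec.anchor is None or item_spec.planted_level is Relationship.DIFFERENT:
                # fresh concept codes guarantee DIFFERENT to everything else
                item, cl = _base_item(auto_name, rng, pool, spec, oid, cl_oid)
                if item_spec.anchor is not None:
                    truth.append(
                        PlantedPair(
                            form_a=form_spec.form_name,
                            index_a=i_idx,
                            form_b=item_spec.anchor[0],
                            index_b=item_spec.anchor[1],
                            level=Relationship.DIFFERENT,
                        )
                    )
            else:
                a_item, a_cl = built[item_spec.anchor]
                item, cl = _derive(
                    a_item,
                    a_cl,
                    item_spec.planted_level,
                    rng,
                    pool,
                    oid,
                    cl_oid,
                    item_spec.name,
                )
                truth.append(
                    PlantedPair(
                        form_a=form_spec.form_name,
                        index_a=i_idx,
                        form_b=item_spec.anchor[0],
                        index_b=item_spec.anchor[1],
                        level=item_spec.planted_level,
                    )
                )

            built[(form_spec.form_name, i_idx)] = (item, cl)
            mdv.item_defs.append(item)
            if cl is not None:
                mdv.code_lists.append(cl)
            group.item_refs.append(oid)

        study = Study(
            oid=f"S.{f_idx}", name=form_spec.form_name, metadata_versions=[mdv]
        )
        docs.append(
            ODMDocument(
                source_name=_file_name(form_spec.form_name),
                odm_version="1.3.2",
                studies=[study],
            )
        )
    return docs, truth


def ground_truth(spec: SynthSpec) -> list[PlantedPair]:
    return build_documents(spec)[1]


def _file_name(form_name: str) -> str:
    slug = re.sub(r"[^A-Za-z0-9]+", "_", form_name).strip("_").lower()
    return f"{slug or 'form'}.xml"


def generate(spec: SynthSpec, out_dir: Optional[str | Path] = None) -> list[tuple[str, bytes]]:
    """Emit ODM 1.3.2 files for the spec; returns (file name, bytes) pairs
    and writes them under ``out_dir`` when given."""
    docs, _ = build_documents(spec)
    files = [(doc.source_name, write_odm(doc)) for doc in docs]
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, data in files:
            (out / name).write_bytes(data)
    return files


# ---------------------------------------------------------------------------
# ODM serialization (only this module emits ODM)


def _el(parent, tag: str, **attrs) -> etree._Element:
    e = etree.SubElement(parent, f"{{{ODM_NS}}}{tag}")
    for k, v in attrs.items():
        e.set(k, v)
    return e


def write_odm(doc: ODMDocument) -> bytes:
    """Serialize a document to ODM 1.3.2 XML with a fixed default namespace
    and deterministic attribute order."""
    root = etree.Element(
        f"{{{ODM_NS}}}ODM",
        nsmap={None: ODM_NS},
        attrib={
            "FileOID": doc.source_name or "generated",
            "FileType": "Snapshot",
            "ODMVersion": doc.odm_version or "1.3.2",
            "CreationDateTime": _CREATION,
        },
    )
    for study in doc.studies:
        s = _el(root, "Study", OID=study.oid)
        gv = _el(s, "GlobalVariables")
        name_el = _el(gv, "StudyName")
        name_el.text = study.name
        desc = _el(gv, "StudyDescription")
        desc.text = study.name
        proto = _el(gv, "ProtocolName")
        proto.text = study.name
        for mdv in study.metadata_versions:
            m = _el(s, "MetaDataVersion", OID=mdv.oid, Name=mdv.name)
            if mdv.study_event_defs:
                p = _el(m, "Protocol")
                for ev in mdv.study_event_defs:
                    _el(p, "StudyEventRef", StudyEventOID=ev.oid, Mandatory="No")
            for ev in mdv.study_event_defs:
                e = _el(m, "StudyEventDef", OID=ev.oid, Name=ev.name, Repeating="No", Type="Common")
                for f_oid in ev.form_refs:
                    _el(e, "FormRef", FormOID=f_oid, Mandatory="No")
            for form in mdv.form_defs:
                f = _el(m, "FormDef", OID=form.oid, Name=form.name, Repeating="No")
                for ig_oid in form.item_group_refs:
                    _el(f, "ItemGroupRef", ItemGroupOID=ig_oid, Mandatory="No")
            for group in mdv.item_group_defs:
                g = _el(m, "ItemGroupDef", OID=group.oid, Name=group.name, Repeating="No")
                for item_oid in group.item_refs:
                    _el(g, "ItemRef", ItemOID=item_oid, Mandatory="No")
            for item in mdv.item_defs:
                i = _el(m, "ItemDef", OID=item.oid, Name=item.name, DataType=item.data_type)
                if item.question_text:
                    q = _el(i, "Question")
                    t = _el(q, "TranslatedText")
                    t.set("{http://www.w3.org/XML/1998/namespace}lang", "en")
                    t.text = item.question_text
                if item.codelist_oid:
                    _el(i, "CodeListRef", CodeListOID=item.codelist_oid)
                for code in sorted(item.concept_domain.codes):
                    _el(i, "Alias", Context="UMLS", Name=code)
            for cl in mdv.code_lists:
                c = _el(m, "CodeList", OID=cl.oid, Name=cl.name, DataType=cl.data_type)
                for entry in cl.items:
                    ce = _el(c, "CodeListItem", CodedValue=entry.coded_value)
                    if entry.decode_text:
                        d = _el(ce, "Decode")
                        t = _el(d, "TranslatedText")
                        t.set("{http://www.w3.org/XML/1998/namespace}lang", "en")
                        t.text = entry.decode_text
                    for code in sorted(entry.concept_domain.codes):
                        _el(ce, "Alias", Context="UMLS", Name=code)
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


# ---------------------------------------------------------------------------
# Presets reproducing the documented use-case patterns


def preset(name: str) -> SynthSpec:
    """Fixed small scenarios: form-set versioning, routine vs. trial
    documentation, and cross-institution comparison."""
    if name == "versions":
        # a total-score item identical in versions 1-3 and absent in 4;
        # a dystonia item whose code list changes in every version (SIMILAR)
        forms = []
        for v in range(1, 5):
            items: list[ItemSpec] = []
            if v == 1:
                items.append(ItemSpec(name="Gesamtscore"))
                items.append(ItemSpec(name="Dystonie"))
            else:
                if v <= 3:
                    items.append(
                        ItemSpec(
                            name="Gesamtscore",
                            planted_level=Relationship.IDENTICAL,
                            anchor=("Version 1", 0),
                        )
                    )
                items.append(
                    ItemSpec(
                        name="Dystonie",
                        planted_level=Relationship.SIMILAR,
                        anchor=("Version 1", 1),
                    )
                )
            items.append(ItemSpec(name=f"Extra {v}"))  # fresh, DIFFERENT filler
            forms.append(FormSpec(form_name=f"Version {v}", items=tuple(items)))
        return SynthSpec(seed=90, forms=tuple(forms))

    if name == "routine_vs_trial":
        matching = (
            "Number of Lymph Nodes examined",
            "Number of positive Lymph Nodes",
            "ECOG Status",
            "ER Status",
        )
        routine = FormSpec(
            form_name="Routine Pathology",
            items=tuple(ItemSpec(name=n) for n in matching)
            + (ItemSpec(name="Macroscopy"), ItemSpec(name="Report text", planted_level=Relationship.NOTCODED)),
        )
        trial = FormSpec(
            form_name="Trial Documentation",
            items=tuple(
                ItemSpec(
                    name=f"{n} (trial)",
                    planted_level=Relationship.MATCHING,
                    anchor=("Routine Pathology", i),
                )
                for i, n in enumerate(matching)
            )
            + (ItemSpec(name="Randomization arm"),),
        )
        return SynthSpec(seed=91, forms=(routine, trial))

    if name == "cross_institution":
        shared = (
            ("Act. Surveillance", Relationship.IDENTICAL),
            ("Analgesics", Relationship.IDENTICAL),
            ("Type of the Tumour Board", Relationship.MATCHING),
            ("Irradiation", Relationship.IDENTICAL),
            ("Chemotherapy", Relationship.MATCHING),
            ("Diagnosis", Relationship.TRANSFORMABLE),
            ("Birthdate", Relationship.IDENTICAL),
            ("Hormone therapy", Relationship.SIMILAR),
        )
        inst_a = FormSpec(
            form_name="Institution A Cancer Documentation",
            items=tuple(ItemSpec(name=n) for n, _ in shared)
            + (ItemSpec(name="Local ID A"),),
        )
        inst_b = FormSpec(
            form_name="Institution B Cancer Documentation",
            items=tuple(
                ItemSpec(
                    name=(n if lvl is not Relationship.MATCHING else f"{n} (B)"),
                    planted_level=lvl,
                    anchor=("Institution A Cancer Documentation", i),
                )
                for i, (n, lvl) in enumerate(shared)
            )
            + (ItemSpec(name="Local ID B"),),
        )
        return SynthSpec(seed=92, forms=(inst_a, inst_b))

    raise ValueError(f"unknown preset {name!r}; known presets: {', '.join(PRESETS)}")


def random_spec(seed: int, max_forms: int = 4, max_items: int = 6) -> SynthSpec:
    """A randomized spec with a mix of planted levels — used for
    ground-truth-recovery testing."""
    rng = random.Random(seed)
    n_forms = rng.randint(2, max_forms)
    forms: list[FormSpec] = []
    anchors: list[tuple[str, int]] = []
    levels = [
        Relationship.NOTCODED,
        Relationship.DIFFERENT,
        Relationship.SIMILAR,
        Relationship.TRANSFORMABLE,
        Relationship.MATCHING,
        Relationship.IDENTICAL,
    ]
    for f in range(n_forms):
        form_name = f"Form {f + 1}"
        items: list[ItemSpec] = []
        for i in range(rng.randint(1, max_items)):
            level = rng.choice(levels)
            if level in _ANCHORED and anchors:
                items.append(ItemSpec(planted_level=level, anchor=rng.choice(anchors)))
            elif level is Relationship.NOTCODED:
                items.append(ItemSpec(planted_level=Relationship.NOTCODED))
            else:
                items.append(ItemSpec())
                anchors.append((form_name, i))
        forms.append(FormSpec(form_name=form_name, items=tuple(items)))
    return SynthSpec(seed=rng.randrange(2**31), forms=tuple(forms))


def load_spec(path: str | Path) -> SynthSpec:
    """Read a spec from a JSON or YAML config file.

    Schema: ``{seed: int, code_pool_size?: int, entries_per_list?: int,
    forms: [{form_name: str, items: [{name?: str, planted_level?: str,
    anchor?: [form_name, index]}]}]}``.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        import yaml

        raw = yaml.safe_load(text)
    forms = tuple(
        FormSpec(
            form_name=f["form_name"],
            items=tuple(
                ItemSpec(
                    planted_level=Relationship[i.get("planted_level", "DIFFERENT").upper()],
                    anchor=tuple(i["anchor"]) if i.get("anchor") else None,
                    name=i.get("name"),
                )
                for i in f.get("items", [])
            ),
        )
        for f in raw.get("forms", [])
    )
    kwargs = {}
    for key in ("code_pool_size", "entries_per_list"):
        if key in raw:
            kwargs[key] = raw[key]
    return SynthSpec(seed=int(raw.get("seed", 0)), forms=forms, **kwargs)
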