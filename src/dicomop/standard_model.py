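"""Typed in-memory model of normalized DICOM Standard content.

The DICOM Standard defines imaging metadata in three places that matter
here: Part 6 (the data dictionary of attributes/tags), Part 16 (context
groups — value sets of coded triplets — plus the Body Part Examined to
SNOMED cross-map), and Part 3 (per-attribute Enumerated Values / Defined
Terms and attribute-value constraints).

This module does not parse the official DocBook XML.  It ingests a
normalized interchange format of five UTF-8 comma-delimited, headered
files::

    attributes.csv     tag,name,keyword,vr,vm,retired
    cid_members.csv    cid,scheme,code,meaning
    bodypart_map.csv   value_string,snomed_code,meaning
    part3_terms.csv    attribute_tag,value_string,meaning,term_kind,snomed_code
    constraints.csv    attribute_tag,constraint_kind,cid

Validation is strict: malformed tags, unknown VR codes and dangling
attribute references are errors naming the offending row, not warnings.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

logger = logging.getLogger("dicomop")

# ---------------------------------------------------------------------------
# Constants
# ---------------------------------------------------------------------------

#: All two-letter Value Representation codes of the current DICOM Standard.
VR_CODES = frozenset(
    """AE AS AT CS DA DS DT FL FD IS LO LT OB OD OF OL OV OW PN SH SL SQ SS
    ST SV TM UC UI UL UN UR US UT UV""".split()
)

TAG_RE = re.compile(r"^[0-9A-F]{8}$")

#: Well-known tags used throughout the pipeline (canonical 8-hex form).
MODALITY_TAG = "00080060"
BODY_PART_TAG = "00180015"
PATIENT_POSITION_TAG = "00185100"
LOSSY_COMPRESSION_METHOD_TAG = "00282114"
MANUFACTURER_TAG = "00080070"

TERM_KINDS = frozenset({"Enumerated", "Defined"})
CONSTRAINT_KINDS = frozenset({"CID", "TermList"})

#: Column contracts for the interchange files, enforced on load.  Kept as
#: data so the contract is introspectable (e.g. by the CLI's `schema` help).
INTERCHANGE_SCHEMAS = {
    "attributes.csv": ["tag", "name", "keyword", "vr", "vm", "retired"],
    "cid_members.csv": ["cid", "scheme", "code", "meaning"],
    "bodypart_map.csv": ["value_string", "snomed_code", "meaning"],
    "part3_terms.csv": ["attribute_tag", "value_string", "meaning", "term_kind", "snomed_code"],
    "constraints.csv": ["attribute_tag", "constraint_kind", "cid"],
}


class SchemaViolationError(ValueError):
    """An interchange file does not conform to its column/row contract."""


class ReferentialIntegrityError(ValueError):
    """A cross-reference (attribute tag, concept id) does not resolve."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AttributeDef:
    """One Part-6 data-dictionary entry.

    ``tag`` is the canonical key: uppercase, zero-padded, 8 hex digits,
    no punctuation.  ``name`` may be empty (the dictionary contains a
    handful of placeholder rows without attribute names; they are kept
    here and excluded later, when concepts are built).
    """

    tag: str
    name: str
    keyword: str
    vr: str
    vm: str = "1"
    retired: bool = False
    source_part: str = "6"

    def display_tag(self) -> str:
        """Presentation form ``(gggg,eeee)``."""
        return f"({self.tag[:4]},{self.tag[4:]})"


@dataclass
class CodedValue:
    """A coded triplet (code value, coding scheme, code meaning).

    Before deduplication each instance carries exactly one context-group
    id; after deduplication ``cids`` is the union over all context groups
    the (scheme, code) pair belongs to.
    """

    code_value: str
    coding_scheme: str
    code_meaning: str
    cids: frozenset[int] = field(default_factory=frozenset)

    @property
    def is_dcm(self) -> bool:
        """True for DICOM-managed codes; SCT/LN etc. are external."""
        return self.coding_scheme == "DCM"

    @property
    def key(self) -> tuple[str, str]:
        return (self.coding_scheme, self.code_value)


@dataclass(frozen=True)
class DefinedTerm:
    """A Part-3 Enumerated Value or Defined Term constraining one attribute."""

    attribute_tag: str
    value_string: str
    meaning: str
    term_kind: str = "Defined"
    snomed_code: str = ""


@dataclass(frozen=True)
class AttributeValueConstraint:
    """An attribute's permitted-value constraint: a CID or a term list."""

    attribute_tag: str
    constraint_kind: str
    cid: int | None = None
    term_refs: tuple[DefinedTerm, ...] | None = None

    def __post_init__(self) -> None:
        if self.constraint_kind == "CID":
            if self.cid is None or self.term_refs is not None:
                raise SchemaViolationError(
                    f"CID constraint on {self.attribute_tag} must carry a cid and no terms"
                )
        elif self.constraint_kind == "TermList":
            if self.term_refs is None or self.cid is not None:
                raise SchemaViolationError(
                    f"TermList constraint on {self.attribute_tag} must carry terms and no cid"
                )
        else:
            raise SchemaViolationError(
                f"unknown constraint_kind {self.constraint_kind!r} on {self.attribute_tag}"
            )


@dataclass
class StandardBundle:
    """Container for loaded Parts 3/6/16 content (pre-deduplication)."""

    attributes: list[AttributeDef]
    coded_values: list[CodedValue]  # one occurrence per (cid, scheme, code) row
    defined_terms: list[DefinedTerm]
    constraints: list[AttributeValueConstraint]
    bodypart_snomed_map: list[tuple[str, str]]  # (value_string, snomed_code)

    def attribute_tags(self) -> set[str]:
        return {a.tag for a in self.attributes}

    def validate(self) -> None:
        """Assert the bundle's cross-reference and uniqueness invariants."""
        tags = [a.tag for a in self.attributes]
        if len(tags) != len(set(tags)):
            dupes = sorted({t for t in tags if tags.count(t) > 1})
            raise SchemaViolationError(f"duplicate attribute tags: {dupes[:5]}")
        known = set(tags)
        for term in self.defined_terms:
            if term.attribute_tag not in known:
                raise ReferentialIntegrityError(
                    f"term {term.value_string!r} references unknown attribute "
                    f"{term.attribute_tag}"
                )
        for con in self.constraints:
            if con.attribute_tag not in known:
                raise ReferentialIntegrityError(
                    f"constraint references unknown attribute {con.attribute_tag}"
                )


# ---------------------------------------------------------------------------
# Low-level CSV plumbing
# ---------------------------------------------------------------------------


def _read_rows(source: str | Path, expected_columns: Sequence[str]) -> list[dict[str, str]]:
    path = Path(source)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaViolationError(f"{path.name}: empty file, header required")
        missing = [c for c in expected_columns if c not in reader.fieldnames]
        if missing:
            raise SchemaViolationError(f"{path.name}: missing columns {missing}")
        return [dict(row) for row in reader]


def _parse_bool(text: str) -> bool:
    return text.strip().lower() in {"1", "true", "yes", "y"}


# ---------------------------------------------------------------------------
# Loaders
# ---------------------------------------------------------------------------


def load_attribute_dictionary(source: str | Path) -> list[AttributeDef]:
    """Load the normalized Part-6 attribute dictionary.

    Returns one :class:`AttributeDef` per row, input order preserved.
    Rows with empty attribute names are retained — the exclusion of
    nameless attributes happens when vocabulary concepts are built, not
    at load time.

    Raises
    ------
    SchemaViolationError
        On a malformed tag, an unknown VR code or a duplicate tag; the
        message names the offending (1-based, data) row number.
    """
    rows = _read_rows(source, INTERCHANGE_SCHEMAS["attributes.csv"])
    out: list[AttributeDef] = []
    seen: set[str] = set()
    for i, row in enumerate(rows, start=1):
        tag = row["tag"].strip().upper()
        if not TAG_RE.match(tag):
            raise SchemaViolationError(f"attributes.csv row {i}: malformed tag {row['tag']!r}")
        vr = row["vr"].strip()
        if vr not in VR_CODES:
            raise SchemaViolationError(f"attributes.csv row {i}: unknown VR {vr!r}")
        if tag in seen:
            raise SchemaViolationError(f"attributes.csv row {i}: duplicate tag {tag}")
        seen.add(tag)
        out.append(
            AttributeDef(
                tag=tag,
                name=row["name"].strip(),
                keyword=row["keyword"].strip(),
                vr=vr,
                vm=row["vm"].strip() or "1",
                retired=_parse_bool(row.get("retired", "")),
            )
        )
    logger.info("loaded %d attribute definitions", len(out))
    return out


def load_context_groups(
    cid_members: str | Path,
    bodypart_map: str | Path | None = None,
) -> tuple[list[CodedValue], list[tuple[str, str]]]:
    """Load Part-16 context-group members and the body-part cross-map.

    Each ``cid_members.csv`` row becomes one :class:`CodedValue`
    occurrence with a singleton ``cids`` set — deduplication across
    context groups is a vocabulary-builder concern, not a loading one.
    Codes from external schemes (SCT, LN, ...) are loaded like any other
    occurrence; :attr:`CodedValue.is_dcm` distinguishes them.

    The body-part cross-map rows (Body Part Examined code string →
    SNOMED code) are returned separately; either side may be empty.
    """
    rows = _read_rows(cid_members, INTERCHANGE_SCHEMAS["cid_members.csv"])
    occurrences: list[CodedValue] = []
    n_foreign = 0
    for i, row in enumerate(rows, start=1):
        cid_text = row["cid"].strip()
        if not cid_text:
            raise SchemaViolationError(f"cid_members.csv row {i}: missing cid")
        try:
            cid = int(cid_text)
        except ValueError:
            raise SchemaViolationError(
                f"cid_members.csv row {i}: non-integer cid {cid_text!r}"
            ) from None
        meaning = row["meaning"].strip()
        if not meaning:
            raise SchemaViolationError(f"cid_members.csv row {i}: empty code meaning")
        cv = CodedValue(
            code_value=row["code"].strip(),
            coding_scheme=row["scheme"].strip(),
            code_meaning=meaning,
            cids=frozenset({cid}),
        )
        if not cv.is_dcm:
            n_foreign += 1
        occurrences.append(cv)

    bp_map: list[tuple[str, str]] = []
    if bodypart_map is not None and Path(bodypart_map).exists():
        for row in _read_rows(bodypart_map, INTERCHANGE_SCHEMAS["bodypart_map.csv"]):
            bp_map.append((row["value_string"].strip(), row["snomed_code"].strip()))
    logger.info(
        "loaded %d context-group occurrences (%d non-DCM) and %d body-part map rows",
        len(occurrences), n_foreign, len(bp_map),
    )
    return occurrences, bp_map


def load_part3_terms(
    source: str | Path,
    attribute_tags: set[str] | None = None,
) -> tuple[list[DefinedTerm], list[AttributeValueConstraint]]:
    """Load Part-3 Enumerated Values / Defined Terms.

    Exact duplicate ``(attribute_tag, value_string)`` rows are collapsed
    to one term.  Terms are then grouped into one ``TermList`` constraint
    per attribute.  When ``attribute_tags`` is given, every referenced
    tag must resolve to a dictionary entry.
    """
    rows = _read_rows(source, INTERCHANGE_SCHEMAS["part3_terms.csv"])
    terms: list[DefinedTerm] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(rows, start=1):
        tag = row["attribute_tag"].strip().upper()
        if not TAG_RE.match(tag):
            raise SchemaViolationError(f"part3_terms.csv row {i}: malformed tag {row['attribute_tag']!r}")
        if attribute_tags is not None and tag not in attribute_tags:
            raise ReferentialIntegrityError(
                f"part3_terms.csv row {i}: unknown attribute tag {tag}"
            )
        value = row["value_string"].strip()
        if not value:
            raise SchemaViolationError(f"part3_terms.csv row {i}: empty value_string")
        kind = row["term_kind"].strip() or "Defined"
        if kind not in TERM_KINDS:
            raise SchemaViolationError(f"part3_terms.csv row {i}: unknown term_kind {kind!r}")
        key = (tag, value)
        if key in seen:
            continue
        seen.add(key)
        terms.append(
            DefinedTerm(
                attribute_tag=tag,
                value_string=value,
                meaning=row["meaning"].strip() or value,
                term_kind=kind,
                snomed_code=row.get("snomed_code", "").strip(),
            )
        )

    by_attr: dict[str, list[DefinedTerm]] = {}
    for term in terms:
        by_attr.setdefault(term.attribute_tag, []).append(term)
    constraints = [
        AttributeValueConstraint(
            attribute_tag=tag, constraint_kind="TermList", term_refs=tuple(group)
        )
        for tag, group in by_attr.items()
    ]
    for tag, group in sorted(by_attr.items()):
        logger.info("part3 terms: attribute %s has %d terms", tag, len(group))
    return terms, constraints


def load_cid_constraints(
    source: str | Path,
    attribute_tags: set[str] | None = None,
) -> list[AttributeValueConstraint]:
    """Load ``constraints.csv`` (CID-kind attribute-value constraints)."""
    rows = _read_rows(source, INTERCHANGE_SCHEMAS["constraints.csv"])
    out: list[AttributeValueConstraint] = []
    for i, row in enumerate(rows, start=1):
        tag = row["attribute_tag"].strip().upper()
        if not TAG_RE.match(tag):
            raise SchemaViolationError(f"constraints.csv row {i}: malformed tag {row['attribute_tag']!r}")
        if attribute_tags is not None and tag not in attribute_tags:
            raise ReferentialIntegrityError(f"constraints.csv row {i}: unknown attribute tag {tag}")
        kind = row["constraint_kind"].strip()
        if kind != "CID":
            raise SchemaViolationError(
                f"constraints.csv row {i}: only CID constraints are file-borne, got {kind!r}"
            )
        try:
            cid = int(row["cid"].strip())
        except ValueError:
            raise SchemaViolationError(f"constraints.csv row {i}: non-integer cid") from None
        out.append(AttributeValueConstraint(attribute_tag=tag, constraint_kind="CID", cid=cid))
    return out


def load_standard_bundle(directory: str | Path) -> StandardBundle:
    """Load a full :class:`StandardBundle` from an interchange directory.

    Term-list constraints are derived by grouping the Part-3 terms per
    attribute; CID constraints come from ``constraints.csv``.  The
    assembled bundle is validated (unique tags, resolvable references)
    before being returned.
    """
    directory = Path(directory)
    attributes = load_attribute_dictionary(directory / "attributes.csv")
    tags = {a.tag for a in attributes}
    occurrences, bp_map = load_context_groups(
        directory / "cid_members.csv", directory / "bodypart_map.csv"
    )
    terms, term_constraints = load_part3_terms(directory / "part3_terms.csv", tags)
    cid_constraints = load_cid_constraints(directory / "constraints.csv", tags)
    bundle = StandardBundle(
        attributes=attributes,
        coded_values=occurrences,
        defined_terms=terms,
        constraints=cid_constraints + term_constraints,
        bodypart_snomed_map=bp_map,
    )
    bundle.validate()
    return bundle


# ---------------------------------------------------------------------------
# Writer (round-trip partner of the loaders)
# ---------------------------------------------------------------------------


def write_standard_bundle(bundle: StandardBundle, out_dir: str | Path) -> None:
    """Write a bundle back to the five interchange files.

    Re-loading the written directory yields structurally identical
    content (the round-trip property the tests assert).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with (out / "attributes.csv").open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(INTERCHANGE_SCHEMAS["attributes.csv"])
        for a in bundle.attributes:
            w.writerow([a.tag, a.name, a.keyword, a.vr, a.vm, "true" if a.retired else "false"])

    with (out / "cid_members.csv").open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(INTERCHANGE_SCHEMAS["cid_members.csv"])
        for cv in bundle.coded_values:
            for cid in sorted(cv.cids):
                w.writerow([cid, cv.coding_scheme, cv.code_value, cv.code_meaning])

    with (out / "bodypart_map.csv").open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(INTERCHANGE_SCHEMAS["bodypart_map.csv"])
        for value, snomed in bundle.bodypart_snomed_map:
            w.writerow([value, snomed, value])

    with (out / "part3_terms.csv").open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(INTERCHANGE_SCHEMAS["part3_terms.csv"])
        for t in bundle.defined_terms:
            w.writerow([t.attribute_tag, t.value_string, t.meaning, t.term_kind, t.snomed_code])

    with (out / "constraints.csv").open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(INTERCHANGE_SCHEMAS["constraints.csv"])
        for c in bundle.constraints:
            if c.constraint_kind == "CID":
                w.writerow([c.attribute_tag, "CID", c.cid])
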