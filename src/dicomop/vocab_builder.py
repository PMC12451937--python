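"""Build a custom OMOP CDM vocabulary from loaded DICOM Standard content.

The construction follows OMOP conventions for site-defined vocabularies:

* every DICOM attribute with a nonempty name, every deduplicated
  DICOM-managed (scheme ``DCM``) coded value, and every surviving Part-3
  term becomes a non-standard concept with a custom ``concept_id`` in
  the reserved 2-billion range (consecutive from ``id_base``, default
  2 128 000 000);
* ``"Maps to value"`` rows link an attribute concept to each of its
  permitted value concepts (from context-group constraints and from
  term-list constraints);
* ``"Maps to"`` rows link DICOM value concepts to pre-existing standard
  concepts in other terminologies (here: Body Part Examined values to
  SNOMED, resolved through an :class:`ExternalConceptResolver`).

Codes that DICOM borrows from external schemes (SNOMED/LOINC members of
context groups) receive no custom concepts: OMOP already has ids for
them, reachable only through the resolver.

Concept codes are canonical and collision-free by construction:
attributes use the bare 8-hex tag, DCM values use ``DCM:<code>``, and
term values use ``<tag>:<value_string>``.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .standard_model import (
    BODY_PART_TAG,
    LOSSY_COMPRESSION_METHOD_TAG,
    MODALITY_TAG,
    PATIENT_POSITION_TAG,
    AttributeDef,
    CodedValue,
    DefinedTerm,
    ReferentialIntegrityError,
    StandardBundle,
)

logger = logging.getLogger("dicomop")

MAPS_TO = "Maps to"
MAPS_TO_VALUE = "Maps to value"

CONCEPT_COLUMNS = [
    "concept_id", "concept_name", "domain_id", "vocabulary_id",
    "concept_class_id", "standard_concept", "concept_code",
    "valid_start_date", "valid_end_date", "invalid_reason",
]
RELATIONSHIP_COLUMNS = [
    "concept_id_1", "concept_id_2", "relationship_id",
    "valid_start_date", "valid_end_date", "invalid_reason",
]


class ConceptIdCollisionError(ValueError):
    """A custom id collides with a resolver-supplied external id."""


@dataclass(frozen=True)
class BuilderConfig:
    """Knobs of the vocabulary build.

    ``id_base`` must sit in OMOP's reserved ≥2-billion range for local
    concepts; 2 128 000 000 is the conventional start for DICOM
    terminology.  Dates follow the usual OMOP open-interval convention.
    """

    id_base: int = 2_128_000_000
    vocabulary_id: str = "DICOM"
    domain_label: str = "Measurement"
    valid_start_date: str = "1970-01-01"
    valid_end_date: str = "2099-12-31"

    def __post_init__(self) -> None:
        if self.id_base < 2_000_000_000:
            raise ValueError("id_base must be >= 2000000000 (OMOP custom-concept range)")


@dataclass
class Concept:
    concept_id: int
    concept_name: str
    domain_id: str
    vocabulary_id: str
    concept_class_id: str  # "Attribute" | "Value"
    concept_code: str
    standard_concept: str = ""
    valid_start_date: str = "1970-01-01"
    valid_end_date: str = "2099-12-31"
    invalid_reason: str = ""

    def as_row(self) -> list:
        return [
            self.concept_id, self.concept_name, self.domain_id, self.vocabulary_id,
            self.concept_class_id, self.standard_concept, self.concept_code,
            self.valid_start_date, self.valid_end_date, self.invalid_reason,
        ]


@dataclass(frozen=True)
class ConceptRelationship:
    concept_id_1: int
    concept_id_2: int
    relationship_id: str
    valid_start_date: str = "1970-01-01"
    valid_end_date: str = "2099-12-31"
    invalid_reason: str = ""
    #: construction provenance, not emitted: "cid" | "term" | "bodypart"
    provenance: str = field(default="", compare=False)

    def as_row(self) -> list:
        return [
            self.concept_id_1, self.concept_id_2, self.relationship_id,
            self.valid_start_date, self.valid_end_date, self.invalid_reason,
        ]


class ExternalConceptResolver:
    """Resolve (coding_scheme, code) pairs to pre-existing standard ids.

    Misses are soft: :meth:`resolve` returns ``None`` and the miss is
    recorded for the load log — the build continues.
    """

    def __init__(self, mapping: Mapping[tuple[str, str], int] | None = None):
        self._map: dict[tuple[str, str], int] = dict(mapping or {})
        self.misses: list[tuple[str, str]] = []

    @classmethod
    def from_csv(cls, path: str | Path) -> "ExternalConceptResolver":
        """Load a resolver from a (scheme, code, concept_id) CSV."""
        mapping: dict[tuple[str, str], int] = {}
        with Path(path).open(newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                mapping[(row["scheme"].strip(), row["code"].strip())] = int(row["concept_id"])
        return cls(mapping)

    def resolve(self, scheme: str, code: str) -> int | None:
        hit = self._map.get((scheme, code))
        if hit is None:
            self.misses.append((scheme, code))
        return hit

    def ids(self) -> set[int]:
        return set(self._map.values())

    def __len__(self) -> int:
        return len(self._map)


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------


@dataclass
class DedupResult:
    """Outcome of coded-value deduplication.

    ``dcm_values`` are the distinct DICOM-managed codes with their
    context-group memberships unioned.  ``surviving_terms`` are Part-3
    terms that did not duplicate a DCM code and therefore get their own
    value concepts; ``dropped_terms`` maps each duplicate term to the
    (scheme, code) key of its existing DCM twin.
    """

    dcm_values: list[CodedValue]
    foreign_values: list[CodedValue]
    surviving_terms: list[DefinedTerm]
    dropped_terms: dict[DefinedTerm, tuple[str, str]]

    @property
    def n_repeated(self) -> int:
        """Distinct DCM codes that occurred in more than one context group."""
        return sum(1 for cv in self.dcm_values if len(cv.cids) > 1)


def dedup_coded_values(
    occurrences: Sequence[CodedValue],
    terms: Sequence[DefinedTerm] = (),
) -> DedupResult:
    """Collapse context-group occurrences and drop duplicate Part-3 terms.

    Occurrences sharing a (coding_scheme, code_value) key collapse to a
    single :class:`CodedValue` whose ``cids`` is the union of memberships
    (meaning taken from the first occurrence seen).  A Part-3 term whose
    ``value_string`` exactly (case-sensitively) equals an existing DCM
    ``code_value`` is dropped as a duplicate — it keeps no concept of its
    own and later resolves to the DCM twin.

    The operation is idempotent and permutation-invariant on its set
    semantics: permuting the inputs changes no resulting key set.
    """
    collapsed: dict[tuple[str, str], CodedValue] = {}
    for occ in occurrences:
        prev = collapsed.get(occ.key)
        if prev is None:
            collapsed[occ.key] = CodedValue(
                code_value=occ.code_value,
                coding_scheme=occ.coding_scheme,
                code_meaning=occ.code_meaning,
                cids=frozenset(occ.cids),
            )
        else:
            prev.cids = prev.cids | occ.cids

    dcm = sorted(
        (cv for cv in collapsed.values() if cv.is_dcm),
        key=lambda cv: cv.key,
    )
    foreign = sorted(
        (cv for cv in collapsed.values() if not cv.is_dcm),
        key=lambda cv: cv.key,
    )

    dcm_codes = {cv.code_value for cv in dcm}
    surviving: list[DefinedTerm] = []
    dropped: dict[DefinedTerm, tuple[str, str]] = {}
    for term in terms:
        if term.value_string in dcm_codes:
            dropped[term] = ("DCM", term.value_string)
        else:
            surviving.append(term)
    if dropped:
        logger.info("dedup: dropped %d Part-3 terms duplicating DCM codes", len(dropped))
    logger.info(
        "dedup: %d occurrences -> %d distinct DCM codes (%d repeated), %d foreign",
        len(occurrences), len(dcm), sum(1 for cv in dcm if len(cv.cids) > 1), len(foreign),
    )
    return DedupResult(
        dcm_values=dcm,
        foreign_values=foreign,
        surviving_terms=surviving,
        dropped_terms=dropped,
    )


# ---------------------------------------------------------------------------
# Concept construction
# ---------------------------------------------------------------------------


def build_attribute_concepts(
    attributes: Sequence[AttributeDef], cfg: BuilderConfig
) -> list[Concept]:
    """One ``Attribute``-class concept payload per named dictionary entry.

    Entries without an attribute name cannot be meaningful concepts and
    are excluded (and logged).  Payloads carry ``concept_id = 0`` until
    :func:`assign_concept_ids` runs; they are emitted sorted by tag so
    id assignment is reproducible.
    """
    named = [a for a in attributes if a.name]
    skipped = len(attributes) - len(named)
    if skipped:
        logger.info("excluded %d nameless attributes from concept creation", skipped)
    return [
        Concept(
            concept_id=0,
            concept_name=a.name,
            domain_id=cfg.domain_label,
            vocabulary_id=cfg.vocabulary_id,
            concept_class_id="Attribute",
            concept_code=a.tag,
            valid_start_date=cfg.valid_start_date,
            valid_end_date=cfg.valid_end_date,
        )
        for a in sorted(named, key=lambda a: a.tag)
    ]


def build_value_concepts(dedup: DedupResult, cfg: BuilderConfig) -> list[Concept]:
    """``Value``-class payloads: distinct DCM codes, then surviving terms.

    Ordering is fixed — DCM values by (scheme, code), then term values by
    (attribute_tag, value_string) — so that reruns assign identical ids.
    """
    payloads = [
        Concept(
            concept_id=0,
            concept_name=cv.code_meaning,
            domain_id=cfg.domain_label,
            vocabulary_id=cfg.vocabulary_id,
            concept_class_id="Value",
            concept_code=f"{cv.coding_scheme}:{cv.code_value}",
            valid_start_date=cfg.valid_start_date,
            valid_end_date=cfg.valid_end_date,
        )
        for cv in sorted(dedup.dcm_values, key=lambda cv: cv.key)
    ]
    payloads.extend(
        Concept(
            concept_id=0,
            concept_name=t.meaning,
            domain_id=cfg.domain_label,
            vocabulary_id=cfg.vocabulary_id,
            concept_class_id="Value",
            concept_code=f"{t.attribute_tag}:{t.value_string}",
            valid_start_date=cfg.valid_start_date,
            valid_end_date=cfg.valid_end_date,
        )
        for t in sorted(dedup.surviving_terms, key=lambda t: (t.attribute_tag, t.value_string))
    )
    return payloads


def assign_concept_ids(
    payloads: Sequence[Concept],
    cfg: BuilderConfig,
    resolver: ExternalConceptResolver | None = None,
) -> list[Concept]:
    """Assign consecutive custom ids from ``cfg.id_base``.

    Deterministic: identical payload order yields identical ids.  A
    collision between the custom range and resolver-supplied external
    ids is fatal — external standard ids live below 2 billion, so a
    collision means a misconfigured resolver.
    """
    external = resolver.ids() if resolver is not None else set()
    out: list[Concept] = []
    codes: set[str] = set()
    for offset, payload in enumerate(payloads):
        cid = cfg.id_base + offset
        if cid in external:
            raise ConceptIdCollisionError(f"custom id {cid} collides with an external concept id")
        if payload.concept_code in codes:
            raise ValueError(f"duplicate concept_code {payload.concept_code!r}")
        codes.add(payload.concept_code)
        payload.concept_id = cid
        out.append(payload)
    return out


# ---------------------------------------------------------------------------
# Relationships
# ---------------------------------------------------------------------------


@dataclass
class ConceptIndex:
    """Lookup structure over assigned concepts."""

    by_code: dict[str, Concept]

    @classmethod
    def build(cls, concepts: Iterable[Concept]) -> "ConceptIndex":
        return cls(by_code={c.concept_code: c for c in concepts})

    def attribute(self, tag: str) -> Concept | None:
        c = self.by_code.get(tag)
        return c if c is not None and c.concept_class_id == "Attribute" else None

    def dcm_value(self, code_value: str) -> Concept | None:
        return self.by_code.get(f"DCM:{code_value}")

    def term_value(self, tag: str, value_string: str) -> Concept | None:
        return self.by_code.get(f"{tag}:{value_string}")


def build_relationships(
    bundle: StandardBundle,
    index: ConceptIndex,
    resolver: ExternalConceptResolver | None = None,
    cfg: BuilderConfig | None = None,
) -> list[ConceptRelationship]:
    """Build the ``Maps to value`` / ``Maps to`` relationship rows.

    * CID constraint → one ``Maps to value`` per DICOM-managed member of
      that context group (external-scheme members have no custom concept
      and yield no row).
    * TermList constraint → one ``Maps to value`` per term; a term that
      was dropped as a duplicate resolves to its DCM twin concept.
    * Body-part cross-map row → one ``Maps to`` from the Body Part
      Examined value concept to the resolver's standard SNOMED concept;
      rows with no matching value concept or an unresolvable SNOMED code
      are logged and skipped.

    A dangling reference from a *constraint* (an attribute with no
    concept, or a CID with no members) is fatal.
    """
    cfg = cfg or BuilderConfig()
    dates = dict(valid_start_date=cfg.valid_start_date, valid_end_date=cfg.valid_end_date)
    members_by_cid: dict[int, list[CodedValue]] = {}
    for occ in bundle.coded_values:
        for cid in occ.cids:
            members_by_cid.setdefault(cid, []).append(occ)

    rows: list[ConceptRelationship] = []
    seen: set[tuple[int, int, str]] = set()

    def _add(id1: int, id2: int, rel: str, provenance: str) -> None:
        key = (id1, id2, rel)
        if key in seen:
            return
        seen.add(key)
        rows.append(ConceptRelationship(id1, id2, rel, provenance=provenance, **dates))

    for con in bundle.constraints:
        attr = index.attribute(con.attribute_tag)
        if attr is None:
            raise ReferentialIntegrityError(
                f"constraint references attribute {con.attribute_tag} with no concept"
            )
        if con.constraint_kind == "CID":
            members = members_by_cid.get(con.cid, [])
            dcm_members = sorted({m.code_value for m in members if m.is_dcm})
            for code in dcm_members:
                value = index.dcm_value(code)
                if value is None:
                    raise ReferentialIntegrityError(f"DCM code {code!r} has no concept")
                _add(attr.concept_id, value.concept_id, MAPS_TO_VALUE, "cid")
        else:
            for term in con.term_refs:
                value = index.term_value(term.attribute_tag, term.value_string) or index.dcm_value(
                    term.value_string
                )
                if value is None:
                    raise ReferentialIntegrityError(
                        f"term {term.value_string!r} on {term.attribute_tag} has no concept"
                    )
                _add(attr.concept_id, value.concept_id, MAPS_TO_VALUE, "term")

    n_skipped = 0
    for value_string, snomed_code in bundle.bodypart_snomed_map:
        value = index.term_value(BODY_PART_TAG, value_string) if value_string else None
        target = resolver.resolve("SCT", snomed_code) if (resolver and snomed_code) else None
        if value is None or target is None:
            n_skipped += 1
            continue
        _add(value.concept_id, target, MAPS_TO, "bodypart")
    if n_skipped:
        logger.info("body-part map: skipped %d unresolvable rows", n_skipped)
    return rows


# ---------------------------------------------------------------------------
# Summary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VocabularySummary:
    """Row counts of the built vocabulary, in the shape the field reports
    them: relationships count toward the vocabulary grand total even
    though they live in CONCEPT_RELATIONSHIP, not CONCEPT."""

    n_attributes: int
    n_cid_values: int
    n_bodypart_values: int
    n_modality_terms: int
    n_patientposition_terms: int
    n_compression_terms: int
    n_other_term_values: int
    n_total_values: int
    n_maps_to_value: int
    n_maps_to: int
    n_total_relationships: int
    n_total_concepts: int

    def __post_init__(self) -> None:
        parts = (
            self.n_cid_values + self.n_bodypart_values + self.n_modality_terms
            + self.n_patientposition_terms + self.n_compression_terms
            + self.n_other_term_values
        )
        assert self.n_total_values == parts, "value subtotal mismatch"
        assert self.n_total_relationships == self.n_maps_to_value + self.n_maps_to
        assert self.n_total_concepts == (
            self.n_attributes + self.n_total_values + self.n_total_relationships
        )


def summarize(
    concepts: Sequence[Concept], relationships: Sequence[ConceptRelationship]
) -> VocabularySummary:
    """Aggregate the build into a :class:`VocabularySummary`.

    Counts are derived from the emitted tables themselves (concept class
    and concept-code prefixes), so the summary equals an independent
    recount of the output files.
    """
    n_attr = sum(1 for c in concepts if c.concept_class_id == "Attribute")
    values = [c for c in concepts if c.concept_class_id == "Value"]

    def _n(prefix: str) -> int:
        return sum(1 for c in values if c.concept_code.startswith(prefix + ":"))

    n_cid = _n("DCM")
    n_bp = _n(BODY_PART_TAG)
    n_mod = _n(MODALITY_TAG)
    n_pp = _n(PATIENT_POSITION_TAG)
    n_comp = _n(LOSSY_COMPRESSION_METHOD_TAG)
    n_other = len(values) - n_cid - n_bp - n_mod - n_pp - n_comp
    n_mtv = sum(1 for r in relationships if r.relationship_id == MAPS_TO_VALUE)
    n_mt = sum(1 for r in relationships if r.relationship_id == MAPS_TO)
    return VocabularySummary(
        n_attributes=n_attr,
        n_cid_values=n_cid,
        n_bodypart_values=n_bp,
        n_modality_terms=n_mod,
        n_patientposition_terms=n_pp,
        n_compression_terms=n_comp,
        n_other_term_values=n_other,
        n_total_values=len(values),
        n_maps_to_value=n_mtv,
        n_maps_to=n_mt,
        n_total_relationships=n_mtv + n_mt,
        n_total_concepts=n_attr + len(values) + n_mtv + n_mt,
    )


# ---------------------------------------------------------------------------
# Full build + emission
# ---------------------------------------------------------------------------


@dataclass
class VocabularyBuild:
    concepts: list[Concept]
    relationships: list[ConceptRelationship]
    summary: VocabularySummary
    dedup: DedupResult

    @property
    def n_maps_to_value_cid(self) -> int:
        return sum(1 for r in self.relationships if r.provenance == "cid")

    @property
    def n_maps_to_value_term(self) -> int:
        return sum(1 for r in self.relationships if r.provenance == "term")


def build_vocabulary(
    bundle: StandardBundle,
    cfg: BuilderConfig | None = None,
    resolver: ExternalConceptResolver | None = None,
) -> VocabularyBuild:
    """Run the full vocabulary construction on a loaded bundle."""
    cfg = cfg or BuilderConfig()
    attr_payloads = build_attribute_concepts(bundle.attributes, cfg)
    dedup = dedup_coded_values(bundle.coded_values, bundle.defined_terms)
    value_payloads = build_value_concepts(dedup, cfg)
    concepts = assign_concept_ids(attr_payloads + value_payloads, cfg, resolver)
    index = ConceptIndex.build(concepts)
    relationships = build_relationships(bundle, index, resolver, cfg)
    summary = summarize(concepts, relationships)
    logger.info(
        "vocabulary build: %d concepts, %d relationships (%d Maps to value / %d Maps to)",
        len(concepts), len(relationships), summary.n_maps_to_value, summary.n_maps_to,
    )
    return VocabularyBuild(concepts=concepts, relationships=relationships,
                           summary=summary, dedup=dedup)


def emit_vocabulary(
    concepts: Sequence[Concept],
    relationships: Sequence[ConceptRelationship],
    out_dir: str | Path,
) -> dict[str, int]:
    """Write ``CONCEPT.csv`` and ``CONCEPT_RELATIONSHIP.csv``.

    Returns the written row counts per file.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with (out / "CONCEPT.csv").open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(CONCEPT_COLUMNS)
        for c in concepts:
            w.writerow(c.as_row())
    with (out / "CONCEPT_RELATIONSHIP.csv").open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(RELATIONSHIP_COLUMNS)
        for r in relationships:
            w.writerow(r.as_row())
    counts = {"CONCEPT.csv": len(concepts), "CONCEPT_RELATIONSHIP.csv": len(relationships)}
    logger.info("emitted vocabulary: %s", counts)
    return counts


def load_vocabulary(
    directory: str | Path,
) -> tuple[list[Concept], list[ConceptRelationship]]:
    """Re-load emitted vocabulary CSVs into memory (round-trip partner)."""
    directory = Path(directory)
    concepts: list[Concept] = []
    with (directory / "CONCEPT.csv").open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            concepts.append(
                Concept(
                    concept_id=int(row["concept_id"]),
                    concept_name=row["concept_name"],
                    domain_id=row["domain_id"],
                    vocabulary_id=row["vocabulary_id"],
                    concept_class_id=row["concept_class_id"],
                    standard_concept=row["standard_concept"],
                    concept_code=row["concept_code"],
                    valid_start_date=row["valid_start_date"],
                    valid_end_date=row["valid_end_date"],
                    invalid_reason=row["invalid_reason"],
                )
            )
    relationships: list[ConceptRelationship] = []
    with (directory / "CONCEPT_RELATIONSHIP.csv").open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            relationships.append(
                ConceptRelationship(
                    concept_id_1=int(row["concept_id_1"]),
                    concept_id_2=int(row["concept_id_2"]),
                    relationship_id=row["relationship_id"],
                    valid_start_date=row["valid_start_date"],
                    valid_end_date=row["valid_end_date"],
                    invalid_reason=row["invalid_reason"],
                )
            )
    return concepts, relationships
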