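"""Load filtered series metadata into OMOP CDM imaging-extension rows.

Mapping of harvested content onto the medical-imaging extension of the
OMOP CDM:

* one ``Procedure_occurrence`` row per imaging study (date = Study Date);
* one ``Image_occurrence`` row per series (date = Series Date), with the
  Modality and Body Part Examined values resolved to vocabulary concepts
  (0 when unmapped — real-world DICOM is inconsistent in these fields,
  so unresolvable codes are soft);
* one ``Image_feature`` + ``Measurement`` pair per kept header element.
  The Measurement row carries the raw string in ``value_source_value``;
  ``value_as_number`` is set only for numeric VRs that parse, and
  ``value_as_concept_id`` only for coded values that resolve through a
  "Maps to value" relationship — never both.

Dates and times (DA/DT/TM) are stored as source values only; they pass
the VR filter but have no meaningful numeric encoding.
"""

from __future__ import annotations

import csv
import logging
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .dicom_harvester import MetadataElement, SeriesRecord
from .standard_model import BODY_PART_TAG, MODALITY_TAG
from .vocab_builder import MAPS_TO_VALUE, load_vocabulary

logger = logging.getLogger("dicomop")

#: VRs whose values may populate Measurement.value_as_number.
NUMERIC_VRS = frozenset({"DS", "IS", "FL", "FD", "SL", "SS", "SV", "UL", "US", "UV"})

PROCEDURE_COLUMNS = [
    "procedure_occurrence_id", "person_id", "procedure_concept_id",
    "procedure_date", "procedure_source_value",
]
IMAGE_OCCURRENCE_COLUMNS = [
    "image_occurrence_id", "person_id", "procedure_occurrence_id",
    "image_occurrence_date", "image_study_uid", "image_series_uid",
    "modality_concept_id", "modality_source_value",
    "anatomic_site_concept_id", "anatomic_site_source_value",
]
IMAGE_FEATURE_COLUMNS = [
    "image_feature_id", "image_occurrence_id", "image_feature_concept_id",
    "anatomic_site_concept_id", "measurement_id",
]
MEASUREMENT_COLUMNS = [
    "measurement_id", "person_id", "measurement_concept_id", "measurement_date",
    "value_as_number", "value_as_concept_id", "value_source_value",
    "measurement_source_value",
]

TABLE_FILES = {
    "procedure_occurrence": "PROCEDURE_OCCURRENCE.csv",
    "image_occurrence": "IMAGE_OCCURRENCE.csv",
    "image_feature": "IMAGE_FEATURE.csv",
    "measurement": "MEASUREMENT.csv",
}


class PersonMappingError(KeyError):
    """A source patient id has no person_id mapping."""


def parse_da(value: str) -> str:
    """DICOM DA ``YYYYMMDD`` → ISO ``YYYY-MM-DD``; empty/odd input passes
    through unchanged."""
    v = value.strip()
    if len(v) == 8 and v.isdigit():
        return f"{v[:4]}-{v[4:6]}-{v[6:]}"
    return v


# ---------------------------------------------------------------------------
# Vocabulary index over emitted CSVs
# ---------------------------------------------------------------------------


class VocabIndex:
    """Concept lookups over an emitted vocabulary directory.

    Attribute queries resolve by tag; (tag, value) queries follow the
    attribute's "Maps to value" edges to the value concept whose code
    carries that code string.  Misses return 0 with a logged warning.
    """

    def __init__(self, concepts, relationships):
        self._attr_by_tag: dict[str, int] = {}
        self._code_by_id: dict[int, str] = {}
        self._name_by_id: dict[int, str] = {}
        for c in concepts:
            self._code_by_id[c.concept_id] = c.concept_code
            self._name_by_id[c.concept_id] = c.concept_name
            if c.concept_class_id == "Attribute":
                self._attr_by_tag[c.concept_code] = c.concept_id
        # attribute concept id -> {code string -> value concept id}
        self._values_by_attr: dict[int, dict[str, int]] = {}
        for r in relationships:
            if r.relationship_id != MAPS_TO_VALUE:
                continue
            code = self._code_by_id.get(r.concept_id_2, "")
            value_string = code.split(":", 1)[1] if ":" in code else code
            self._values_by_attr.setdefault(r.concept_id_1, {})[value_string] = r.concept_id_2

    @classmethod
    def load(cls, vocab_dir: str | Path) -> "VocabIndex":
        concepts, relationships = load_vocabulary(vocab_dir)
        return cls(concepts, relationships)

    @property
    def attribute_tags(self) -> set[str]:
        return set(self._attr_by_tag)

    def resolve_attribute(self, tag: str) -> int:
        cid = self._attr_by_tag.get(tag, 0)
        if cid == 0:
            logger.warning("no attribute concept for tag %s", tag)
        return cid

    def resolve_value(self, tag: str, value_string: str) -> int:
        attr = self._attr_by_tag.get(tag)
        if attr is None:
            logger.warning("no attribute concept for tag %s", tag)
            return 0
        hit = self._values_by_attr.get(attr, {}).get(value_string, 0)
        if hit == 0:
            logger.warning("no value concept for (%s, %r)", tag, value_string)
        return hit


def resolve_concept(
    vocab: VocabIndex, tag: str, value_string: str | None = None
) -> int:
    """Resolve an attribute tag, or a (tag, value) pair, to a concept id.

    Misses are soft: the lookup returns 0 and logs a warning.
    """
    if value_string is None:
        return vocab.resolve_attribute(tag)
    return vocab.resolve_value(tag, value_string)


# ---------------------------------------------------------------------------
# Row types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProcedureOccurrenceRow:
    procedure_occurrence_id: int
    person_id: int
    procedure_concept_id: int
    procedure_date: str
    procedure_source_value: str  # study UID

    def as_row(self) -> list:
        return [self.procedure_occurrence_id, self.person_id, self.procedure_concept_id,
                self.procedure_date, self.procedure_source_value]


@dataclass(frozen=True)
class ImageOccurrenceRow:
    image_occurrence_id: int
    person_id: int
    procedure_occurrence_id: int
    image_occurrence_date: str
    image_study_uid: str
    image_series_uid: str
    modality_concept_id: int
    modality_source_value: str
    anatomic_site_concept_id: int
    anatomic_site_source_value: str

    def as_row(self) -> list:
        return [self.image_occurrence_id, self.person_id, self.procedure_occurrence_id,
                self.image_occurrence_date, self.image_study_uid, self.image_series_uid,
                self.modality_concept_id, self.modality_source_value,
                self.anatomic_site_concept_id, self.anatomic_site_source_value]


@dataclass(frozen=True)
class ImageFeatureRow:
    image_feature_id: int
    image_occurrence_id: int
    image_feature_concept_id: int
    anatomic_site_concept_id: int
    measurement_id: int

    def as_row(self) -> list:
        return [self.image_feature_id, self.image_occurrence_id, self.image_feature_concept_id,
                self.anatomic_site_concept_id, self.measurement_id]


@dataclass(frozen=True)
class MeasurementRow:
    measurement_id: int
    person_id: int
    measurement_concept_id: int
    measurement_date: str
    value_as_number: float | None
    value_as_concept_id: int | None
    value_source_value: str
    measurement_source_value: str  # the 8-hex tag

    def as_row(self) -> list:
        return [self.measurement_id, self.person_id, self.measurement_concept_id,
                self.measurement_date,
                "" if self.value_as_number is None else repr(self.value_as_number),
                "" if self.value_as_concept_id is None else self.value_as_concept_id,
                self.value_source_value, self.measurement_source_value]


@dataclass
class CdmRows:
    procedure_occurrence: list[ProcedureOccurrenceRow] = field(default_factory=list)
    image_occurrence: list[ImageOccurrenceRow] = field(default_factory=list)
    image_feature: list[ImageFeatureRow] = field(default_factory=list)
    measurement: list[MeasurementRow] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Transformation
# ---------------------------------------------------------------------------


def _measurement_value(
    el: MetadataElement, vocab: VocabIndex
) -> tuple[float | None, int | None]:
    """Derive (value_as_number, value_as_concept_id) for one element.

    Numeric VRs populate the number when the text parses; coded-string
    values try a "Maps to value" lookup.  At most one of the two is set.
    """
    if el.vr in NUMERIC_VRS:
        try:
            return float(el.value), None
        except ValueError:
            return None, None
    if el.vr in {"CS", "AT"}:
        attr = vocab._attr_by_tag.get(el.tag)
        hit = vocab._values_by_attr.get(attr, {}).get(el.value, 0) if attr else 0
        return None, (hit or None)
    return None, None


def build_rows(
    series: Sequence[SeriesRecord],
    kept: Mapping[str, Sequence[MetadataElement]],
    vocab: VocabIndex,
    person_map: Mapping[str, int],
    procedure_concept_id: int = 0,
    on_missing_person: str = "fail",
) -> CdmRows:
    """Transform series records and kept elements into the four row sets.

    Conservation holds by construction: one Image_feature and one
    Measurement row per kept element, one Image_occurrence per series,
    one Procedure_occurrence per study.

    ``on_missing_person`` is ``"fail"`` (raise) or ``"skip"`` (drop the
    series with a warning).
    """
    if on_missing_person not in {"fail", "skip"}:
        raise ValueError("on_missing_person must be 'fail' or 'skip'")
    rows = CdmRows()
    ordered = sorted(series, key=lambda r: (r.patient_id, r.study_uid, r.series_uid))

    procedure_ids: dict[str, int] = {}
    io_id = feat_id = meas_id = 0
    for rec in ordered:
        if rec.patient_id not in person_map:
            if on_missing_person == "skip":
                logger.warning("patient %r has no person mapping; series %s skipped",
                               rec.patient_id, rec.series_uid)
                continue
            raise PersonMappingError(f"no person_id for patient {rec.patient_id!r}")
        person_id = person_map[rec.patient_id]

        if rec.study_uid not in procedure_ids:
            procedure_ids[rec.study_uid] = len(procedure_ids) + 1
            rows.procedure_occurrence.append(
                ProcedureOccurrenceRow(
                    procedure_occurrence_id=procedure_ids[rec.study_uid],
                    person_id=person_id,
                    procedure_concept_id=procedure_concept_id,
                    procedure_date=parse_da(rec.study_date),
                    procedure_source_value=rec.study_uid,
                )
            )

        io_id += 1
        anatomic = vocab.resolve_value(BODY_PART_TAG, rec.body_part) if rec.body_part else 0
        rows.image_occurrence.append(
            ImageOccurrenceRow(
                image_occurrence_id=io_id,
                person_id=person_id,
                procedure_occurrence_id=procedure_ids[rec.study_uid],
                image_occurrence_date=parse_da(rec.series_date),
                image_study_uid=rec.study_uid,
                image_series_uid=rec.series_uid,
                modality_concept_id=(
                    vocab.resolve_value(MODALITY_TAG, rec.modality) if rec.modality else 0
                ),
                modality_source_value=rec.modality,
                anatomic_site_concept_id=anatomic,
                anatomic_site_source_value=rec.body_part,
            )
        )

        for el in kept.get(rec.series_uid, []):
            meas_id += 1
            feat_id += 1
            attr_concept = vocab.resolve_attribute(el.tag)
            number, value_concept = _measurement_value(el, vocab)
            rows.measurement.append(
                MeasurementRow(
                    measurement_id=meas_id,
                    person_id=person_id,
                    measurement_concept_id=attr_concept,
                    measurement_date=parse_da(rec.series_date),
                    value_as_number=number,
                    value_as_concept_id=value_concept,
                    value_source_value=el.value,
                    measurement_source_value=el.tag,
                )
            )
            rows.image_feature.append(
                ImageFeatureRow(
                    image_feature_id=feat_id,
                    image_occurrence_id=io_id,
                    image_feature_concept_id=attr_concept,
                    anatomic_site_concept_id=anatomic,
                    measurement_id=meas_id,
                )
            )
    logger.info(
        "CDM rows: %d procedures, %d image occurrences, %d feature/measurement pairs",
        len(rows.procedure_occurrence), len(rows.image_occurrence), len(rows.measurement),
    )
    return rows


# ---------------------------------------------------------------------------
# Emission: CSVs + relational store
# ---------------------------------------------------------------------------


def emit_cdm(rows: CdmRows, out_dir: str | Path, sqlite_store: bool = True) -> dict[str, int]:
    """Write the four CDM tables as CSVs (and a sqlite mirror).

    Returns row counts per table.  The sqlite store (``cdm.sqlite``)
    holds the same four tables so cohort evaluation can run on SQL.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table_data = {
        "procedure_occurrence": (PROCEDURE_COLUMNS, rows.procedure_occurrence),
        "image_occurrence": (IMAGE_OCCURRENCE_COLUMNS, rows.image_occurrence),
        "image_feature": (IMAGE_FEATURE_COLUMNS, rows.image_feature),
        "measurement": (MEASUREMENT_COLUMNS, rows.measurement),
    }
    counts: dict[str, int] = {}
    for table, (columns, data) in table_data.items():
        with (out / TABLE_FILES[table]).open("w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(columns)
            for row in data:
                w.writerow(row.as_row())
        counts[table] = len(data)

    if sqlite_store:
        db_path = out / "cdm.sqlite"
        if db_path.exists():
            db_path.unlink()
        con = sqlite3.connect(db_path)
        try:
            for table, (columns, data) in table_data.items():
                col_sql = ", ".join(f'"{c}"' for c in columns)
                con.execute(f"CREATE TABLE {table} ({col_sql})")
                placeholders = ", ".join("?" for _ in columns)
                # native field values (not CSV strings) so numeric
                # comparisons in SQL behave numerically
                con.executemany(
                    f"INSERT INTO {table} VALUES ({placeholders})",
                    [tuple(getattr(row, c) for c in columns) for row in data],
                )
            con.commit()
        finally:
            con.close()
    logger.info("emitted CDM tables: %s", counts)
    return counts


def load_cdm(directory: str | Path) -> CdmRows:
    """Re-load emitted CDM CSVs (round-trip partner of :func:`emit_cdm`)."""
    directory = Path(directory)

    def _rows(name: str):
        with (directory / TABLE_FILES[name]).open(newline="", encoding="utf-8") as fh:
            return list(csv.DictReader(fh))

    rows = CdmRows()
    for r in _rows("procedure_occurrence"):
        rows.procedure_occurrence.append(ProcedureOccurrenceRow(
            procedure_occurrence_id=int(r["procedure_occurrence_id"]),
            person_id=int(r["person_id"]),
            procedure_concept_id=int(r["procedure_concept_id"]),
            procedure_date=r["procedure_date"],
            procedure_source_value=r["procedure_source_value"],
        ))
    for r in _rows("image_occurrence"):
        rows.image_occurrence.append(ImageOccurrenceRow(
            image_occurrence_id=int(r["image_occurrence_id"]),
            person_id=int(r["person_id"]),
            procedure_occurrence_id=int(r["procedure_occurrence_id"]),
            image_occurrence_date=r["image_occurrence_date"],
            image_study_uid=r["image_study_uid"],
            image_series_uid=r["image_series_uid"],
            modality_concept_id=int(r["modality_concept_id"]),
            modality_source_value=r["modality_source_value"],
            anatomic_site_concept_id=int(r["anatomic_site_concept_id"]),
            anatomic_site_source_value=r["anatomic_site_source_value"],
        ))
    for r in _rows("image_feature"):
        rows.image_feature.append(ImageFeatureRow(
            image_feature_id=int(r["image_feature_id"]),
            image_occurrence_id=int(r["image_occurrence_id"]),
            image_feature_concept_id=int(r["image_feature_concept_id"]),
            anatomic_site_concept_id=int(r["anatomic_site_concept_id"]),
            measurement_id=int(r["measurement_id"]),
        ))
    for r in _rows("measurement"):
        rows.measurement.append(MeasurementRow(
            measurement_id=int(r["measurement_id"]),
            person_id=int(r["person_id"]),
            measurement_concept_id=int(r["measurement_concept_id"]),
            measurement_date=r["measurement_date"],
            value_as_number=float(r["value_as_number"]) if r["value_as_number"] else None,
            value_as_concept_id=int(r["value_as_concept_id"]) if r["value_as_concept_id"] else None,
            value_source_value=r["value_source_value"],
            measurement_source_value=r["measurement_source_value"],
        ))
    return rows
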