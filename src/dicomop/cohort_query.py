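"""Evaluate imaging-phenotype cohort definitions over loaded CDM tables.

A cohort definition is a conjunction of attribute criteria plus an
optional modality, evaluated with *series-scoped* semantics: a series
matches only if every criterion is satisfied by that same series'
metadata (criteria never mix across series), and a person matches if at
least one of their series matches.  This is the stricter,
protocol-faithful reading — an MPRAGE definition must find TR, TE and TI
on one acquisition, not scattered over a study.

Criteria operate on the Measurement rows reachable from a series through
Image_feature:

* ``present`` — the attribute occurs with a nonempty value;
* ``eq``      — the raw code-string value equals ``value``;
* ``in_range``— ``value_as_number`` lies in [low, high] (inclusive).

Evaluation is store-agnostic: the in-memory (CSV-backed) path and the
generated SQL against the sqlite store return identical UID sets.
"""

from __future__ import annotations

import csv
import logging
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .cdm_loader import CdmRows, VocabIndex
from .standard_model import TAG_RE

logger = logging.getLogger("dicomop")

OPS = frozenset({"present", "eq", "in_range"})

#: Default T1-weighted volumetric (MPRAGE-style) template.  These ranges
#: are calibrated to this package's synthetic MR fixtures — they are
#: configuration defaults to edit per site protocol, not authoritative
#: clinical thresholds.
T1_VOLUMETRIC_TEMPLATE = {
    "modality": "MR",
    "criteria": [
        {"attribute": "00180082", "op": "present"},                      # Inversion Time
        {"attribute": "00180080", "op": "in_range", "low": 2100, "high": 2500},  # TR (ms)
        {"attribute": "00180081", "op": "in_range", "low": 2, "high": 4},        # TE (ms)
    ],
}


class CohortDefinitionError(ValueError):
    """The definition is malformed or references an unknown attribute."""


@dataclass(frozen=True)
class CohortCriterion:
    attribute: str | int  # 8-hex tag or attribute concept id
    op: str
    value: str | None = None
    low: float | None = None
    high: float | None = None

    def __post_init__(self) -> None:
        if self.op not in OPS:
            raise CohortDefinitionError(f"unknown op {self.op!r}")
        if self.op == "eq" and not self.value:
            raise CohortDefinitionError("op=eq requires a value")
        if self.op == "in_range":
            if self.low is None or self.high is None or self.low > self.high:
                raise CohortDefinitionError("op=in_range requires low <= high")
        if isinstance(self.attribute, str) and not TAG_RE.match(self.attribute):
            raise CohortDefinitionError(f"attribute {self.attribute!r} is not an 8-hex tag")


@dataclass(frozen=True)
class CohortDefinition:
    criteria: tuple[CohortCriterion, ...] = ()
    modality: str | None = None

    def __post_init__(self) -> None:
        if not self.criteria and not self.modality:
            raise CohortDefinitionError("definition needs criteria or a modality")

    @classmethod
    def from_dict(cls, payload: Mapping) -> "CohortDefinition":
        criteria = tuple(
            CohortCriterion(
                attribute=c["attribute"],
                op=c["op"],
                value=c.get("value"),
                low=c.get("low"),
                high=c.get("high"),
            )
            for c in payload.get("criteria", [])
        )
        return cls(criteria=criteria, modality=payload.get("modality"))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortDefinition":
        with Path(path).open(encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class CohortResult:
    person_ids: set[int] = field(default_factory=set)
    series_uids: set[str] = field(default_factory=set)
    series_by_person: dict[int, set[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# In-memory evaluation
# ---------------------------------------------------------------------------


def _criterion_series(crit: CohortCriterion, rows: CdmRows) -> set[int]:
    """Image-occurrence ids whose series satisfies one criterion."""
    meas_by_id = {m.measurement_id: m for m in rows.measurement}
    hits: set[int] = set()
    for feat in rows.image_feature:
        m = meas_by_id.get(feat.measurement_id)
        if m is None:
            continue
        if isinstance(crit.attribute, int):
            if m.measurement_concept_id != crit.attribute:
                continue
        elif m.measurement_source_value != crit.attribute:
            continue
        if crit.op == "present":
            ok = bool(m.value_source_value.strip())
        elif crit.op == "eq":
            ok = m.value_source_value == crit.value
        else:  # in_range
            ok = m.value_as_number is not None and crit.low <= m.value_as_number <= crit.high
        if ok:
            hits.add(feat.image_occurrence_id)
    return hits


def evaluate(
    defn: CohortDefinition,
    rows: CdmRows,
    vocab: VocabIndex | None = None,
) -> CohortResult:
    """Evaluate a cohort definition with series-scoped conjunction.

    When a vocabulary index is supplied, tag criteria are validated
    against its Attribute concepts and an unknown tag is a definition
    error; without one, an unknown tag simply matches nothing.
    """
    if vocab is not None:
        known = vocab.attribute_tags
        for crit in defn.criteria:
            if isinstance(crit.attribute, str) and crit.attribute not in known:
                raise CohortDefinitionError(
                    f"criterion references unknown attribute {crit.attribute}"
                )

    matching = {io.image_occurrence_id for io in rows.image_occurrence}
    if defn.modality:
        matching &= {
            io.image_occurrence_id
            for io in rows.image_occurrence
            if io.modality_source_value == defn.modality
        }
    for crit in defn.criteria:
        matching &= _criterion_series(crit, rows)

    result = CohortResult()
    for io in rows.image_occurrence:
        if io.image_occurrence_id in matching:
            result.person_ids.add(io.person_id)
            result.series_uids.add(io.image_series_uid)
            result.series_by_person.setdefault(io.person_id, set()).add(io.image_series_uid)
    logger.info("cohort: %d persons, %d series match", len(result.person_ids),
                len(result.series_uids))
    return result


# ---------------------------------------------------------------------------
# SQL route
# ---------------------------------------------------------------------------


def build_sql(defn: CohortDefinition) -> tuple[str, list]:
    """Render the definition as one parameterized SELECT over the store.

    Each criterion becomes an EXISTS subquery joining Measurement through
    Image_feature back to the candidate Image_occurrence row — the SQL
    mirror of series-scoped conjunction.
    """
    clauses: list[str] = []
    params: list = []
    if defn.modality:
        clauses.append("io.modality_source_value = ?")
        params.append(defn.modality)
    for crit in defn.criteria:
        if isinstance(crit.attribute, int):
            attr_clause = "m.measurement_concept_id = ?"
        else:
            attr_clause = "m.measurement_source_value = ?"
        params.append(crit.attribute)
        if crit.op == "present":
            op_clause = "TRIM(m.value_source_value) <> ''"
        elif crit.op == "eq":
            op_clause = "m.value_source_value = ?"
            params.append(crit.value)
        else:
            op_clause = "m.value_as_number BETWEEN ? AND ?"
            params.extend([crit.low, crit.high])
        clauses.append(
            "EXISTS (SELECT 1 FROM measurement m "
            "JOIN image_feature f ON f.measurement_id = m.measurement_id "
            f"WHERE f.image_occurrence_id = io.image_occurrence_id AND {attr_clause} "
            f"AND {op_clause})"
        )
    where = " AND ".join(clauses) if clauses else "1=1"
    sql = (
        "SELECT io.person_id, io.image_series_uid FROM image_occurrence io "
        f"WHERE {where} ORDER BY io.image_series_uid"
    )
    return sql, params


def evaluate_sql(defn: CohortDefinition, sqlite_path: str | Path) -> CohortResult:
    """Evaluate the definition against the sqlite store."""
    sql, params = build_sql(defn)
    con = sqlite3.connect(sqlite_path)
    try:
        result = CohortResult()
        for person_id, series_uid in con.execute(sql, params):
            pid = int(person_id)
            result.person_ids.add(pid)
            result.series_uids.add(series_uid)
            result.series_by_person.setdefault(pid, set()).add(series_uid)
        return result
    finally:
        con.close()


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def export_result(
    result: CohortResult,
    out_dir: str | Path,
    defn: CohortDefinition | None = None,
) -> None:
    """Write series UIDs (one per line), a person CSV, and the SQL text.

    Empty results produce empty (header-only) files and succeed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with (out / "series_uids.txt").open("w", encoding="utf-8") as fh:
        for uid in sorted(result.series_uids):
            fh.write(uid + "\n")
    with (out / "persons.csv").open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["person_id", "n_matched_series"])
        for pid in sorted(result.person_ids):
            w.writerow([pid, len(result.series_by_person.get(pid, ()))])
    if defn is not None:
        sql, params = build_sql(defn)
        with (out / "cohort.sql").open("w", encoding="utf-8") as fh:
            fh.write("-- parameterized series-scoped cohort query\n")
            fh.write(sql + ";\n")
            fh.write(f"-- parameters: {params!r}\n")
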