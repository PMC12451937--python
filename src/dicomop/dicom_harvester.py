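"""Harvest series-level metadata from a DICOM Part-10 file tree.

The harvest works at the series level: every distinct Series Instance
UID contributes exactly one representative instance (lowest Instance
Number, ties broken by lexicographic file path), whose top-level header
elements are extracted as key–value pairs.  Sequence contents are not
descended, pixel data is never loaded, and private (odd-group) tags are
excluded outright.

Filtering then applies a VR whitelist covering numeric and coded values

    AT CS DA DT DS FL FD IS SL SS SV TM UL US UV

with a single free-text exception — Manufacturer (0008,0070) — and
drops any element whose value is empty after trimming whitespace and
trailing null padding.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pydicom
from pydicom.errors import InvalidDicomError
from pydicom.multival import MultiValue

from .standard_model import MANUFACTURER_TAG

logger = logging.getLogger("dicomop")

#: VRs kept by the filter: every numeric or coded representation.
VR_WHITELIST = frozenset(
    {"AT", "CS", "DA", "DT", "DS", "FL", "FD", "IS", "SL", "SS", "SV", "TM", "UL", "US", "UV"}
)

#: VRs whose payloads are binary buffers; they carry no scalar text and
#: are skipped at harvest time (they are outside the whitelist anyway).
_BINARY_VRS = frozenset({"OB", "OW", "OD", "OF", "OL", "OV", "UN", "SQ"})

#: Pixel-data element tags (float, double-float and classic).
_PIXEL_TAGS = frozenset({0x7FE00008, 0x7FE00009, 0x7FE00010})

HARVEST_COLUMNS = [
    "patient_id", "study_uid", "series_uid", "tag", "keyword", "vr", "value", "value_index",
]
SERIES_COLUMNS = [
    "patient_id", "study_uid", "series_uid", "study_date", "series_date",
    "modality", "body_part", "representative_file",
]


@dataclass(frozen=True)
class SeriesRecord:
    """One imaging series with its representative instance."""

    patient_id: str
    study_uid: str
    series_uid: str
    study_date: str
    series_date: str
    modality: str
    body_part: str
    representative_file: str


@dataclass(frozen=True)
class MetadataElement:
    """One harvested scalar header value.

    Multi-valued attributes are expanded to one element per value, with
    ``value_index`` giving the 0-based position.
    """

    tag: str
    keyword: str
    vr: str
    value: str
    value_index: int = 0


def _trim(value: str) -> str:
    """DICOM string normalization: strip whitespace and null padding."""
    return value.strip().strip("\x00").strip()


def _element_text(raw) -> str:
    if raw is None:
        return ""
    return _trim(str(raw))


# ---------------------------------------------------------------------------
# Indexing
# ---------------------------------------------------------------------------


def index_dataset(root: str | Path) -> list[SeriesRecord]:
    """Walk a DICOM tree and build one :class:`SeriesRecord` per series.

    The representative instance of a series is the file with the lowest
    Instance Number (0020,0013); ties and missing Instance Numbers fall
    back to lexicographic file-path order.  Files that are not DICOM or
    lack a Series Instance UID are logged and skipped.

    Raises ``FileNotFoundError`` for an unreadable root; an empty tree
    yields an empty index with a warning.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"DICOM root {root} is not a readable directory")

    # (series_uid) -> (sort_key, candidate fields)
    best: dict[str, tuple[tuple[int, str], SeriesRecord]] = {}
    n_skipped = 0
    for path in sorted(p for p in root.rglob("*") if p.is_file()):
        try:
            ds = pydicom.dcmread(path, stop_before_pixels=True)
        except (InvalidDicomError, OSError, ValueError):
            n_skipped += 1
            continue
        series_uid = _element_text(getattr(ds, "SeriesInstanceUID", ""))
        if not series_uid:
            logger.warning("file %s has no Series Instance UID; skipped", path)
            n_skipped += 1
            continue
        try:
            instance_number = int(ds.InstanceNumber)
        except (AttributeError, TypeError, ValueError):
            instance_number = 2**31
        key = (instance_number, str(path))
        record = SeriesRecord(
            patient_id=_element_text(getattr(ds, "PatientID", "")),
            study_uid=_element_text(getattr(ds, "StudyInstanceUID", "")),
            series_uid=series_uid,
            study_date=_element_text(getattr(ds, "StudyDate", "")),
            series_date=_element_text(getattr(ds, "SeriesDate", "")),
            modality=_element_text(getattr(ds, "Modality", "")),
            body_part=_element_text(getattr(ds, "BodyPartExamined", "")),
            representative_file=str(path),
        )
        current = best.get(series_uid)
        if current is None or key < current[0]:
            best[series_uid] = (key, record)

    records = sorted(
        (rec for _, rec in best.values()),
        key=lambda r: (r.patient_id, r.study_uid, r.series_uid),
    )
    if not records:
        logger.warning("no DICOM series found under %s", root)
    if n_skipped:
        logger.info("index: skipped %d non-DICOM/UID-less files", n_skipped)
    return records


# ---------------------------------------------------------------------------
# Header extraction
# ---------------------------------------------------------------------------


def harvest_header(file: str | Path) -> list[MetadataElement]:
    """Extract the top-level header of one instance as scalar elements.

    Excluded outright: private (odd-group) tags, pixel-data tags,
    sequences and binary-buffer VRs.  Multi-valued attributes expand to
    one element per value.  Values are decoded per the file's specific
    character set; a value that fails to decode is replaced rather than
    aborting the harvest.

    Raises a parse error naming the file for non-DICOM input.
    """
    path = Path(file)
    try:
        ds = pydicom.dcmread(path, stop_before_pixels=True)
    except (InvalidDicomError, ValueError) as exc:
        raise InvalidDicomError(f"cannot parse DICOM file {path}: {exc}") from exc

    out: list[MetadataElement] = []
    n_binary = 0
    for elem in ds:
        tag_int = int(elem.tag)
        if elem.tag.group % 2 == 1:  # private tag
            continue
        if tag_int in _PIXEL_TAGS:
            continue
        if elem.VR in _BINARY_VRS:
            n_binary += 1
            continue
        tag = f"{elem.tag.group:04X}{elem.tag.element:04X}"
        keyword = elem.keyword or ""
        try:
            raw = elem.value
        except Exception:  # charset or parse trouble in one element
            raw = ""
        if isinstance(raw, (MultiValue, list, tuple)):
            values = [_element_text(v) for v in raw]
        else:
            values = [_element_text(raw)]
        for idx, text in enumerate(values):
            out.append(MetadataElement(tag=tag, keyword=keyword, vr=elem.VR,
                                       value=text, value_index=idx))
    if n_binary:
        logger.debug("%s: skipped %d sequence/binary elements", path.name, n_binary)
    return out


# ---------------------------------------------------------------------------
# VR filter
# ---------------------------------------------------------------------------


def filter_elements(elements: Sequence[MetadataElement]) -> list[MetadataElement]:
    """Apply the VR whitelist with the Manufacturer free-text exception.

    Pure, order-preserving and idempotent: an element is kept iff its
    trimmed value is nonempty AND (its VR is whitelisted OR its tag is
    Manufacturer (0008,0070)).  Drop counts per reason are logged.
    """
    kept: list[MetadataElement] = []
    n_empty = 0
    n_vr = 0
    for el in elements:
        if not _trim(el.value):
            n_empty += 1
            continue
        if el.vr in VR_WHITELIST or el.tag == MANUFACTURER_TAG:
            kept.append(el)
        else:
            n_vr += 1
    logger.info(
        "filter: kept %d of %d elements (%d empty-valued, %d excluded VR)",
        len(kept), len(elements), n_empty, n_vr,
    )
    return kept


# ---------------------------------------------------------------------------
# Whole-tree harvest + CSV emission
# ---------------------------------------------------------------------------


def harvest_dataset(
    root: str | Path, apply_filter: bool = True
) -> tuple[list[SeriesRecord], dict[str, list[MetadataElement]]]:
    """Index a tree and harvest each series' representative header.

    Returns the series index and a map series_uid → elements (filtered
    by default).
    """
    records = index_dataset(root)
    elements: dict[str, list[MetadataElement]] = {}
    n_raw = 0
    for rec in records:
        els = harvest_header(rec.representative_file)
        n_raw += len(els)
        elements[rec.series_uid] = filter_elements(els) if apply_filter else els
    n_kept = sum(len(v) for v in elements.values())
    logger.info("harvested %d series: %d raw elements, %d retained", len(records), n_raw, n_kept)
    return records, elements


def write_harvest_csv(
    records: Sequence[SeriesRecord],
    elements: dict[str, list[MetadataElement]],
    out_path: str | Path,
) -> None:
    """Write the long-format harvest CSV plus a series-index sidecar.

    ``<out>.csv`` holds one row per harvested element; the sidecar
    ``<out stem>.series.csv`` holds one row per series.
    """
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    with out_path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(HARVEST_COLUMNS)
        for rec in records:
            for el in elements.get(rec.series_uid, []):
                w.writerow([rec.patient_id, rec.study_uid, rec.series_uid,
                            el.tag, el.keyword, el.vr, el.value, el.value_index])
    sidecar = out_path.with_suffix(".series.csv")
    with sidecar.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(SERIES_COLUMNS)
        for rec in records:
            w.writerow([rec.patient_id, rec.study_uid, rec.series_uid, rec.study_date,
                        rec.series_date, rec.modality, rec.body_part, rec.representative_file])


def read_harvest_csv(
    harvest_path: str | Path,
) -> tuple[list[SeriesRecord], dict[str, list[MetadataElement]]]:
    """Re-load a harvest CSV pair written by :func:`write_harvest_csv`."""
    harvest_path = Path(harvest_path)
    sidecar = harvest_path.with_suffix(".series.csv")
    records: list[SeriesRecord] = []
    with sidecar.open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            records.append(SeriesRecord(**row))
    elements: dict[str, list[MetadataElement]] = {r.series_uid: [] for r in records}
    with harvest_path.open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            elements.setdefault(row["series_uid"], []).append(
                MetadataElement(tag=row["tag"], keyword=row["keyword"], vr=row["vr"],
                                value=row["value"], value_index=int(row["value_index"]))
            )
    return records, elements
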