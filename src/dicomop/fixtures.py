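"""Synthetic inputs: standard bundles, DICOM file trees, and EHR tables.

Everything downstream of this package is exercised on generated data, so
the generators double as ground-truth oracles: each one emits a manifest
of the counts it constructed, against which pipeline output is checked.

Three generators:

* :func:`make_standard_fixture` — a normalized DICOM-Standard interchange
  directory.  The default profile ("table2") reproduces the published
  category counts of the standard's content exactly: 5190 dictionary
  attributes (7 nameless), 5223 DICOM-managed context-group occurrences
  over 3281 distinct codes (1063 in more than one CID), 398 body-part
  cross-map rows, Part-3 term counts 79/318/16/8 for Modality / Body
  Part Examined / Patient Position / Lossy Image Compression Method with
  74 Modality terms duplicating CID codes, constraints sized to yield
  7101 CID-derived and 739 term-derived "Maps to value" rows, and 307
  body-part values resolvable to SNOMED.
* :func:`make_dicom_fixture` — a patient/study/series/instance tree of
  MR Part-10 files emulating volumetric-imaging study data: MPRAGE
  series carry an Inversion Time, T2/FLAIR differ in TR/TE, plus
  deliberately empty values, free-text fields, private tags and a
  sequence to exercise the harvest filter.
* :func:`make_ehr_fixture` — simulated Person / Condition_occurrence /
  Measurement CSVs with a cognitively-normal : MCI : AD diagnosis mix
  defaulting to 133:151:87, plus the patient-id → person_id map.

All identifiers are unmistakably synthetic: UIDs sit under the
documentation enterprise OID 1.3.6.1.4.1.32473 and patient ids follow
``SYN-%04d``.  Every generator is deterministic given its seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from pydicom.dataset import FileDataset, FileMetaDataset, Dataset
from pydicom.uid import ExplicitVRLittleEndian

from .standard_model import (
    BODY_PART_TAG,
    LOSSY_COMPRESSION_METHOD_TAG,
    MODALITY_TAG,
    PATIENT_POSITION_TAG,
    AttributeDef,
    AttributeValueConstraint,
    CodedValue,
    DefinedTerm,
    StandardBundle,
    write_standard_bundle,
)

UID_ROOT = "1.3.6.1.4.1.32473.9"  # documentation/example enterprise OID


class FixtureGenerationError(ValueError):
    """A fixture profile is internally inconsistent."""


# ---------------------------------------------------------------------------
# Standard-content fixture
# ---------------------------------------------------------------------------

#: Real Part-6 entries the pipeline relies on (tag, name, keyword, vr).
CORE_ATTRIBUTES: list[tuple[str, str, str, str]] = [
    ("00080005", "Specific Character Set", "SpecificCharacterSet", "CS"),
    ("00080008", "Image Type", "ImageType", "CS"),
    ("00080016", "SOP Class UID", "SOPClassUID", "UI"),
    ("00080018", "SOP Instance UID", "SOPInstanceUID", "UI"),
    ("00080020", "Study Date", "StudyDate", "DA"),
    ("00080021", "Series Date", "SeriesDate", "DA"),
    ("00080022", "Acquisition Date", "AcquisitionDate", "DA"),
    ("00080030", "Study Time", "StudyTime", "TM"),
    ("00080060", "Modality", "Modality", "CS"),
    ("00080070", "Manufacturer", "Manufacturer", "LO"),
    ("0008103E", "Series Description", "SeriesDescription", "LO"),
    ("00100010", "Patient's Name", "PatientName", "PN"),
    ("00100020", "Patient ID", "PatientID", "LO"),
    ("00180015", "Body Part Examined", "BodyPartExamined", "CS"),
    ("00180020", "Scanning Sequence", "ScanningSequence", "CS"),
    ("00180022", "Scan Options", "ScanOptions", "CS"),
    ("00180080", "Repetition Time", "RepetitionTime", "DS"),
    ("00180081", "Echo Time", "EchoTime", "DS"),
    ("00180082", "Inversion Time", "InversionTime", "DS"),
    ("00180087", "Magnetic Field Strength", "MagneticFieldStrength", "DS"),
    ("00180091", "Echo Train Length", "EchoTrainLength", "IS"),
    ("00181030", "Protocol Name", "ProtocolName", "LO"),
    ("00181314", "Flip Angle", "FlipAngle", "DS"),
    ("00185100", "Patient Position", "PatientPosition", "CS"),
    ("0020000D", "Study Instance UID", "StudyInstanceUID", "UI"),
    ("0020000E", "Series Instance UID", "SeriesInstanceUID", "UI"),
    ("00200013", "Instance Number", "InstanceNumber", "IS"),
    ("00280010", "Rows", "Rows", "US"),
    ("00280011", "Columns", "Columns", "US"),
    ("00282114", "Lossy Image Compression Method", "LossyImageCompressionMethod", "CS"),
]

PATIENT_POSITION_VALUES = [
    "HFS", "HFP", "FFS", "FFP", "HFDR", "HFDL", "FFDR", "FFDL",
    "LFP", "LFS", "RFP", "RFS", "AFDR", "AFDL", "PFDR", "PFDL",
]
COMPRESSION_VALUES = [
    "ISO_10918_1", "ISO_14495_1", "ISO_15444_1", "ISO_13818_2",
    "ISO_14496_10", "ISO_15444_15", "ISO_23008_2", "ISO_10918_4",
]
MODALITY_UNIQUE_VALUES = ["MR", "CT", "US", "PT", "CR"]


@dataclass(frozen=True)
class StandardFixtureProfile:
    """Category counts the generated standard content must hit.

    The defaults are the published category totals (the "table2"
    profile).  The repeated-code multiplicity plan — 2218 codes in one
    CID, 879 in three, 184 in two — is one admissible layout of the
    under-determined totals (5223 occurrences, 3281 distinct, 1063
    repeated) and is fixed here so downstream counts are exact.
    """

    n_attributes: int = 5190
    n_nameless: int = 7
    cid_multiplicity_plan: tuple[tuple[int, int], ...] = ((2218, 1), (879, 3), (184, 2))
    n_cid_occurrences: int | None = 5223
    n_foreign_cid_rows: int = 20
    n_bodypart_p16: int = 398
    n_bodypart_terms: int = 318
    n_modality_terms: int = 79
    n_modality_overlap: int = 74
    n_patientposition_terms: int = 16
    n_compression_terms: int = 8
    n_extra_dup_terms: int = 318
    n_snomed_mapped: int = 307
    cid_maps_to_value_target: int | None = 7101
    single_bucket: int = 100
    first_single_bucket: int = 120
    seed: int = 1

    def __post_init__(self) -> None:
        counts = [
            self.n_attributes, self.n_nameless, self.n_bodypart_p16,
            self.n_bodypart_terms, self.n_modality_terms, self.n_modality_overlap,
            self.n_patientposition_terms, self.n_compression_terms,
            self.n_extra_dup_terms, self.n_snomed_mapped,
        ]
        if any(c < 0 for c in counts):
            raise FixtureGenerationError("profile counts must be non-negative")
        if self.n_modality_overlap > self.n_modality_terms:
            raise FixtureGenerationError("modality overlap exceeds modality term count")
        if self.n_nameless > self.n_attributes:
            raise FixtureGenerationError("nameless count exceeds attribute count")
        occurrences = sum(n * m for n, m in self.cid_multiplicity_plan)
        if self.n_cid_occurrences is not None and occurrences != self.n_cid_occurrences:
            raise FixtureGenerationError(
                f"multiplicity plan yields {occurrences} occurrences, "
                f"profile declares {self.n_cid_occurrences}"
            )

    @classmethod
    def table2(cls, seed: int = 1) -> "StandardFixtureProfile":
        return cls(seed=seed)

    @classmethod
    def tiny(cls, seed: int = 1) -> "StandardFixtureProfile":
        """Five attributes, one CID of three codes, nothing else."""
        return cls(
            n_attributes=5, n_nameless=0,
            cid_multiplicity_plan=((3, 1),), n_cid_occurrences=3,
            n_foreign_cid_rows=0, n_bodypart_p16=0, n_bodypart_terms=0,
            n_modality_terms=0, n_modality_overlap=0,
            n_patientposition_terms=0, n_compression_terms=0,
            n_extra_dup_terms=0, n_snomed_mapped=0,
            cid_maps_to_value_target=None,
            single_bucket=3, first_single_bucket=3, seed=seed,
        )


def _synthetic_attributes(profile: StandardFixtureProfile) -> list[AttributeDef]:
    n_named = profile.n_attributes - profile.n_nameless
    core = CORE_ATTRIBUTES[:n_named]
    attrs = [
        AttributeDef(tag=t, name=n, keyword=k, vr=vr) for t, n, k, vr in core
    ]
    vr_cycle = ["DS", "CS", "IS", "LO", "US", "TM", "UI", "SH", "FD"]
    for i in range(n_named - len(core)):
        attrs.append(
            AttributeDef(
                tag=f"4000{i:04X}",
                name=f"Synthetic Attribute {i:04d}",
                keyword=f"SyntheticAttribute{i:04d}",
                vr=vr_cycle[i % len(vr_cycle)],
                retired=(i % 97 == 0),
            )
        )
    for i in range(profile.n_nameless):
        attrs.append(AttributeDef(tag=f"4002{i:04X}", name="", keyword="", vr="UN"))
    return attrs


def _cid_layout(profile: StandardFixtureProfile) -> tuple[list[str], dict[int, list[str]]]:
    """Lay distinct DCM codes out into context groups per the plan.

    Returns (all distinct codes, cid -> member code list).
    """
    cids: dict[int, list[str]] = {}
    codes: list[str] = []
    next_cid = 9000
    next_code = 100000
    for count, mult in profile.cid_multiplicity_plan:
        group = [str(next_code + i) for i in range(count)]
        next_code += count
        codes.extend(group)
        if mult == 1:
            sizes: list[int] = []
            remaining = count
            first = min(profile.first_single_bucket, remaining)
            if first:
                sizes.append(first)
                remaining -= first
            while remaining > 0:
                take = min(profile.single_bucket, remaining)
                sizes.append(take)
                remaining -= take
            offset = 0
            for size in sizes:
                cids[next_cid] = group[offset:offset + size]
                offset += size
                next_cid += 1
        else:
            for _ in range(mult):
                cids[next_cid] = list(group)
                next_cid += 1
    return codes, cids


def _plan_constraints(
    cids: Mapping[int, list[str]],
    target: int | None,
) -> list[int]:
    """Choose the constrained CID multiset: every CID once, plus greedy
    repeats of the largest fitting CIDs until the "Maps to value" target
    is met exactly.  An unreachable target is a generation error."""
    chosen = sorted(cids)
    if target is None:
        return chosen
    base = sum(len(v) for v in cids.values())
    deficit = target - base
    if deficit < 0:
        raise FixtureGenerationError(f"target {target} below base membership {base}")
    sizes = sorted(((len(v), cid) for cid, v in cids.items()), reverse=True)
    while deficit > 0:
        for size, cid in sizes:
            if size <= deficit:
                chosen.append(cid)
                deficit -= size
                break
        else:
            raise FixtureGenerationError(
                f"cannot meet Maps-to-value target exactly; residual {deficit}"
            )
    return chosen


def build_standard_fixture_bundle(
    profile: StandardFixtureProfile,
) -> tuple[StandardBundle, dict[tuple[str, str], int]]:
    """Construct the in-memory bundle and the stub SNOMED resolver map."""
    rng = np.random.default_rng(profile.seed)
    attributes = _synthetic_attributes(profile)
    named = [a for a in attributes if a.name]
    semantic_tags = {MODALITY_TAG, BODY_PART_TAG, PATIENT_POSITION_TAG,
                     LOSSY_COMPRESSION_METHOD_TAG}
    pool = [a.tag for a in reversed(named) if a.tag not in semantic_tags]

    codes, cid_members = _cid_layout(profile)
    occurrences: list[CodedValue] = []
    for cid, members in cid_members.items():
        for code in members:
            occurrences.append(
                CodedValue(code_value=code, coding_scheme="DCM",
                           code_meaning=f"Synthetic coded value {code}",
                           cids=frozenset({cid}))
            )
    foreign_cid = 8999
    for i in range(profile.n_foreign_cid_rows):
        occurrences.append(
            CodedValue(code_value=str(30000000 + i), coding_scheme="SCT",
                       code_meaning=f"External concept {i}",
                       cids=frozenset({foreign_cid}))
        )
    constrained = _plan_constraints(cid_members, profile.cid_maps_to_value_target)
    if profile.n_foreign_cid_rows:
        constrained.append(foreign_cid)
    if len(constrained) + 1 > len(pool):
        raise FixtureGenerationError("not enough named attributes for constraints")
    dup_term_tag = pool[0]
    cid_constraints = [
        AttributeValueConstraint(attribute_tag=pool[i + 1], constraint_kind="CID", cid=cid)
        for i, cid in enumerate(constrained)
    ]

    # --- Part-3 terms ------------------------------------------------------
    terms: list[DefinedTerm] = []
    n_unique_modality = profile.n_modality_terms - profile.n_modality_overlap
    for v in MODALITY_UNIQUE_VALUES[:n_unique_modality]:
        terms.append(DefinedTerm(MODALITY_TAG, v, f"Modality {v}", "Defined"))
    for i in range(n_unique_modality - len(MODALITY_UNIQUE_VALUES)):
        terms.append(DefinedTerm(MODALITY_TAG, f"MODX{i:03d}", f"Modality X{i}", "Defined"))
    # overlap terms reuse DCM code strings, so dedup drops them later
    singles = [c for c, (count, mult) in _expand_codes(profile) if mult == 1]
    multi = [c for c, (count, mult) in _expand_codes(profile) if mult > 1]
    if profile.n_modality_overlap > len(singles):
        raise FixtureGenerationError("not enough single-CID codes for modality overlap")
    for code in singles[:profile.n_modality_overlap]:
        terms.append(DefinedTerm(MODALITY_TAG, code, f"Modality dup {code}", "Defined"))

    bodypart_values = (["BRAIN"] + [f"BPART{i:03d}" for i in range(1, profile.n_bodypart_terms)])
    bodypart_values = bodypart_values[:profile.n_bodypart_terms]
    for v in bodypart_values:
        terms.append(DefinedTerm(BODY_PART_TAG, v, f"Body part {v}", "Defined"))
    for v in PATIENT_POSITION_VALUES[:profile.n_patientposition_terms]:
        terms.append(DefinedTerm(PATIENT_POSITION_TAG, v, f"Patient position {v}", "Enumerated"))
    for i in range(max(0, profile.n_patientposition_terms - len(PATIENT_POSITION_VALUES))):
        terms.append(DefinedTerm(PATIENT_POSITION_TAG, f"POSX{i:03d}", f"Position X{i}", "Enumerated"))
    for v in COMPRESSION_VALUES[:profile.n_compression_terms]:
        terms.append(DefinedTerm(LOSSY_COMPRESSION_METHOD_TAG, v, f"Compression {v}", "Defined"))

    dup_source = multi if len(multi) >= profile.n_extra_dup_terms else codes
    if profile.n_extra_dup_terms > len(dup_source):
        raise FixtureGenerationError("not enough DCM codes for extra duplicate terms")
    for code in dup_source[:profile.n_extra_dup_terms]:
        terms.append(DefinedTerm(dup_term_tag, code, f"Aux dup {code}", "Defined"))

    term_constraints = _group_terms(terms)

    # --- Body-part cross-map and resolver ----------------------------------
    bp_map: list[tuple[str, str]] = []
    resolver_map: dict[tuple[str, str], int] = {}
    n_mapped = min(profile.n_snomed_mapped, len(bodypart_values))
    if n_mapped < profile.n_snomed_mapped:
        raise FixtureGenerationError("n_snomed_mapped exceeds body-part term count")
    for i, v in enumerate(bodypart_values[:n_mapped]):
        snomed = "12738006" if v == "BRAIN" else str(9000000 + i)
        bp_map.append((v, snomed))
        resolver_map[("SCT", snomed)] = 36000000 + i
    # unresolvable rows: known value, SNOMED missing from the resolver (or absent)
    leftover = bodypart_values[n_mapped:]
    for j, v in enumerate(leftover):
        snomed = str(8800000 + j) if j % 2 == 0 else ""
        bp_map.append((v, snomed))
    # rows with no code string at all (SNOMED-only body parts)
    for j in range(profile.n_bodypart_p16 - len(bp_map)):
        bp_map.append(("", str(8700000 + j)))
    if len(bp_map) != profile.n_bodypart_p16:
        raise FixtureGenerationError(
            f"body-part map has {len(bp_map)} rows, profile declares {profile.n_bodypart_p16}"
        )

    # deterministic shuffles exercise order-insensitivity downstream
    occurrences = [occurrences[i] for i in rng.permutation(len(occurrences))]
    terms = [terms[i] for i in rng.permutation(len(terms))]

    bundle = StandardBundle(
        attributes=attributes,
        coded_values=occurrences,
        defined_terms=terms,
        constraints=cid_constraints + term_constraints,
        bodypart_snomed_map=bp_map,
    )
    bundle.validate()
    return bundle, resolver_map


def _expand_codes(profile: StandardFixtureProfile) -> list[tuple[str, tuple[int, int]]]:
    out = []
    next_code = 100000
    for count, mult in profile.cid_multiplicity_plan:
        for i in range(count):
            out.append((str(next_code + i), (count, mult)))
        next_code += count
    return out


def _group_terms(terms: Sequence[DefinedTerm]) -> list[AttributeValueConstraint]:
    by_attr: dict[str, list[DefinedTerm]] = {}
    for t in terms:
        by_attr.setdefault(t.attribute_tag, []).append(t)
    return [
        AttributeValueConstraint(attribute_tag=tag, constraint_kind="TermList",
                                 term_refs=tuple(group))
        for tag, group in sorted(by_attr.items())
    ]


def make_standard_fixture(
    profile: StandardFixtureProfile, out_dir: str | Path
) -> StandardBundle:
    """Write the interchange directory (plus ``snomed_resolver.csv``)."""
    bundle, resolver_map = build_standard_fixture_bundle(profile)
    out = Path(out_dir)
    write_standard_bundle(bundle, out)
    with (out / "snomed_resolver.csv").open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["scheme", "code", "concept_id"])
        for (scheme, code), concept_id in sorted(resolver_map.items()):
            w.writerow([scheme, code, concept_id])
    return bundle


# ---------------------------------------------------------------------------
# DICOM file-tree fixture
# ---------------------------------------------------------------------------

#: MR protocol parameter profiles (milliseconds).  MPRAGE is the
#: T1-weighted volumetric protocol and is the only one carrying an
#: inversion pulse, hence an Inversion Time.
PROTOCOLS = {
    "MPRAGE": {"tr": 2300.0, "te": 2.98, "ti": 900.0,
               "description": "Accelerated Sagittal MPRAGE",
               "tr_jitter": 80.0, "te_jitter": 0.3},
    "T2": {"tr": 3200.0, "te": 409.0, "ti": None,
           "description": "Sagittal 3D T2 SPACE",
           "tr_jitter": 150.0, "te_jitter": 10.0},
    "FLAIR": {"tr": 4800.0, "te": 119.0, "ti": 1650.0,
              "description": "Axial T2 FLAIR",
              "tr_jitter": 150.0, "te_jitter": 5.0},
}


@dataclass(frozen=True)
class DicomFixtureSpec:
    """Shape of the synthetic MR tree (one study per patient)."""

    n_patients: int = 5
    series_per_patient: int = 8
    instances_per_series: int = 3
    protocol_mix: tuple[tuple[str, float], ...] = (
        ("MPRAGE", 0.5), ("T2", 0.25), ("FLAIR", 0.25),
    )
    missing_bodypart_rate: float = 0.1
    empty_value_rate: float = 0.1
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.series_per_patient < 1 or self.instances_per_series < 1:
            raise FixtureGenerationError("tree dimensions must be positive")
        total = sum(f for _, f in self.protocol_mix)
        if abs(total - 1.0) > 1e-9:
            raise FixtureGenerationError("protocol fractions must sum to 1")
        for name, _ in self.protocol_mix:
            if name not in PROTOCOLS:
                raise FixtureGenerationError(f"unknown protocol {name!r}")
        for rate in (self.missing_bodypart_rate, self.empty_value_rate):
            if not 0.0 <= rate <= 1.0:
                raise FixtureGenerationError("rates must lie in [0, 1]")


MANIFEST_COLUMNS = [
    "patient_id", "study_uid", "series_uid", "protocol", "series_date",
    "body_part", "has_ti", "n_instances", "n_kept_expected",
]


def _allocate_protocols(spec: DicomFixtureSpec, rng: np.random.Generator) -> list[str]:
    """Largest-remainder allocation of protocols over all series, then a
    seeded shuffle — exact counts, randomized placement."""
    total = spec.n_patients * spec.series_per_patient
    quotas = [(name, frac * total) for name, frac in spec.protocol_mix]
    counts = {name: int(q) for name, q in quotas}
    leftover = total - sum(counts.values())
    remainders = sorted(quotas, key=lambda x: x[1] - int(x[1]), reverse=True)
    for name, _ in remainders[:leftover]:
        counts[name] += 1
    assigned = [name for name, n in counts.items() for _ in range(n)]
    return [assigned[i] for i in rng.permutation(total)]


def make_dicom_fixture(spec: DicomFixtureSpec, out_dir: str | Path) -> list[dict]:
    """Write the Part-10 tree and its ground-truth manifest.

    Returns the manifest rows (also written to ``manifest.csv`` at the
    tree root).  ``n_kept_expected`` is determined at construction time
    from what each element *is* (VR, emptiness, privateness), so it is an
    oracle for the harvest-filter-load chain that does not depend on the
    harvester's code.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    protocols = _allocate_protocols(spec, rng)
    manifest: list[dict] = []

    slot = 0
    for p in range(1, spec.n_patients + 1):
        patient_id = f"SYN-{p:04d}"
        study_uid = f"{UID_ROOT}.1.{spec.seed}.{p}"
        study_date = f"2017{(p - 1) % 12 + 1:02d}{(p * 7) % 27 + 1:02d}"
        for s in range(1, spec.series_per_patient + 1):
            protocol = protocols[slot]
            slot += 1
            params = PROTOCOLS[protocol]
            series_uid = f"{UID_ROOT}.2.{spec.seed}.{p}.{s}"
            tr = params["tr"] + float(rng.uniform(-1, 1)) * params["tr_jitter"]
            te = params["te"] + float(rng.uniform(-1, 1)) * params["te_jitter"]
            ti = params["ti"]
            missing_bp = bool(rng.random() < spec.missing_bodypart_rate)
            empty_scan_options = bool(rng.random() < spec.empty_value_rate)

            # element plan: (keyword, value, kept?) — kept is decided here,
            # by construction, not by calling the filter
            kept_plan = [
                ("SpecificCharacterSet", "ISO_IR 100", 1),
                ("ImageType", ["ORIGINAL", "PRIMARY"], 2),  # multi-value
                ("StudyDate", study_date, 1),
                ("SeriesDate", study_date, 1),
                ("StudyTime", "081500", 1),
                ("Modality", "MR", 1),
                ("Manufacturer", "SYN Imaging", 1),  # LO kept by exception
                ("ScanningSequence", "GR" if protocol == "MPRAGE" else "SE", 1),
                ("PatientPosition", "HFS", 1),
                ("RepetitionTime", f"{tr:.1f}", 1),
                ("EchoTime", f"{te:.2f}", 1),
                ("MagneticFieldStrength", "3", 1),
                ("EchoTrainLength", "1" if protocol == "MPRAGE" else "16", 1),
                ("FlipAngle", "9", 1),
                ("Rows", 16, 1),
                ("Columns", 16, 1),
                ("InstanceNumber", None, 1),  # per instance
            ]
            if ti is not None:
                kept_plan.append(("InversionTime", f"{ti:.1f}", 1))
            if not missing_bp:
                kept_plan.append(("BodyPartExamined", "BRAIN", 1))
            dropped_plan = [
                ("SeriesDescription", params["description"]),  # LO free text
                ("PatientName", f"Synthetic^Subject{p:04d}"),  # PN
                ("PatientID", patient_id),                      # LO
                ("ProtocolName", params["description"]),        # LO
                ("StudyInstanceUID", study_uid),                # UI
                ("SeriesInstanceUID", series_uid),              # UI
            ]
            if empty_scan_options:
                dropped_plan.append(("ScanOptions", ""))        # CS but empty

            n_kept = sum(k for _, _, k in kept_plan)
            # UI/SOP identity elements written per instance are also dropped
            # (UI is not a whitelisted VR): SOPClassUID, SOPInstanceUID.

            series_dir = out / patient_id / "study001" / f"series{s:03d}"
            series_dir.mkdir(parents=True, exist_ok=True)
            for i in range(1, spec.instances_per_series + 1):
                sop_uid = f"{UID_ROOT}.3.{spec.seed}.{p}.{s}.{i}"
                _write_instance(
                    series_dir / f"instance{i:03d}.dcm",
                    kept_plan, dropped_plan, sop_uid=sop_uid, instance_number=i,
                )
            manifest.append({
                "patient_id": patient_id,
                "study_uid": study_uid,
                "series_uid": series_uid,
                "protocol": protocol,
                "series_date": study_date,
                "body_part": "" if missing_bp else "BRAIN",
                "has_ti": int(ti is not None),
                "n_instances": spec.instances_per_series,
                "n_kept_expected": n_kept,
            })

    with (out / "manifest.csv").open("w", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(fh, fieldnames=MANIFEST_COLUMNS)
        w.writeheader()
        w.writerows(manifest)
    return manifest


def _write_instance(path: Path, kept_plan, dropped_plan, sop_uid: str,
                    instance_number: int) -> None:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = "1.2.840.10008.5.1.4.1.1.4"  # MR Image Storage
    meta.MediaStorageSOPInstanceUID = sop_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    meta.ImplementationClassUID = f"{UID_ROOT}.0.1"
    meta.ImplementationVersionName = "DICOMOP_01"

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\x00" * 128)
    for keyword, value, _ in kept_plan:
        if keyword == "InstanceNumber":
            value = str(instance_number)
        setattr(ds, keyword, value)
    for keyword, value in dropped_plan:
        setattr(ds, keyword, value)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = sop_uid
    # a private element and a sequence: both must vanish during harvest
    ds.add_new(0x00090010, "LO", "SYNTHETIC PRIVATE BLOCK")
    ref = Dataset()
    ref.ReferencedSOPClassUID = meta.MediaStorageSOPClassUID
    ref.ReferencedSOPInstanceUID = sop_uid
    ds.ReferencedImageSequence = [ref]
    # minimal placeholder pixel payload (never loaded by the harvester)
    ds.add_new(0x7FE00010, "OW", b"\x00\x01" * 8)
    ds.save_as(path, enforce_file_format=True)


# ---------------------------------------------------------------------------
# Simulated EHR fixture
# ---------------------------------------------------------------------------

#: Default cognitively-normal : MCI : AD mix of the emulated study arm.
DEFAULT_DIAGNOSIS_MIX = (("CN", 133), ("MCI", 151), ("AD", 87))

#: OMOP standard concept ids for the two diagnosed groups.
CONDITION_CONCEPTS = {"MCI": 4297400, "AD": 378419}


def _allocate_mix(n: int, mix: Sequence[tuple[str, int]]) -> list[str]:
    total = sum(w for _, w in mix)
    quotas = [(g, n * w / total) for g, w in mix]
    counts = {g: int(q) for g, q in quotas}
    leftover = n - sum(counts.values())
    for g, _ in sorted(quotas, key=lambda x: x[1] - int(x[1]), reverse=True)[:leftover]:
        counts[g] += 1
    return [g for g, c in counts.items() for _ in range(c)]


def make_ehr_fixture(
    n_persons: int,
    seed: int,
    out_dir: str | Path,
    mix: Sequence[tuple[str, int]] = DEFAULT_DIAGNOSIS_MIX,
) -> dict[str, int]:
    """Write person / condition_occurrence / measurement CSVs plus the
    patient-id map; returns per-group person counts."""
    if n_persons < 1:
        raise ValueError("n_persons must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    groups = _allocate_mix(n_persons, mix)
    groups = [groups[i] for i in rng.permutation(n_persons)]

    with (out / "person.csv").open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["person_id", "gender_concept_id", "year_of_birth",
                    "race_concept_id", "ethnicity_concept_id"])
        for pid in range(1, n_persons + 1):
            w.writerow([pid, int(rng.choice([8507, 8532])),
                        int(rng.integers(1930, 1956)), 0, 0])

    with (out / "condition_occurrence.csv").open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["condition_occurrence_id", "person_id", "condition_concept_id",
                    "condition_start_date"])
        cid = 0
        for pid, group in enumerate(groups, start=1):
            if group in CONDITION_CONCEPTS:
                cid += 1
                w.writerow([cid, pid, CONDITION_CONCEPTS[group],
                            f"2017-{int(rng.integers(1, 13)):02d}-15"])

    with (out / "measurement.csv").open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["measurement_id", "person_id", "measurement_concept_id",
                    "measurement_date", "value_as_number"])
        mid = 0
        for pid in range(1, n_persons + 1):
            for item in range(3):  # questionnaire-style inventory items
                mid += 1
                w.writerow([mid, pid, 2128900001 + item, "2017-06-15",
                            int(rng.integers(0, 13))])

    with (out / "patient_map.csv").open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["source_patient_id", "person_id"])
        for pid in range(1, n_persons + 1):
            w.writerow([f"SYN-{pid:04d}", pid])

    with (out / "groups.csv").open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["person_id", "group"])
        for pid, group in enumerate(groups, start=1):
            w.writerow([pid, group])

    return {g: groups.count(g) for g, _ in mix}


def load_person_map(path: str | Path) -> dict[str, int]:
    """Read a (source_patient_id, person_id) CSV into a mapping."""
    out: dict[str, int] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out[row["source_patient_id"].strip()] = int(row["person_id"])
    return out
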