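"""Imaging-phenotype cohort evaluation with series-scoped conjunction."""

import pytest

from dicomop import (
    CohortCriterion,
    CohortDefinition,
    CohortDefinitionError,
    build_rows,
    emit_cdm,
    evaluate,
    evaluate_sql,
    export_result,
    harvest_dataset,
)
from dicomop.cohort_query import T1_VOLUMETRIC_TEMPLATE
from dicomop.fixtures import DicomFixtureSpec, make_dicom_fixture

TI_PRESENT = CohortCriterion(attribute="00180082", op="present")
TR_RANGE = CohortCriterion(attribute="00180080", op="in_range", low=2100, high=2500)
TE_RANGE = CohortCriterion(attribute="00180081", op="in_range", low=2, high=4)


class TestDefinitionValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(attribute="00180080", op="eq"),                       # eq without value
            dict(attribute="00180080", op="in_range", low=5, high=1),  # inverted range
            dict(attribute="00180080", op="teleport"),                 # unknown op
            dict(attribute="nope", op="present"),                      # malformed tag
        ],
    )
    def test_malformed_criteria_rejected(self, kwargs):
        with pytest.raises(CohortDefinitionError):
            CohortCriterion(**kwargs)

    def test_definition_needs_criteria_or_modality(self):
        with pytest.raises(CohortDefinitionError):
            CohortDefinition()

    def test_unknown_attribute_with_vocab_is_definition_error(self, cdm_rows, vocab_index):
        defn = CohortDefinition(criteria=(CohortCriterion("ABCD0001", "present"),))
        with pytest.raises(CohortDefinitionError, match="unknown attribute"):
            evaluate(defn, cdm_rows, vocab_index)

    def test_known_but_absent_attribute_gives_empty_result(self, cdm_rows, vocab_index):
        # Lossy Image Compression Method exists in the vocabulary but no
        # fixture series carries it
        defn = CohortDefinition(criteria=(CohortCriterion("00282114", "present"),))
        result = evaluate(defn, cdm_rows, vocab_index)
        assert result.person_ids == set() and result.series_uids == set()


@pytest.fixture(scope="module")
def mprage_cohort_setup(tmp_path_factory, vocab_index):
    """15 patients, one series each: 10 MPRAGE (TI-bearing), 5 T2."""
    root = tmp_path_factory.mktemp("cohort_tree")
    spec = DicomFixtureSpec(n_patients=15, series_per_patient=1,
                            instances_per_series=2,
                            protocol_mix=(("MPRAGE", 10 / 15), ("T2", 5 / 15)),
                            missing_bodypart_rate=0.0, empty_value_rate=0.0, seed=11)
    manifest = make_dicom_fixture(spec, root)
    records, elements = harvest_dataset(root)
    person_map = {f"SYN-{i:04d}": i for i in range(1, 16)}
    rows = build_rows(records, elements, vocab_index, person_map)
    cdm = tmp_path_factory.mktemp("cohort_cdm")
    emit_cdm(rows, cdm)
    return manifest, rows, cdm, person_map


class TestEvaluation:
    def test_mprage_definition_finds_exactly_the_ti_bearing_patients(
        self, mprage_cohort_setup
    ):
        manifest, rows, _, person_map = mprage_cohort_setup
        expected = {person_map[m["patient_id"]] for m in manifest
                    if m["protocol"] == "MPRAGE"}
        assert len(expected) == 10
        defn = CohortDefinition(criteria=(TI_PRESENT, TR_RANGE, TE_RANGE), modality="MR")
        result = evaluate(defn, rows)
        assert result.person_ids == expected
        assert result.series_uids == {m["series_uid"] for m in manifest
                                      if m["protocol"] == "MPRAGE"}

    def test_vacuous_present_criterion_matches_all_imaged_persons(self, mprage_cohort_setup):
        _, rows, _, person_map = mprage_cohort_setup
        defn = CohortDefinition(criteria=(CohortCriterion("00180080", "present"),))
        assert evaluate(defn, rows).person_ids == set(person_map.values())

    def test_eq_criterion_on_code_string(self, mprage_cohort_setup):
        _, rows, _, _ = mprage_cohort_setup
        defn = CohortDefinition(
            criteria=(CohortCriterion("00185100", "eq", value="HFS"),))
        assert len(evaluate(defn, rows).person_ids) == 15

    def test_adding_criteria_never_enlarges_the_result(self, mprage_cohort_setup):
        _, rows, _, _ = mprage_cohort_setup
        chain = [TI_PRESENT, TR_RANGE, TE_RANGE,
                 CohortCriterion("00180087", "in_range", low=10, high=20)]
        previous = None
        for k in range(1, len(chain) + 1):
            result = evaluate(CohortDefinition(criteria=tuple(chain[:k])), rows)
            if previous is not None:
                assert result.series_uids <= previous.series_uids
                assert result.person_ids <= previous.person_ids
            previous = result

    def test_criteria_are_series_scoped_not_study_scoped(self, vocab_index, tmp_path_factory):
        # one patient, two series in one study: TR-only and TI-only —
        # a definition requiring both must not match across series
        root = tmp_path_factory.mktemp("scoped")
        spec = DicomFixtureSpec(n_patients=1, series_per_patient=2,
                                instances_per_series=1,
                                protocol_mix=(("MPRAGE", 0.5), ("T2", 0.5)),
                                missing_bodypart_rate=0.0, empty_value_rate=0.0, seed=5)
        manifest = make_dicom_fixture(spec, root)
        records, elements = harvest_dataset(root)
        assert {m["protocol"] for m in manifest} == {"MPRAGE", "T2"}
        rows = build_rows(records, elements, vocab_index, {"SYN-0001": 1})
        # TE of the T2 protocol is ~400 ms; MPRAGE TE is 2-4 ms.  Require
        # a TI (MPRAGE-only) together with a T2-range TE: no single series
        # has both, even though the patient's study has each separately.
        defn = CohortDefinition(criteria=(
            TI_PRESENT, CohortCriterion("00180081", "in_range", low=300, high=500)))
        assert evaluate(defn, rows).person_ids == set()


class TestSqlEquivalence:
    @pytest.mark.parametrize(
        "defn",
        [
            CohortDefinition.from_dict(T1_VOLUMETRIC_TEMPLATE),
            CohortDefinition(criteria=(TI_PRESENT,)),
            CohortDefinition(modality="MR"),
            CohortDefinition(criteria=(CohortCriterion("00185100", "eq", value="HFS"),
                                       TR_RANGE)),
        ],
        ids=["t1-template", "ti-present", "modality-only", "eq-and-range"],
    )
    def test_sql_store_agrees_with_in_memory_evaluation(
        self, mprage_cohort_setup, defn
    ):
        _, rows, cdm, _ = mprage_cohort_setup
        mem = evaluate(defn, rows)
        sql = evaluate_sql(defn, cdm / "cdm.sqlite")
        assert mem.series_uids == sql.series_uids
        assert mem.person_ids == sql.person_ids
        assert mem.series_by_person == sql.series_by_person


class TestExport:
    def test_export_writes_uid_lines_and_person_csv(self, mprage_cohort_setup, tmp_path):
        _, rows, _, _ = mprage_cohort_setup
        defn = CohortDefinition(criteria=(TI_PRESENT,))
        result = evaluate(defn, rows)
        export_result(result, tmp_path, defn)
        uids = (tmp_path / "series_uids.txt").read_text().splitlines()
        assert sorted(uids) == sorted(result.series_uids)
        persons = (tmp_path / "persons.csv").read_text().splitlines()
        assert len(persons) - 1 == len(result.person_ids)
        assert "SELECT" in (tmp_path / "cohort.sql").read_text()

    def test_empty_result_exports_empty_files(self, mprage_cohort_setup, tmp_path):
        _, rows, _, _ = mprage_cohort_setup
        defn = CohortDefinition(criteria=(CohortCriterion("00282114", "present"),))
        export_result(evaluate(defn, rows), tmp_path)
        assert (tmp_path / "series_uids.txt").read_text() == ""
        assert len((tmp_path / "persons.csv").read_text().splitlines()) == 1
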