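"""Loading and validating normalized DICOM Standard content."""

import csv

import pytest

from dicomop import (
    ReferentialIntegrityError,
    SchemaViolationError,
    load_attribute_dictionary,
    load_context_groups,
    load_part3_terms,
    load_standard_bundle,
    write_standard_bundle,
)
from dicomop.standard_model import (
    BODY_PART_TAG,
    LOSSY_COMPRESSION_METHOD_TAG,
    MODALITY_TAG,
    PATIENT_POSITION_TAG,
)


def _write_csv(path, header, rows):
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        w.writerows(rows)
    return path


ATTR_HEADER = ["tag", "name", "keyword", "vr", "vm", "retired"]


class TestAttributeDictionary:
    def test_modality_row_parses_to_canonical_form(self, tmp_path):
        p = _write_csv(tmp_path / "attributes.csv", ATTR_HEADER,
                       [["00080060", "Modality", "Modality", "CS", "1", "false"]])
        (a,) = load_attribute_dictionary(p)
        assert (a.tag, a.name, a.vr) == ("00080060", "Modality", "CS")
        assert a.display_tag() == "(0008,0060)"

    def test_header_only_file_yields_empty_list(self, tmp_path):
        p = _write_csv(tmp_path / "attributes.csv", ATTR_HEADER, [])
        assert load_attribute_dictionary(p) == []

    @pytest.mark.parametrize(
        "row, fragment",
        [
            (["0008006", "Modality", "Modality", "CS", "1", ""], "malformed tag"),
            (["00080060", "Modality", "Modality", "XX", "1", ""], "unknown VR"),
        ],
    )
    def test_malformed_rows_name_the_row_number(self, tmp_path, row, fragment):
        p = _write_csv(tmp_path / "attributes.csv", ATTR_HEADER,
                       [["00080020", "Study Date", "StudyDate", "DA", "1", ""], row])
        with pytest.raises(SchemaViolationError, match=f"row 2.*{fragment}|{fragment}"):
            load_attribute_dictionary(p)

    def test_duplicate_tag_rejected(self, tmp_path):
        row = ["00080060", "Modality", "Modality", "CS", "1", ""]
        p = _write_csv(tmp_path / "attributes.csv", ATTR_HEADER, [row, row])
        with pytest.raises(SchemaViolationError, match="duplicate tag"):
            load_attribute_dictionary(p)

    def test_nameless_entries_are_retained_at_load(self, table2_bundle):
        assert len(table2_bundle.attributes) == 5190
        assert sum(1 for a in table2_bundle.attributes if not a.name) == 7


class TestContextGroups:
    def test_same_code_in_two_cids_stays_two_occurrences(self, tmp_path):
        p = _write_csv(tmp_path / "cid_members.csv", ["cid", "scheme", "code", "meaning"],
                       [[29, "DCM", "MR", "Magnetic Resonance"],
                        [30, "DCM", "MR", "Magnetic Resonance"]])
        occ, _ = load_context_groups(p)
        assert len(occ) == 2
        assert occ[0].key == occ[1].key == ("DCM", "MR")

    def test_missing_cid_is_schema_violation(self, tmp_path):
        p = _write_csv(tmp_path / "cid_members.csv", ["cid", "scheme", "code", "meaning"],
                       [["", "DCM", "MR", "Magnetic Resonance"]])
        with pytest.raises(SchemaViolationError, match="row 1.*missing cid"):
            load_context_groups(p)

    def test_external_scheme_loaded_but_flagged(self, tmp_path):
        p = _write_csv(tmp_path / "cid_members.csv", ["cid", "scheme", "code", "meaning"],
                       [[4030, "SCT", "12738006", "Brain structure"]])
        (occ,), _ = load_context_groups(p)
        assert not occ.is_dcm

    def test_table2_occurrence_and_bodypart_counts(self, table2_bundle):
        dcm = [o for o in table2_bundle.coded_values if o.is_dcm]
        assert len(dcm) == 5223
        assert len(table2_bundle.bodypart_snomed_map) == 398


class TestPart3Terms:
    def test_table2_per_attribute_term_counts(self, table2_bundle):
        by_attr = {}
        for t in table2_bundle.defined_terms:
            by_attr[t.attribute_tag] = by_attr.get(t.attribute_tag, 0) + 1
        assert by_attr[MODALITY_TAG] == 79
        assert by_attr[BODY_PART_TAG] == 318
        assert by_attr[PATIENT_POSITION_TAG] == 16
        assert by_attr[LOSSY_COMPRESSION_METHOD_TAG] == 8

    def test_terms_grouped_into_one_constraint_per_attribute(self, tmp_path):
        p = _write_csv(tmp_path / "part3_terms.csv",
                       ["attribute_tag", "value_string", "meaning", "term_kind", "snomed_code"],
                       [["00080060", "MR", "MR", "Defined", ""],
                        ["00080060", "CT", "CT", "Defined", ""]])
        terms, constraints = load_part3_terms(p)
        assert len(terms) == 2
        (con,) = constraints
        assert con.constraint_kind == "TermList" and len(con.term_refs) == 2

    def test_duplicate_rows_collapse_to_distinct_terms(self, tmp_path):
        # oracle: distinct (attribute_tag, value_string) pairs over the raw rows
        rows = [["00080060", v, v, "Defined", ""] for v in ["MR", "CT", "MR", "MR", "CT"]]
        distinct = len({(r[0], r[1]) for r in rows})
        p = _write_csv(tmp_path / "part3_terms.csv",
                       ["attribute_tag", "value_string", "meaning", "term_kind", "snomed_code"],
                       rows)
        terms, _ = load_part3_terms(p)
        assert len(terms) == distinct == 2

    def test_dangling_attribute_tag_is_referential_error(self, tmp_path):
        p = _write_csv(tmp_path / "part3_terms.csv",
                       ["attribute_tag", "value_string", "meaning", "term_kind", "snomed_code"],
                       [["DEADBEEF", "MR", "MR", "Defined", ""]])
        with pytest.raises(ReferentialIntegrityError, match="unknown attribute"):
            load_part3_terms(p, attribute_tags={"00080060"})


class TestBundleProperties:
    def test_round_trip_preserves_structure(self, table2_bundle, tmp_path):
        write_standard_bundle(table2_bundle, tmp_path)
        reloaded = load_standard_bundle(tmp_path)
        assert reloaded.attributes == table2_bundle.attributes
        assert sorted((o.key, tuple(sorted(o.cids))) for o in reloaded.coded_values) == \
            sorted((o.key, tuple(sorted(o.cids))) for o in table2_bundle.coded_values)
        assert set(reloaded.defined_terms) == set(table2_bundle.defined_terms)
        assert sorted(reloaded.bodypart_snomed_map) == sorted(table2_bundle.bodypart_snomed_map)
        assert {(c.attribute_tag, c.constraint_kind, c.cid) for c in reloaded.constraints} == \
            {(c.attribute_tag, c.constraint_kind, c.cid) for c in table2_bundle.constraints}

    def test_referential_integrity_full_scan(self, table2_bundle):
        tags = table2_bundle.attribute_tags()
        assert all(t.attribute_tag in tags for t in table2_bundle.defined_terms)
        assert all(c.attribute_tag in tags for c in table2_bundle.constraints)

    def test_row_permutation_leaves_concept_key_set_unchanged(self, tmp_path, table2_dir):
        import random

        src = (table2_dir / "cid_members.csv").read_text(encoding="utf-8").splitlines()
        header, rows = src[0], src[1:]
        random.Random(7).shuffle(rows)
        (tmp_path / "cid_members.csv").write_text(
            "\n".join([header] + rows) + "\n", encoding="utf-8"
        )
        occ_orig, _ = load_context_groups(table2_dir / "cid_members.csv")
        occ_perm, _ = load_context_groups(tmp_path / "cid_members.csv")
        key = lambda occs: sorted((o.key, tuple(sorted(o.cids))) for o in occs)
        assert key(occ_orig) == key(occ_perm)
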