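"""Vocabulary construction: dedup, id assignment, relationships, summary."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dicomop import (
    AttributeDef,
    AttributeValueConstraint,
    BuilderConfig,
    CodedValue,
    ConceptIndex,
    DefinedTerm,
    ExternalConceptResolver,
    StandardBundle,
    assign_concept_ids,
    build_attribute_concepts,
    build_relationships,
    build_value_concepts,
    build_vocabulary,
    dedup_coded_values,
    emit_vocabulary,
    load_vocabulary,
    summarize,
)
from dicomop.vocab_builder import MAPS_TO, MAPS_TO_VALUE, ConceptIdCollisionError


def _attr(tag, name="Some Attribute", vr="CS"):
    return AttributeDef(tag=tag, name=name, keyword=name.replace(" ", ""), vr=vr)


def _occ(code, cid, scheme="DCM"):
    return CodedValue(code_value=code, coding_scheme=scheme,
                      code_meaning=f"meaning {code}", cids=frozenset({cid}))


class TestAttributeConcepts:
    @pytest.mark.parametrize(
        "names, expected",
        [(["A", "B", ""], 2), (["", "", ""], 0), (["A", "B"], 2)],
    )
    def test_nameless_entries_excluded(self, names, expected):
        attrs = [_attr(f"0008{i:04X}", name=n) for i, n in enumerate(names)]
        assert len(build_attribute_concepts(attrs, BuilderConfig())) == expected

    def test_table2_yields_5183_attribute_concepts(self, table2_build):
        attrs = [c for c in table2_build.concepts if c.concept_class_id == "Attribute"]
        assert len(attrs) == 5183


occurrence_lists = st.lists(
    st.tuples(
        st.sampled_from(["DCM", "SCT"]),
        st.integers(0, 30).map(str),   # code value
        st.integers(1, 6),             # cid
    ),
    max_size=60,
)


class TestDedup:
    def test_same_code_across_cids_unions_memberships(self):
        result = dedup_coded_values([_occ("MR", 29), _occ("MR", 30)])
        (cv,) = result.dcm_values
        assert cv.cids == {29, 30}

    def test_table2_distinct_codes_and_surviving_modality_terms(self, table2_build):
        dedup = table2_build.dedup
        assert len(dedup.dcm_values) == 3281
        assert dedup.n_repeated == 1063
        modality_survivors = [t for t in dedup.surviving_terms
                              if t.attribute_tag == "00080060"]
        assert len(modality_survivors) == 5

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(occurrence_lists)
    def test_distinct_count_matches_brute_force_oracle(self, raw):
        occs = [_occ(code, cid, scheme) for scheme, code, cid in raw]
        result = dedup_coded_values(occs)
        # independent oracle: distinct-set arithmetic straight off the rows
        oracle_dcm = {(s, c) for s, c, _ in raw if s == "DCM"}
        oracle_cids = {}
        for scheme, code, cid in raw:
            oracle_cids.setdefault((scheme, code), set()).add(cid)
        assert {cv.key for cv in result.dcm_values} == oracle_dcm
        for cv in result.dcm_values + result.foreign_values:
            assert cv.cids == oracle_cids[cv.key]

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(occurrence_lists, st.randoms(use_true_random=False))
    def test_permutation_invariant_and_idempotent(self, raw, rnd):
        occs = [_occ(code, cid, scheme) for scheme, code, cid in raw]
        shuffled = list(occs)
        rnd.shuffle(shuffled)
        key = lambda r: [(cv.key, cv.cids) for cv in r.dcm_values]
        once = dedup_coded_values(occs)
        assert key(dedup_coded_values(shuffled)) == key(once)
        again = dedup_coded_values(once.dcm_values + once.foreign_values)
        assert key(again) == key(once)


class TestIdAssignment:
    def test_ids_consecutive_from_base(self):
        cfg = BuilderConfig()
        payloads = build_attribute_concepts(
            [_attr(f"0010{i:04X}") for i in range(5)], cfg)
        concepts = assign_concept_ids(payloads, cfg)
        ids = [c.concept_id for c in concepts]
        assert ids[0] == 2_128_000_000
        assert ids == list(range(cfg.id_base, cfg.id_base + 5))
        assert max(ids) == cfg.id_base + len(ids) - 1

    def test_two_runs_reproduce_identical_ids(self, table2_bundle):
        b1 = build_vocabulary(table2_bundle)
        b2 = build_vocabulary(table2_bundle)
        assert [(c.concept_id, c.concept_code) for c in b1.concepts] == \
            [(c.concept_id, c.concept_code) for c in b2.concepts]

    def test_collision_with_external_ids_is_fatal(self):
        cfg = BuilderConfig()
        resolver = ExternalConceptResolver({("SCT", "x"): cfg.id_base + 1})
        payloads = build_attribute_concepts(
            [_attr(f"0010{i:04X}") for i in range(3)], cfg)
        with pytest.raises(ConceptIdCollisionError):
            assign_concept_ids(payloads, cfg, resolver)

    def test_id_base_must_sit_in_custom_range(self):
        with pytest.raises(ValueError):
            BuilderConfig(id_base=1_000_000)


def _tiny_bundle():
    attrs = [_attr("00080060", "Modality"), _attr("00081234", "Some Coded Thing")]
    occs = [_occ("A1", 7), _occ("A2", 7), _occ("A3", 7)]
    con = AttributeValueConstraint(attribute_tag="00081234", constraint_kind="CID", cid=7)
    return StandardBundle(attributes=attrs, coded_values=occs, defined_terms=[],
                          constraints=[con], bodypart_snomed_map=[])


class TestRelationships:
    def test_cid_of_three_members_yields_three_maps_to_value(self):
        build = build_vocabulary(_tiny_bundle())
        mtv = [r for r in build.relationships if r.relationship_id == MAPS_TO_VALUE]
        assert len(mtv) == 3
        assert build.n_maps_to_value_cid == 3

    def test_empty_constraints_yield_no_relationships(self):
        bundle = _tiny_bundle()
        bundle.constraints = []
        assert build_vocabulary(bundle).relationships == []

    def test_table2_relationship_split(self, table2_build):
        assert table2_build.n_maps_to_value_cid == 7101
        assert table2_build.n_maps_to_value_term == 739
        n_mt = sum(1 for r in table2_build.relationships if r.relationship_id == MAPS_TO)
        assert n_mt == 307

    def test_maps_to_value_total_matches_constraint_recount(self, table2_bundle, table2_build):
        # brute-force conservation oracle: per-constraint member counts
        members = {}
        for occ in table2_bundle.coded_values:
            if occ.is_dcm:
                for cid in occ.cids:
                    members.setdefault(cid, set()).add(occ.code_value)
        expected = 0
        for con in table2_bundle.constraints:
            if con.constraint_kind == "CID":
                expected += len(members.get(con.cid, ()))
            else:
                expected += len({t.value_string for t in con.term_refs})
        assert table2_build.summary.n_maps_to_value == expected

    def test_relationship_endpoints_all_resolve(self, table2_build):
        ids = {c.concept_id for c in table2_build.concepts}
        resolver_targets = {r.concept_id_2 for r in table2_build.relationships
                            if r.relationship_id == MAPS_TO}
        for r in table2_build.relationships:
            assert r.concept_id_1 in ids
            assert r.concept_id_2 in ids or r.concept_id_2 in resolver_targets


class TestSummary:
    def test_empty_vocabulary_summarizes_to_zeros(self):
        s = summarize([], [])
        assert s.n_total_concepts == s.n_total_values == s.n_total_relationships == 0

    def test_table2_totals(self, table2_build):
        s = table2_build.summary
        assert s.n_total_values == 3628
        assert s.n_cid_values == 3281
        assert (s.n_bodypart_values, s.n_modality_terms,
                s.n_patientposition_terms, s.n_compression_terms) == (318, 5, 16, 8)
        assert s.n_total_relationships == 8147
        assert s.n_total_concepts == 16958

    def test_summary_equals_recount_of_emitted_csv(self, table2_build, vocab_dir):
        concepts, relationships = load_vocabulary(vocab_dir)
        s = summarize(concepts, relationships)
        assert s == table2_build.summary


class TestEmission:
    def test_single_concept_no_relationships(self, tmp_path):
        cfg = BuilderConfig()
        concepts = assign_concept_ids(build_attribute_concepts([_attr("00080060")], cfg), cfg)
        counts = emit_vocabulary(concepts, [], tmp_path)
        assert counts == {"CONCEPT.csv": 1, "CONCEPT_RELATIONSHIP.csv": 0}
        assert len((tmp_path / "CONCEPT_RELATIONSHIP.csv").read_text().splitlines()) == 1

    def test_table2_concept_row_count(self, vocab_dir):
        n_rows = len((vocab_dir / "CONCEPT.csv").read_text(encoding="utf-8").splitlines()) - 1
        assert n_rows == 5183 + 3628

    def test_round_trip_reproduces_tables(self, table2_build, vocab_dir):
        concepts, relationships = load_vocabulary(vocab_dir)
        assert concepts == table2_build.concepts
        assert relationships == table2_build.relationships
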