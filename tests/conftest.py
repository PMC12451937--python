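import pytest

from dicomop import (
    BuilderConfig,
    ExternalConceptResolver,
    VocabIndex,
    build_rows,
    build_vocabulary,
    emit_cdm,
    emit_vocabulary,
    harvest_dataset,
    load_person_map,
    load_standard_bundle,
)
from dicomop.fixtures import (
    DicomFixtureSpec,
    StandardFixtureProfile,
    make_dicom_fixture,
    make_ehr_fixture,
    make_standard_fixture,
)


@pytest.fixture(scope="session")
def table2_dir(tmp_path_factory):
    """Interchange directory for the published-counts standard profile."""
    out = tmp_path_factory.mktemp("std_table2")
    make_standard_fixture(StandardFixtureProfile.table2(seed=1), out)
    return out


@pytest.fixture(scope="session")
def table2_bundle(table2_dir):
    return load_standard_bundle(table2_dir)


@pytest.fixture(scope="session")
def table2_build(table2_dir, table2_bundle):
    resolver = ExternalConceptResolver.from_csv(table2_dir / "snomed_resolver.csv")
    return build_vocabulary(table2_bundle, BuilderConfig(), resolver)


@pytest.fixture(scope="session")
def vocab_dir(tmp_path_factory, table2_build):
    out = tmp_path_factory.mktemp("vocab")
    emit_vocabulary(table2_build.concepts, table2_build.relationships, out)
    return out


@pytest.fixture(scope="session")
def vocab_index(vocab_dir):
    return VocabIndex.load(vocab_dir)


@pytest.fixture(scope="session")
def dicom_tree(tmp_path_factory):
    """Synthetic MR tree at the default (scaled study) size: 5 patients x
    8 series x 3 instances, with the ground-truth manifest."""
    out = tmp_path_factory.mktemp("dicom")
    manifest = make_dicom_fixture(DicomFixtureSpec(seed=1), out)
    return out, manifest


@pytest.fixture(scope="session")
def harvested(dicom_tree):
    root, _ = dicom_tree
    return harvest_dataset(root)


@pytest.fixture(scope="session")
def person_map(tmp_path_factory):
    out = tmp_path_factory.mktemp("ehr")
    make_ehr_fixture(10, seed=1, out_dir=out)
    return load_person_map(out / "patient_map.csv")


@pytest.fixture(scope="session")
def cdm_rows(harvested, vocab_index, person_map):
    records, elements = harvested
    return build_rows(records, elements, vocab_index, person_map)


@pytest.fixture(scope="session")
def cdm_dir(tmp_path_factory, cdm_rows):
    out = tmp_path_factory.mktemp("cdm")
    emit_cdm(cdm_rows, out)
    return out
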