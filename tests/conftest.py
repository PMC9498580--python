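import pytest

from ciliavar import classify_variant, datasets


@pytest.fixture(scope="session")
def study_cohort():
    return datasets.load_study_cohort()


@pytest.fixture(scope="session")
def study_tables():
    return {name: datasets.load_table(name) for name in datasets.TABLE_FILES}


@pytest.fixture(scope="session")
def study_records(study_tables):
    out = []
    for records in study_tables.values():
        out.extend(records)
    return out


@pytest.fixture(scope="session")
def unique_records(study_records):
    return datasets.unique_patient_variants(study_records)


@pytest.fixture(scope="session")
def unique_calls(unique_records):
    return [classify_variant(r) for r in unique_records]


@pytest.fixture(scope="session")
def study_graph():
    return datasets.load_interaction_graph()
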