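import pytest
from hypothesis import settings

from abca4tools import (
    fixture_path,
    load_fixture_cohort,
    read_group_labels,
    run_pipeline_from_records,
)

settings.register_profile("ci", derandomize=True, max_examples=200)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_cohort():
    """The packaged 18-patient cohort: (patients, variants, splice scores)."""
    return load_fixture_cohort()


@pytest.fixture(scope="session")
def fixture_result(fixture_cohort):
    patients, variants, splice = fixture_cohort
    return run_pipeline_from_records(patients, variants, splice)


@pytest.fixture(scope="session")
def printed_groups():
    return read_group_labels(fixture_path("table1_patients.tsv"))
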