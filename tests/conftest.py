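from __future__ import annotations

import pytest

from ehrflow import (
    CohortConfig,
    build_timelines,
    fixture_ontology,
    fixture_osteoporosis,
    fixture_table1,
    generate_cohort,
)


@pytest.fixture()
def table1():
    return fixture_table1()


@pytest.fixture(scope="session")
def store():
    return fixture_ontology()


@pytest.fixture(scope="session")
def osteo():
    return fixture_osteoporosis()


@pytest.fixture(scope="session")
def cohort_events():
    return generate_cohort(CohortConfig(n_patients=100, seed=1))


@pytest.fixture(scope="session")
def cohort_timelines(cohort_events):
    return build_timelines(cohort_events)
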