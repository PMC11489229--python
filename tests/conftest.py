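import hypothesis
import pytest

from lupuscrit import (
    Group,
    PatientRecord,
    default_spec,
    generate_cohort,
    load_all_bundled,
    load_bundled,
)

hypothesis.settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=100
)
hypothesis.settings.load_profile("default")


def make_record(rid="p1", group="case", **features) -> PatientRecord:
    """Record builder: features given as keyword 0/1 flags."""
    return PatientRecord(id=rid, group=Group(group), features=features)


@pytest.fixture(scope="session")
def slerpi():
    return load_bundled("slerpi")


@pytest.fixture(scope="session")
def all_criteria():
    return load_all_bundled()


@pytest.fixture(scope="session")
def default_cohort():
    """One default-spec synthetic cohort shared across tests (seed 123)."""
    return generate_cohort(default_spec(123))
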