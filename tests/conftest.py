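import pytest

from exoncompare import build_fixture_cohort, compare_cohort


@pytest.fixture(scope="session")
def fixture_cohort():
    return build_fixture_cohort(seed=1)


@pytest.fixture(scope="session")
def model(fixture_cohort):
    return fixture_cohort.model


@pytest.fixture(scope="session")
def tumor_summary(fixture_cohort):
    return compare_cohort(fixture_cohort.tumor, fixture_cohort.model)


@pytest.fixture(scope="session")
def healthy_summary(fixture_cohort):
    return compare_cohort(fixture_cohort.healthy, fixture_cohort.model)
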