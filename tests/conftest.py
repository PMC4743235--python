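import pytest

from peritree import (
    BloodProperties,
    FixtureConfig,
    RunConfig,
    TreeParams,
    VesselGroupTable,
    make_outlet_set,
    make_surrogate,
)


@pytest.fixture(scope="session")
def table():
    return VesselGroupTable.default()


@pytest.fixture(scope="session")
def props():
    return BloodProperties()


@pytest.fixture(scope="session")
def params():
    return TreeParams()


@pytest.fixture
def run_config():
    return RunConfig()


@pytest.fixture
def small_surrogate():
    """A seeded 7-branch carotid surrogate used across coupling tests."""
    fc = FixtureConfig(seed=11, n_branches=7)
    return make_surrogate(make_outlet_set(fc), fc)
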