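import pytest
from hypothesis import HealthCheck, settings

import mbstrip as mb

settings.register_profile(
    "mbstrip",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("mbstrip")


@pytest.fixture(scope="session")
def fixture_panels() -> mb.FixturePanel:
    return mb.load_paper_fixture()


@pytest.fixture(scope="session")
def reference_panel(fixture_panels):
    return fixture_panels.reference


@pytest.fixture(scope="session")
def validation_panel(fixture_panels):
    return fixture_panels.validation


@pytest.fixture(scope="session")
def reference_msa(fixture_panels):
    return mb.build_msa(fixture_panels.reference, fixture_panels.reference_id)


@pytest.fixture(scope="session")
def validation_msa(validation_panel):
    return mb.build_msa(validation_panel)


@pytest.fixture(scope="session")
def default_params() -> mb.BindingModelParams:
    return mb.BindingModelParams()


@pytest.fixture(scope="session")
def catalog():
    return mb.load_region_catalog()
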