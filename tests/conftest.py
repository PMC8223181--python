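import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from cdrs import default_framework, full_sheet


@pytest.fixture(scope="session")
def spec():
    return default_framework()


@pytest.fixture
def perfect_sheet(spec):
    """Every cell at its domain maximum (death comorbidity 2, privacy +1)."""
    return full_sheet(spec, "perfect", lambda i: spec.domain(i).max)


@pytest.fixture
def nodata_sheet(spec):
    """All non-privacy cells zero; privacy left unmarked (derived NA)."""
    return full_sheet(
        spec, "silent", lambda i: None if i.category == "privacy" else 0
    )
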