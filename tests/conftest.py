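import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scheme():
    from famcurate.similarity import ScoringScheme

    return ScoringScheme()


@pytest.fixture(scope="session")
def wox_library():
    from famcurate.motifs import default_library

    return default_library()
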