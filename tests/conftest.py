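import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def burkina():
    from listlite.fixtures import burkina_fixture

    return burkina_fixture()


@pytest.fixture(scope="session")
def burkina_result(burkina):
    from listlite.pipeline import run_study

    return run_study(burkina)
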