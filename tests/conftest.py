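import pytest
from hypothesis import HealthCheck, settings

from brcakit.acmg import EngineConfig
from brcakit.simulate import paper_fixture
from brcakit.variant_model import load_transcript_models

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def models():
    return load_transcript_models()


@pytest.fixture(scope="session")
def fixture():
    """The packaged curated fixture: named case-study variants + evidence."""
    return paper_fixture()


@pytest.fixture()
def config():
    return EngineConfig()
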