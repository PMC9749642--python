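import pytest

from bedflow.config import SynthesisSettings
from bedflow.synth import FIXTURE_SEED, gen_config


@pytest.fixture(scope="session")
def fixture_config():
    """The frozen baseline-shortage configuration."""
    return gen_config()


@pytest.fixture(scope="session")
def fixture_run(fixture_config):
    return fixture_config.run()


@pytest.fixture(scope="session")
def inert_config():
    """Feedback-free, zero-growth configuration (equilibrium archetype)."""
    return gen_config(SynthesisSettings(seed=FIXTURE_SEED, archetype="inert"))
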