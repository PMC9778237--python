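import numpy as np
import pytest
from hypothesis import settings

from repgame.engine import RunConfig, run_realization

# property tests must be reproducible run-to-run
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_run():
    """One fully instrumented small simulation shared across tests."""
    cfg = RunConfig(
        n_agents=6,
        n_rounds=40,
        seed=123,
        record_events=True,
        instrument=True,
    )
    return run_realization(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(987654321)
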