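import numpy as np
import pytest

from ampatlas import pipeline, simulate


@pytest.fixture(scope="session")
def default_sim():
    """One deterministic run of the reference synthetic scenario."""
    return simulate.simulate(simulate.default_config(seed=1))


@pytest.fixture(scope="session")
def scenario_report():
    """Full pipeline report over the reference scenario (seed 1)."""
    return pipeline.run_scenario(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
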