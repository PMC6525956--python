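import numpy as np
import pytest

from stpcircuit import ExperimentConfig, run_configured_experiment


@pytest.fixture(scope="session")
def six_unit_experiment():
    """Default 200-step six-unit sweep (noise-free hypothetical stimulus)."""
    config = ExperimentConfig()
    net, seq, results = run_configured_experiment(config)
    return net, seq, results


@pytest.fixture(scope="session")
def two_unit_experiment():
    """Two-unit all-STF sweep on the same default stimulus (gain doubled)."""
    config = ExperimentConfig(network="two_unit")
    net, seq, results = run_configured_experiment(config)
    return net, seq, results


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
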