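import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from islandscan.motif_scan import build_pwm
from islandscan.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def consensus_pwm10():
    """Single-instance −10 matrix: consensus scores 12 bits, any mismatch -inf."""
    return build_pwm(["TATAAT"], name="minus10")


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated library with planted promoters (2 templates)."""
    config = SimulationConfig(n_templates=2, daughters_per_parent=1500, seed=11)
    return config, simulate_dataset(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
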