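import numpy as np
import pytest

from homeorate import NeuronParams, RegimeSchedule
from homeorate.inputs import InputRegime


@pytest.fixture(scope="session")
def neuron() -> NeuronParams:
    """The sigmoidal rate neuron used across the homeostasis figures."""
    return NeuronParams(tau_r=0.01, r_max=100.0, sigma=20.0)


@pytest.fixture(scope="session")
def short_schedule() -> RegimeSchedule:
    """Two quick input regimes for smoke-level closed-loop runs."""
    return RegimeSchedule(
        regimes=(InputRegime(10.0, 4.0, "lo"), InputRegime(30.0, 8.0, "hi")),
        regime_duration=30.0,
        switch_interval=0.05,
        seed=5,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
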