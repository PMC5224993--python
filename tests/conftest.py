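import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import asersim as a

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def step_proto():
    """The canonical 60-s downstep at t = 10 s on a 120-s horizon."""
    return a.step_protocol(10.0, 60.0, 1.0, 120.0)


@pytest.fixture(scope="session")
def reference_traces(step_proto):
    """Model output at the reference (GA-fitted) parameter set."""
    return a.integrate(a.REFERENCE_PARAMETERS, step_proto)


@pytest.fixture(scope="session")
def noiseless_target(reference_traces):
    return a.TargetTraces.from_simulated(reference_traces)


@pytest.fixture(scope="session")
def fitness_grid_time():
    return np.arange(1201) * 0.1
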