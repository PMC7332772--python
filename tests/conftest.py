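import pytest
from hypothesis import HealthCheck, settings

from mtuenergy.parameters import reference_morphometry, reference_parameters
from mtuenergy.pipeline import SimulationConfig, run_simulation
from mtuenergy.synthetic import (
    SyntheticProtocol,
    generate_pedal_angle,
    generate_stimulation,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def ref_morph():
    return reference_morphometry()


@pytest.fixture(scope="session")
def ref_params():
    return reference_parameters()


@pytest.fixture(scope="session")
def short_protocol():
    """Noiseless study protocol truncated to 30 s of load."""
    return SyntheticProtocol(duration_load=30.0, noise_sd_pcr=0.0)


@pytest.fixture(scope="session")
def sim_inputs(short_protocol):
    angle = generate_pedal_angle(short_protocol)
    emg = generate_stimulation(short_protocol)
    return angle, emg


@pytest.fixture(scope="session")
def sim_result(ref_params, sim_inputs):
    """Reference simulation over the validation window plus margin."""
    angle, emg = sim_inputs
    return run_simulation(ref_params, angle, emg.stim, SimulationConfig(),
                          t_end=27.0)
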