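import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from brainfuel.kinetics import PlasmaInputFunction
from brainfuel.regional import load_atlas
from brainfuel.schedules import acac_schedule, fdg_schedule
from brainfuel.synthetic import (
    CompartmentParameters,
    default_input_parameters,
    make_input_function,
    make_phantom,
    simulate_tissue_tac,
)

settings.register_profile(
    "suite", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def atlas():
    return load_atlas()


@pytest.fixture(scope="session")
def fdg_sched():
    return fdg_schedule()


@pytest.fixture(scope="session")
def acac_sched():
    return acac_schedule()


@pytest.fixture(scope="session")
def glucose_ipf():
    return make_input_function(default_input_parameters("glucose"), duration=62.0, cp_met=5.1)


@pytest.fixture(scope="session")
def acac_ipf():
    return make_input_function(default_input_parameters("acac"), duration=12.0, cp_met=0.14)


@pytest.fixture(scope="session")
def std_2tc():
    # irreversible kinetics with closed-form Ki = 0.102*0.062/0.192
    return CompartmentParameters(K1=0.102, k2=0.13, k3=0.062, vb=0.0)


@pytest.fixture(scope="session")
def noiseless_fdg_tac(glucose_ipf, std_2tc, fdg_sched):
    return simulate_tissue_tac(glucose_ipf, std_2tc, fdg_sched, noise_sd_scale=0.0)


@pytest.fixture(scope="session")
def phantom(atlas):
    return make_phantom((40, 44, 40), atlas, seed=0, voxel_size=2.0)


@pytest.fixture
def constant_ipf():
    """Flat plasma curve: theta(t) = t exactly."""
    t = np.arange(0.0, 60.01, 0.1)
    return PlasmaInputFunction(t, np.full_like(t, 2.0), cp_met=5.1)
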