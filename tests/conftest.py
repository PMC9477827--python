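import numpy as np
import pytest

from dropscreen.gradient_design import design_1d_program, design_2d_program
from dropscreen.presets import (
    default_optics,
    nitrate_1d_plan,
    nitrate_growth_params,
    np_2d_plan,
    np_growth_params,
)
from dropscreen.synthetic_trace import OpticsModel, simulate_run


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def plan_1d():
    return nitrate_1d_plan()


@pytest.fixture(scope="session")
def program_1d(plan_1d):
    return design_1d_program(plan_1d)


@pytest.fixture(scope="session")
def plan_2d():
    return np_2d_plan()


@pytest.fixture(scope="session")
def program_2d(plan_2d):
    return design_2d_program(plan_2d)


@pytest.fixture(scope="session")
def growth_1d():
    return nitrate_growth_params()


@pytest.fixture(scope="session")
def growth_2d():
    return np_growth_params()


@pytest.fixture(scope="session")
def optics_default():
    return default_optics()


@pytest.fixture(scope="session")
def optics_clean():
    """Noise-free optics: sharp rectangular pulses, no drift or jitter."""
    return OpticsModel(noise_sd=0.0, heterogeneity_sd=0.0, edge_sigma_samples=0.0)


@pytest.fixture(scope="session")
def clean_run_1d(plan_1d, program_1d, growth_1d, optics_clean):
    """Noise-free 440-droplet 1D run (truth + day-0/day-7 traces)."""
    return simulate_run(
        plan_1d, program_1d, growth_1d, optics_clean,
        seed=11, measure_days=(0, 7), volume_cv=0.0, noise_free=True,
    )


@pytest.fixture(scope="session")
def noisy_run_1d(plan_1d, program_1d, growth_1d, optics_default):
    """Default-noise 440-droplet 1D run (truth + day-0/day-7 traces)."""
    return simulate_run(
        plan_1d, program_1d, growth_1d, optics_default,
        seed=11, measure_days=(0, 7),
    )
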