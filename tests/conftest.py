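import numpy as np
import pytest

from thermoslurry.catalogue import default_design, default_processes, default_sources
from thermoslurry.simulate import simulate


@pytest.fixture(scope="session")
def full_sim_noise_free():
    """Default unamended run over the full 0-80 degC grid, exact observations."""
    design = default_design(seed=11, noise_cv=0.0)
    sim = simulate(design, default_processes(), default_sources())
    return design, sim


@pytest.fixture(scope="session")
def small_sim():
    """A cheap five-temperature run for smoke-level checks."""
    design = default_design(
        seed=5, noise_cv=0.0, temperatures=[10, 25, 40, 55, 70], time_points=(15.0, 40.0, 100.0)
    )
    sim = simulate(design, default_processes(), default_sources())
    return design, sim


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
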