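import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from givh import (
    DesignSpec,
    Grid,
    expand_design,
    observe_counts,
    simulate_abundance,
    simulate_covariate_field,
)
from givh.simulate import draw_convenience


@pytest.fixture(scope="session")
def grid10() -> Grid:
    return Grid(10, 10)


@pytest.fixture(scope="session")
def fields10(grid10):
    return [
        simulate_covariate_field(grid10, 4.0, seed=100 + k, name=f"z{k + 1}")
        for k in range(3)
    ]


@pytest.fixture(scope="session")
def sim_counts(grid10, fields10):
    """A small simulated survey informative enough for quick model fits."""
    surface = simulate_abundance(fields10, [np.log(15.0), 0.6, -0.6, 0.4], seed=7)
    survey = draw_convenience(grid10, 30, grid10.center_cell, 3.0, seed=8)
    counts = observe_counts(surface, survey, coverage=0.3, detection=1.0, seed=9)
    return surface, survey, counts


@pytest.fixture(scope="session")
def design10(fields10):
    return expand_design(fields10[:2], DesignSpec())
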