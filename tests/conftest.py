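"""Shared fixtures: landscapes, ladders, and one reference umbrella run.

The heavy umbrella-exchange run (21 windows, 2e5 steps, fixed master
seed) is session-scoped and shared between the sampling, unbiasing and
acceptance tests so the suite performs it once.
"""

import numpy as np
import pytest
from hypothesis import settings

from dimerpmf import (
    BrownianParams,
    ToyLandscape,
    build_ladder,
    marginal_pmf_oracle,
    run_us_remd,
)

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")

REFERENCE_STEPS = 200_000
REFERENCE_TAU_EX = 0.2          # ps = 20 integrator steps
WELL_BARRIER_REGION = (5.35, 6.2)
BOUNDARY_REGION = (5.9, 6.6)


@pytest.fixture(scope="session")
def landscape():
    return ToyLandscape.default()


@pytest.fixture(scope="session")
def flat_landscape():
    return ToyLandscape.flat()


@pytest.fixture(scope="session")
def ladder(landscape):
    return build_ladder(landscape, d_range=(5.4, 7.4), spacing=0.1)


@pytest.fixture(scope="session")
def oracle(landscape):
    grid = np.arange(landscape.d_range[0] + 0.01, landscape.d_range[1], 0.02)
    return marginal_pmf_oracle(landscape, grid)


@pytest.fixture(scope="session")
def remd_run(landscape, ladder):
    """Bound-start window-exchange run at the reference budget, seed 1."""
    params = BrownianParams(n_steps=REFERENCE_STEPS, seed=1)
    series, log = run_us_remd(landscape, ladder, params,
                              tau_ex=REFERENCE_TAU_EX, init_mode="bound")
    return series, log
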