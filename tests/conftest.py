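"""Shared fixtures.

Expensive reactor runs are session-scoped and reused across test
modules; they use the packaged default parameters, so any test that
needs a modified model builds its own run.
"""

import numpy as np
import pytest

from admtaxa import (
    NoiseModel,
    default_parameters,
    experiment_schedule,
    generate_observations,
    integrate,
    steady_state_init,
)


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def ctrl_schedule(params):
    return experiment_schedule("ctrl", params)


@pytest.fixture(scope="session")
def nh3_schedule(params):
    return experiment_schedule("NH3", params)


@pytest.fixture(scope="session")
def steady_state(params, ctrl_schedule):
    return steady_state_init(params, ctrl_schedule)


@pytest.fixture(scope="session")
def ctrl_run(params, ctrl_schedule, steady_state):
    return integrate(ctrl_schedule, params, y0=steady_state)


@pytest.fixture(scope="session")
def nh3_run(params, nh3_schedule, steady_state):
    return integrate(nh3_schedule, params, y0=steady_state)


@pytest.fixture(scope="session")
def noise_free_obs(params, nh3_schedule, nh3_run):
    return generate_observations(params, nh3_schedule, NoiseModel(cv=0.0),
                                 seed=1, result=nh3_run)
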