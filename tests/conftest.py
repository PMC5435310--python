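import numpy as np
import pytest

from ctscr.geometry import TrapArray, build_grid
from ctscr.model import Params
from ctscr.schedule import Schedule
from ctscr.simulate import simulate_detections, simulate_population


@pytest.fixture
def tiny_domain():
    """2x2 unit region at resolution 0.25 with one linear density covariate."""
    return build_grid(
        (0.0, 0.0, 2.0, 2.0),
        0.25,
        covariate_fields=[lambda pts: (pts[:, 0] - 1.0) / 2.0],
    )


@pytest.fixture
def tiny_traps():
    locs = np.array([[0.5, 0.5], [1.5, 0.5], [0.5, 1.5], [1.5, 1.5]])
    w = np.column_stack([np.ones(4), np.array([-0.5, 0.0, 0.5, 1.0])])
    return TrapArray(locations=locs, durations=np.array([5.0, 5.0, 8.0, 10.0]), w=w)


@pytest.fixture
def tiny_schedule(tiny_traps):
    return Schedule.alternating_day_night(tiny_traps.durations, period=1.0)


@pytest.fixture
def tiny_params():
    return Params(beta=np.array([1.5, 0.6]), alpha=np.array([-0.3, 0.4]),
                  xi=np.array([-0.8]), sigma=0.35)


@pytest.fixture
def tiny_survey(tiny_domain, tiny_traps, tiny_schedule, tiny_params):
    """A small simulated survey with known truth, for sampler/likelihood tests."""
    rng = np.random.default_rng(11)
    centers = simulate_population(tiny_params, tiny_domain, rng)
    data, observed = simulate_detections(
        tiny_params, centers, tiny_traps, tiny_schedule, rng
    )
    return {
        "data": data,
        "domain": tiny_domain,
        "traps": tiny_traps,
        "schedule": tiny_schedule,
        "params": tiny_params,
        "centers": centers,
        "observed": observed,
    }
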