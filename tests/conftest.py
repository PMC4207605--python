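import warnings

import numpy as np
import pytest

from ballincup import (
    ModelParams,
    Strategy,
    simulate_strategy,
    strobe_at_cup_peaks,
)

#: the period-1 anchor strategy: 1 Hz, 10 cm peak-to-peak, ball at 1 rad
PERIOD1 = Strategy(amplitude_pp=0.10, frequency=1.0, theta0=1.0, omega0=0.0)
#: a quasi-periodic neighbour of the anchor
QUASI = Strategy(amplitude_pp=0.10, frequency=1.0, theta0=0.4, omega0=0.0)
#: a strongly chaotic strategy
CHAOTIC = Strategy(amplitude_pp=0.10, frequency=1.0, theta0=-1.35, omega0=0.0)


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def period1_traj():
    return simulate_strategy(PERIOD1)


@pytest.fixture(scope="session")
def quasi_traj():
    return simulate_strategy(QUASI)


@pytest.fixture(scope="session")
def chaotic_traj():
    return simulate_strategy(CHAOTIC)


@pytest.fixture(scope="session")
def period1_strobe(period1_traj):
    return strobe_at_cup_peaks(period1_traj, 1.0)


@pytest.fixture(scope="session")
def coarse_map():
    """A small result-space map shared by the map-pattern tests.

    20 x 20 cells over the full execution-variable ranges; evaluated once
    per session (a few minutes).
    """
    from ballincup.result_space import evaluate_result_space

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return evaluate_result_space(
            np.linspace(0.08, 0.44, 20),
            np.linspace(-np.pi / 2, np.pi / 2, 20),
        )
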