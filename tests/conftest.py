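"""Shared fixtures: the fixed-seed synthetic ensembles.

The three ensembles (10 idling, 10 treadmilling, 10 transition recordings at
the generator defaults) are expensive (~2 s of rasterization per movie), so
they are built once per session and shared by the unit and acceptance tests.
The seeds are fixed regression seeds chosen before the generator defaults
were frozen.
"""

import numpy as np
import pytest

from pmnshape import SyntheticParams, simulate_roundness
from pmnshape.measures import measure_battery

IDLE_SEEDS = tuple(range(1000, 1010))
TREAD_SEEDS = tuple(range(2000, 2010))
TRANS_SEEDS = tuple(range(3000, 3010))


def _ensemble(factory, seeds):
    out = []
    for seed in seeds:
        series, info = simulate_roundness(factory(seed=seed))
        out.append((series, info))
    return out


@pytest.fixture(scope="session")
def idle_ensemble():
    """Ten idling recordings reduced to (RSeries, info) pairs."""
    return _ensemble(SyntheticParams.idling, IDLE_SEEDS)


@pytest.fixture(scope="session")
def tread_ensemble():
    """Ten treadmilling recordings reduced to (RSeries, info) pairs."""
    return _ensemble(SyntheticParams.treadmilling, TREAD_SEEDS)


@pytest.fixture(scope="session")
def trans_ensemble():
    """Ten idling-to-treadmilling transition recordings."""
    return _ensemble(SyntheticParams.transition, TRANS_SEEDS)


@pytest.fixture(scope="session")
def idle_measures(idle_ensemble):
    return [measure_battery(s) for s, _ in idle_ensemble]


@pytest.fixture(scope="session")
def tread_measures(tread_ensemble):
    return [measure_battery(s) for s, _ in tread_ensemble]


@pytest.fixture(scope="session")
def small_recording():
    """One short, small-grid idling recording with frames kept."""
    from pmnshape import simulate_state
    params = SyntheticParams.idling(seed=7, n=40, r0=25.0, grid=96)
    return simulate_state(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
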