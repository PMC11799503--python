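import numpy as np
import pytest

from tiaprop import MonoExpTAC, Schedule, PopulationTauStats


@pytest.fixture
def tac50():
    """Reference curve: A0 = 100 MBq, effective half-life 50 h, 177Lu."""
    return MonoExpTAC.from_half_lives(100.0, 50.0, 159.5)


@pytest.fixture
def sched_full():
    return Schedule([24.0, 96.0, 168.0])


@pytest.fixture
def sched_reduced():
    return Schedule([24.0, 96.0])


@pytest.fixture
def right_kidney_stats():
    return PopulationTauStats.from_mean_cv(78.0, 0.20)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
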