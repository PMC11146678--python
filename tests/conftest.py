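import numpy as np
import pytest

from reachstates import workflows as wf
from reachstates.synthetic import (PopulationSpec, TaskTiming, make_population,
                                   make_task_schedule, simulate_spikes)


@pytest.fixture(scope="session")
def small_session():
    """A 20-unit V6A-like session with 3 trials per target: big enough to
    exercise folds, symbolization and decoding, small enough for unit tests."""
    spec = make_population(20, "V6A-like", seed=11)
    trials = make_task_schedule(3, seed=12)
    data = simulate_spikes(spec, trials, seed=13)
    return spec, trials, data


@pytest.fixture(scope="session")
def tiny_trials():
    return make_task_schedule(2, seed=5)


@pytest.fixture(scope="session")
def flat_spec():
    """Homogeneous population: unit gains and tunings all 1."""
    return make_population(5, "custom", seed=3)
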