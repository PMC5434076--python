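import numpy as np
import pytest

from adtherapy import (ControlBounds, DEConfig, ModelParameters,
                       ObjectiveWeights, pathological_steady_state)


@pytest.fixture(scope="session")
def p():
    return ModelParameters()


@pytest.fixture(scope="session")
def w():
    return ObjectiveWeights()


@pytest.fixture(scope="session")
def b():
    return ControlBounds()


@pytest.fixture(scope="session")
def patho(p):
    """Untreated flare-ON fixed point of the nominal severe cohort."""
    return pathological_steady_state(p)


@pytest.fixture(scope="session")
def de_small():
    """Reduced-budget optimizer settings for unit-level planning tests."""
    return DEConfig(population_size=30, generations=60, seed=123)


@pytest.fixture(scope="session")
def post(p, patho):
    """State after a 19-day constant-potency induction (receptors OFF)."""
    from adtherapy import TreatmentSchedule, simulate
    sched = TreatmentSchedule.constant(19.0, 17.0, 0.04)
    return simulate(patho, sched, p).state_at_end()


@pytest.fixture()
def rng():
    return np.random.default_rng(20171)
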