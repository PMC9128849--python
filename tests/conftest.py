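import numpy as np
import pytest

from mrp import design, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def exp2_plan():
    """Single-batch online design: 30 participants x 34 pairs."""
    return design.build_design("exp2", n_participants=30, seed=7, n_pairs=34)


@pytest.fixture(scope="session")
def exp2_responses(exp2_plan):
    """Simulated cohort from the directional preset (attentive agents)."""
    params = simulate.get_preset("exp2-default")
    return simulate.simulate_responses(exp2_plan, params, seed=11)


@pytest.fixture(scope="session")
def null_responses():
    """Small cohort simulated with zero separation everywhere."""
    plan = design.build_design("exp2", n_participants=8, seed=3, n_pairs=34)
    return simulate.simulate_responses(plan, simulate.get_preset("null-effect"), seed=5)
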