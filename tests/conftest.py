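import numpy as np
import pytest

from surubim import (
    PARAMS_TABLE1,
    FieldSet,
    GridSpec,
    InitSpec,
    PrePatternSpec,
    build_initial_state,
)


@pytest.fixture
def table1():
    return PARAMS_TABLE1


@pytest.fixture
def small_grid():
    return GridSpec(20, 10)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_state(rng):
    """A small random FieldSet for stepper tests."""
    shape = (8, 8)
    return FieldSet(*(rng.uniform(-1, 1, size=shape) for _ in range(4)))


@pytest.fixture
def seeded_initial_state():
    """A 64x64 noisy initial state used by the integration tests."""
    grid = GridSpec(64, 64)
    state = build_initial_state(
        grid,
        PrePatternSpec(n_stripes=4, stripe_width=5),
        InitSpec(u02=0.0, seed=42),
    )
    return grid, state
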