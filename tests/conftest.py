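"""Shared fixtures: parameter sets, small states, and deterministic RNG."""

from __future__ import annotations

import numpy as np
import pytest

from spindlemc import ModelParams, RidgePattern, initialize_state
from spindlemc._rng import seed_state


@pytest.fixture(scope="session")
def default_params() -> ModelParams:
    return ModelParams().validate()


@pytest.fixture(scope="session")
def default_pattern(default_params) -> RidgePattern:
    return RidgePattern.from_params(default_params)


@pytest.fixture()
def small_params() -> ModelParams:
    """A 300 μm box with a handful of cells — fast to simulate."""
    return ModelParams(L=300.0, n_init=12, terminal_count=18,
                       relax_time=0.0).validate()


@pytest.fixture()
def small_state(small_params):
    return initialize_state(small_params, seed=3)


@pytest.fixture()
def rng():
    return seed_state(12345)


def rand_cells(n, L, rng, a_range=(10.0, 45.0), ar_range=(1.0, 5.0)):
    """Random valid cells for oracle comparisons (numpy Generator)."""
    from spindlemc import Cell

    cells = []
    for i in range(n):
        a = rng.uniform(*a_range)
        b = a / rng.uniform(*ar_range)
        cells.append(Cell(
            id=i,
            center=rng.uniform(0, L, 2),
            a=a, b=b,
            phi=rng.uniform(0, 2 * np.pi),
            polarity=rng.normal(size=2),
        ))
    return cells
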