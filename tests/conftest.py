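"""Shared fixtures: a small synthetic study region with known truth."""

from __future__ import annotations

import numpy as np
import pytest

from ashazard import (
    build_dataset,
    calibrate_true_model,
    generate_stack,
    sample_wells,
)

ACTIVE = ["cont_00", "cont_01", "cont_02"]
TRUE_COEFS = [1.0, -0.8, 0.6]


@pytest.fixture(scope="session")
def stack():
    return generate_stack(seed=1, nrows=32, ncols=32, n_continuous=5,
                          n_categorical=2, smoothing_radius=3)


@pytest.fixture(scope="session")
def truth(stack):
    return calibrate_true_model(stack, ACTIVE, TRUE_COEFS)


@pytest.fixture(scope="session")
def wells(stack, truth):
    return sample_wells(stack, truth, n=2000, seed=7)


@pytest.fixture(scope="session")
def dataset(stack, wells):
    return build_dataset(stack, wells)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
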