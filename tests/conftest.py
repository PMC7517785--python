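"""Shared fixtures: small designs that keep unit tests fast."""

import numpy as np
import pytest

from lgcdm import (
    AttributeGrowthParameters,
    ItemParameters,
    LongitudinalResponses,
    ModelSpec,
    QMatrix,
    TimeCoding,
)
from lgcdm.simulation import SimulationDesign, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_qmatrix():
    """Six items, two attributes: four single-attribute items, two double."""
    return QMatrix(
        entries=np.array(
            [[1, 0], [1, 0], [0, 1], [0, 1], [1, 1], [1, 1]]
        )
    )


@pytest.fixture
def small_design(small_qmatrix):
    """A small unconditional growth design used across estimation tests."""
    spec = ModelSpec(
        family="lg_uncond",
        qmatrix=small_qmatrix,
        time_coding=TimeCoding(np.array([0.0, 1.0])),
        quadrature=5,
        eps_sd=0.0,
    )
    item = ItemParameters(f=np.full(6, -1.4), d=np.full(6, 2.6))
    attr = AttributeGrowthParameters(
        b=np.array([-0.3, 0.4]), sigma0=0.5, sigma1=0.2, eps_sd=0.0
    )
    return SimulationDesign(
        spec=spec, item_params=item, attr_params=attr, n_persons=200, seed=3
    )


@pytest.fixture
def small_data(small_design):
    data, truth = simulate_dataset(small_design, seed=11)
    return data


@pytest.fixture
def small_cond_design(small_qmatrix):
    spec = ModelSpec(
        family="lg_cond",
        qmatrix=small_qmatrix,
        time_coding=TimeCoding(np.array([0.0, 1.0])),
        covariate_names=("z",),
        quadrature=5,
        eps_sd=0.0,
    )
    item = ItemParameters(f=np.full(6, -1.4), d=np.full(6, 2.6))
    attr = AttributeGrowthParameters(
        b=np.array([-0.3, 0.4]), sigma0=0.5, sigma1=0.2,
        h=np.array([0.4, 0.2]), h0=0.2, h1=0.1, eps_sd=0.0,
    )
    return SimulationDesign(
        spec=spec, item_params=item, attr_params=attr, n_persons=200,
        covariate_generator="bernoulli(0.5)", seed=3,
    )
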