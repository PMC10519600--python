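"""Shared fixtures: the decay model, its 3-cell-type replicate, and data."""

import pytest
from hypothesis import settings

from foldclust import ParameterVector, replicate_model

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from foldclust.datasets import toy_model, toy_scenario


@pytest.fixture(scope="session")
def decay_model():
    return toy_model()


@pytest.fixture(scope="session")
def decay3(decay_model):
    """Three cell types, decay rate specific, cell type 1 as reference."""
    return replicate_model(decay_model, 3, {"p"})


@pytest.fixture(scope="session")
def decay3_true(decay3):
    """True parameters: log10 p = (-1.5, -1.3, -1.2)."""
    return ParameterVector.from_dict(
        decay3, {"p": -1.5, "r_p__2": 0.2, "r_p__3": 0.3}
    )


@pytest.fixture(scope="session")
def toy_data():
    """One fixed noisy realization of the toy experiment (seed 7)."""
    return toy_scenario(seed=7).generate()


@pytest.fixture(scope="session")
def toy_data_noiseless():
    return toy_scenario(seed=7).generate(noiseless=True)
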