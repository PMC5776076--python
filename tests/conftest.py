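import numpy as np
import pytest

from tkrwear import (ImplantParams, MaterialProperties, WearCoefficientModel,
                     make_femoral_surface, make_insert_surface)


@pytest.fixture(scope="session")
def mat():
    return MaterialProperties()


@pytest.fixture(scope="session")
def wear_model():
    return WearCoefficientModel()


@pytest.fixture(scope="session")
def small_params():
    """Coarse implant pair for desk-scale contact/wear tests."""
    return ImplantParams(grid_resolution=40)


@pytest.fixture(scope="session")
def femoral(small_params):
    return make_femoral_surface(small_params)


@pytest.fixture(scope="session")
def insert(small_params):
    return make_insert_surface(small_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
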