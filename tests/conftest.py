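import numpy as np
import pytest
from hypothesis import settings

from dotlattice import ExperimentDesign, ObserverParams, OrientationGrid, make_prior

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

ARS = (1 / 1.3, 1 / 1.2, 1 / 1.1, 1.0, 1.1, 1.2, 1.3)


@pytest.fixture(scope="session")
def grid():
    return OrientationGrid()


@pytest.fixture(scope="session")
def baseline():
    return ObserverParams()


@pytest.fixture(scope="session")
def uniform_prior(grid):
    return make_prior("uniform", grid)


@pytest.fixture(scope="session")
def natural_prior(grid):
    return make_prior("natural", grid)


@pytest.fixture(scope="session")
def design():
    return ExperimentDesign(seed=11)


def logit(p):
    return np.log(np.asarray(p) / (1 - np.asarray(p)))
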