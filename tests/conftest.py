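import numpy as np
import pytest

from ewoc import DoseSpace, PriorSpec, study_scenarios

THETA = 1.0 / 3.0


@pytest.fixture(scope="session")
def cont_space():
    return DoseSpace.continuous()


@pytest.fixture(scope="session")
def disc_space():
    return DoseSpace.discrete()


@pytest.fixture(scope="session")
def scenarios():
    return study_scenarios()


@pytest.fixture(scope="session")
def uniform_prior():
    return PriorSpec.uniform()


@pytest.fixture(scope="session")
def study_prior():
    return PriorSpec.bivariate_normal()


class NoToxScenario:
    """Degenerate true curve with (almost) no toxicity anywhere."""

    def prob(self, x):
        return np.zeros_like(np.asarray(x, dtype=float)) + 1e-12

    def true_mtd(self, space, theta=THETA):
        return space.xmax


class AllToxScenario:
    """Degenerate true curve with certain toxicity everywhere."""

    def prob(self, x):
        return np.ones_like(np.asarray(x, dtype=float)) - 1e-12

    def true_mtd(self, space, theta=THETA):
        return space.xmin


@pytest.fixture
def no_tox_scenario():
    return NoToxScenario()


@pytest.fixture
def all_tox_scenario():
    return AllToxScenario()
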