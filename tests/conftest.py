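import numpy as np
import pytest

from tagkin import DemographyParams, ModelParams, equilibrium_two_locus
from tagkin.engine import PopulationState


@pytest.fixture(scope="session")
def demography():
    return DemographyParams(N=30, m=0.3, r=0.1)


@pytest.fixture(scope="session")
def probs(demography):
    return equilibrium_two_locus(demography)


@pytest.fixture(scope="session")
def fig2c_params():
    return ModelParams(
        demography=DemographyParams(N=30, m=0.3, r=0.08),
        alpha=1.0, c_search=0.0, b=0.3, c=0.1, mu_trait=0.001, L_max=100,
    )


@pytest.fixture
def random_state():
    """Factory for random valid population states."""

    def make(L_max: int, seed: int) -> PopulationState:
        rng = np.random.default_rng(seed)
        x = rng.dirichlet(np.ones(2 * L_max)).reshape(L_max, 2)
        return PopulationState(x)

    return make
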