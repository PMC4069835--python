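import numpy as np
import pytest

from propriosim.synthetic import (default_muscle_params,
                                  default_synthetic_roster)


@pytest.fixture(scope="session")
def roster():
    return default_synthetic_roster()


@pytest.fixture(scope="session")
def muscle_params(roster):
    return default_muscle_params(roster)


@pytest.fixture(scope="session")
def fitted_surfaces(roster):
    from propriosim.pipeline import fit_surface_set
    return fit_surface_set(roster)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
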