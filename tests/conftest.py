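import numpy as np
import pytest

import multicargo as mc
from multicargo import meanfield as mf
from multicargo.gillespie import simulate_ensemble


@pytest.fixture(scope="session")
def uniform():
    return mc.uniform_profile(1.0)


@pytest.fixture(scope="session")
def bump():
    return mc.logistic_bump_profile()


@pytest.fixture(scope="session")
def uniform_model_n4(uniform):
    return mc.CargoModel(N=4, kappa1=uniform, kappa2=mc.uniform_profile(1.0))


@pytest.fixture(scope="session")
def bump_model_n4(bump):
    return mc.CargoModel(N=4, kappa1=bump, kappa2=mc.uniform_profile(1.0))


@pytest.fixture(scope="session")
def pb_uniform():
    return mf.uniform_bound_legs(1.0)


@pytest.fixture(scope="session")
def uniform_ensemble_n4(uniform_model_n4):
    """Moderate uniform-rate ensemble shared by analysis unit tests."""
    return simulate_ensemble(uniform_model_n4, 3000, 12.0, master_seed=101, x0=0.0)


@pytest.fixture(scope="session")
def uniform_ensemble_n10(uniform):
    model = mc.CargoModel(N=10, kappa1=uniform, kappa2=mc.uniform_profile(1.0))
    return simulate_ensemble(model, 800, 25.0, master_seed=102, x0=0.0)
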