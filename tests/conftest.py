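import numpy as np
import pytest

import modefit as mf


@pytest.fixture(scope="session")
def constitutive():
    return mf.build_constitutive_model()


@pytest.fixture(scope="session")
def irf7():
    return mf.build_irf7_model()


@pytest.fixture(scope="session")
def theta_true():
    return mf.ParameterSet(mf.CONSTITUTIVE_TRUE_PARAMS)


@pytest.fixture(scope="session")
def insilico_small():
    """Constitutive in-silico event table at a size cheap enough for units."""
    return mf.generate_insilico_data(n_runs=3000, seed=11)


@pytest.fixture(scope="session")
def insilico_full():
    """Paper-scale constitutive in-silico dataset (10000 runs)."""
    return mf.generate_insilico_data(n_runs=10000, seed=11)


@pytest.fixture(scope="session")
def surrogate():
    return mf.generate_flow_surrogate(mf.SurrogateSpec(seed=3))


@pytest.fixture(scope="session")
def irf7_final_ensemble(irf7):
    """IRF7 ensemble at nominal parameters sampled at 48 h (shared; costly)."""
    return mf.simulate_ensemble(
        irf7,
        irf7.default_parameters,
        irf7.default_initial_state,
        [2880.0],
        ns=400,
        base_seed=5,
    )
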