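import numpy as np
import pytest

from opalstar import (
    OpALParams,
    get_env_preset,
    get_param_preset,
    make_bernoulli_env,
    make_gaussian_env,
)


@pytest.fixture(scope="session")
def env10():
    """10-arm Bernoulli task: one 0.9 arm, nine 0.8 arms."""
    return get_env_preset("bernoulli_10arm")


@pytest.fixture(scope="session")
def env_det():
    """Deterministic 2-arm Bernoulli task [1.0, 0.0]."""
    return make_bernoulli_env([1.0, 0.0], name="det")


@pytest.fixture(scope="session")
def env_gauss():
    """Overlapping Gaussian task, means 0.8 vs 0.7, sigma 0.1."""
    return make_gaussian_env([0.8, 0.7], 0.1, name="gauss")


@pytest.fixture(scope="session")
def fig2_params():
    """Gaussian-task parameter triplet with midrange critic start."""
    return get_param_preset("fig2", v0=0.75)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def default_params():
    return OpALParams()
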