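import dataclasses

import numpy as np
import pytest

from riskreclass import simulate

#: fixed seed for the large calibration cohort (questionnaire month of the
#: emulated study); chosen once, shared across tests to avoid regenerating
BIG_SEED = 20061101
BIG_N = 50_000


@pytest.fixture(scope="session")
def study_params():
    """Default generator parameters at the study's cohort size."""
    return simulate.default_params(n=579, seed=7)


@pytest.fixture(scope="session")
def big_params():
    return simulate.default_params(n=BIG_N, seed=BIG_SEED)


@pytest.fixture(scope="session")
def big_cohort(big_params):
    """One large synthetic cohort shared by marginal/recovery checks."""
    return simulate.generate_cohort(big_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def replace_params(params, **kw):
    return dataclasses.replace(params, **kw)
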