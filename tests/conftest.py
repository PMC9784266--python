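import numpy as np
import pytest
from hypothesis import settings

from cora import datasets

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def demo2spec():
    """f1 = Σm(1,3,7), f2 = Σm(2,6,7) over (x, y, z)."""
    return datasets.two_function_demo()


@pytest.fixture(scope="session")
def demo3spec():
    """Three functions of four inputs with heavy cross-output sharing."""
    return datasets.three_function_demo()


@pytest.fixture(scope="session")
def patients():
    return datasets.patient_groups()


@pytest.fixture(scope="session")
def injuries():
    return datasets.injury_rates()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
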