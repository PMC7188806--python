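import numpy as np
import pytest

from ctdlearn.design import DesignSpec, generate_design
from ctdlearn.synth import (GenerativeParams, NeuralParams, simulate_subject)


@pytest.fixture(scope="session")
def spec():
    return DesignSpec()


@pytest.fixture(scope="session")
def gparams():
    return GenerativeParams()


@pytest.fixture(scope="session")
def nparams():
    return NeuralParams()


@pytest.fixture(scope="session")
def design(spec):
    return generate_design(spec, seed=123)


@pytest.fixture(scope="session")
def subject(spec, gparams, nparams):
    """One fully simulated subject (design + behavior + patterns)."""
    return simulate_subject(spec, gparams, nparams, seed=7, subject=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
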