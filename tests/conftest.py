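import numpy as np
import pytest

from seqchoice import ModelParams, load_mcq_items


@pytest.fixture(scope="session")
def params():
    """The calibrated default model parameters."""
    return ModelParams()


@pytest.fixture(scope="session")
def noiseless(params):
    return params.with_(noise_sd=0.0)


@pytest.fixture(scope="session")
def mcq_items():
    return load_mcq_items()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
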