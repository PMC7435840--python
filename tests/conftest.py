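import numpy as np
import pytest

from alqc import preprocess, synthetic


@pytest.fixture(scope="session")
def default_study():
    """The default seven-product study at the package demo seed."""
    return synthetic.simulate_study(seed=1)


@pytest.fixture(scope="session")
def preprocessed_study(default_study):
    processed, state = preprocess.fit_preprocess(default_study)
    return processed, state


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
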