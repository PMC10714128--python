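import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_session():
    """One simulated closed-loop session shared by streaming/logging tests."""
    from plvloop.pipeline import simulate_session
    from plvloop.synth import MepModel

    return simulate_session(seed=42, n_low=25, n_high=25,
                            mep_model=MepModel(b_fc=0.25, sigma=0.4))
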