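import warnings

import numpy as np
import pytest

from isletkit import pipeline, synthio


@pytest.fixture(scope="session")
def default_islet():
    """One default synthetic islet (seed 1) shared across tests."""
    ts, gt = synthio.generate_islet(synthio.IsletConfig(seed=1))
    return ts, gt


@pytest.fixture(scope="session")
def noiseless_islet():
    ts, gt = synthio.generate_islet(
        synthio.IsletConfig(seed=3, noise_sd=0.0, drift_amp=0.0))
    return ts, gt


@pytest.fixture(scope="session")
def default_bundle(default_islet):
    ts, gt = default_islet
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pipeline.run_all(ts, pipeline.RunConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
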