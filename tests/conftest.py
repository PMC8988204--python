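import numpy as np
import pytest
from hypothesis import settings

from canopynet.prep import PrepConfig, prepare_dataset
from canopynet.synthetic import simulate_dataset

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=30)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_dataset():
    """A 60-plot trial prepared to 120 examples — cheap shared fixture."""
    plots, series = simulate_dataset(seed=7, n_varieties=15, n_nitrogen=2,
                                     n_reps=2)
    return prepare_dataset(plots, series, PrepConfig(target_count=120), seed=7)


@pytest.fixture(scope="session")
def default_dataset():
    """The full emulated trial: 480 plots augmented to 1000 examples."""
    plots, series = simulate_dataset(seed=1)
    ds = prepare_dataset(plots, series, PrepConfig(), seed=1)
    ds.plots = plots  # keep design metadata available to tests
    return ds


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
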