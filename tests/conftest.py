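import numpy as np
import pandas as pd
import pytest

from accelcal.metrics import RawSignal
from accelcal.pipeline import run_demo
from accelcal.synthetic import DEFAULT_DEMO_SEED


@pytest.fixture(scope="session")
def demo_result():
    """The packaged fixed-seed demonstration run (calibration + cross-validation)."""
    return run_demo(seed=DEFAULT_DEMO_SEED)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_signal(samples, fs=80.0, start="2021-05-11 08:00:00"):
    return RawSignal(pd.Timestamp(start), fs, np.asarray(samples, dtype=float))


@pytest.fixture
def constant_signal_factory():
    """Signals holding a constant (x, y, z) triple for a given duration."""

    def make(xyz, seconds=4, fs=80.0):
        n = int(seconds * fs)
        return make_signal(np.tile(np.asarray(xyz, dtype=float), (n, 1)), fs=fs)

    return make
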