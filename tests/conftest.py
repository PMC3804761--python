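import numpy as np
import pytest

from emicconn._mine import warm_up
from emicconn.preprocess import RegionalTimeSeries


@pytest.fixture(scope="session", autouse=True)
def _warm_kernels():
    # pay the JIT compilation cost once, outside timed assertions
    warm_up()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_series(data, tr=2.0):
    data = np.asarray(data, dtype=float)
    labels = tuple(f"R{i + 1:03d}" for i in range(data.shape[0]))
    return RegionalTimeSeries(data, labels, tr)


@pytest.fixture()
def small_series(rng):
    return make_series(rng.standard_normal((5, 60)))
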