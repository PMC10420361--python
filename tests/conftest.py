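import numpy as np
import pytest

from aagrowth import PatientSeries


def make_series(pid, times, diameters, **kwargs):
    return PatientSeries(pid, np.asarray(times, float),
                         np.asarray(diameters, float), **kwargs)


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
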