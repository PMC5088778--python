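import numpy as np
import pytest

from alphalat import SimulationParams, build_layout


@pytest.fixture(scope="session")
def layout8():
    return build_layout(8)


@pytest.fixture(scope="session")
def layout16():
    return build_layout(16)


@pytest.fixture(scope="session")
def layout32():
    return build_layout(32)


@pytest.fixture
def small_params():
    """A cheap simulation: 8 channels, 12 trials per cell, 4 subjects."""
    return SimulationParams(n_subjects=4, trials_per_condition=12, n_channels=8)


def make_epochs(data, srate=256.0, t0=0.0, layout=None):
    """Wrap a raw (trials, channels, samples) array as a minimal epochs object."""
    from types import SimpleNamespace

    data = np.asarray(data, dtype=float)
    times = t0 + np.arange(data.shape[-1]) / srate
    return SimpleNamespace(data=data, times=times, srate=srate, layout=layout)
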