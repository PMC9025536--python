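import numpy as np
import pytest
import scipy.integrate

from tfseize import (
    KernelParams,
    SampledSignal,
    analytic_signal,
    compute_adtfd,
    wvd,
)

try:
    from hypothesis import settings

    settings.register_profile("suite", deadline=None, derandomize=True)
    settings.load_profile("suite")
except ImportError:  # pragma: no cover
    pass

FS = 32.0
N = 256
T = np.arange(N) / FS


@pytest.fixture(scope="session")
def tone_signal():
    return SampledSignal(np.cos(2 * np.pi * 4 * T), FS)


@pytest.fixture(scope="session")
def spike_signal():
    x = np.zeros(N)
    x[[48, 128, 208]] = 1.0
    return SampledSignal(x, FS)


@pytest.fixture(scope="session")
def chirp_signal():
    # fundamental IF rising 1 -> 3 Hz over the 8-s segment
    f0 = 1.0 + 2.0 * T / 8.0
    phase = scipy.integrate.cumulative_trapezoid(f0, T, initial=0.0)
    return SampledSignal(np.cos(2 * np.pi * phase), FS)


@pytest.fixture(scope="session")
def tone_wvd(tone_signal):
    return wvd(analytic_signal(tone_signal), FS)


@pytest.fixture(scope="session")
def spike_wvd(spike_signal):
    return wvd(analytic_signal(spike_signal), FS)


@pytest.fixture(scope="session")
def tone_chain(tone_signal):
    return compute_adtfd(tone_signal, KernelParams())


@pytest.fixture(scope="session")
def spike_chain(spike_signal):
    return compute_adtfd(spike_signal, KernelParams())


@pytest.fixture(scope="session")
def chirp_chain(chirp_signal):
    return compute_adtfd(chirp_signal, KernelParams())
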