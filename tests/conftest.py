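import numpy as np
import pytest

from neuromse.io import WaveformSignal


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_abp(duration_s=60.0, fs=100.0, mean=100.0, pulse_pp=40.0, f0=1.2,
             start_time=0.0):
    """Clean sinusoidal arterial-pressure surrogate (pulse amp = pulse_pp)."""
    t = np.arange(int(duration_s * fs)) / fs
    samples = mean + (pulse_pp / 2) * np.sin(2 * np.pi * f0 * t)
    return WaveformSignal("ABP", fs, start_time, samples)


def make_icp(duration_s=60.0, fs=100.0, mean=10.0, pulse_pp=2.0, f0=1.0,
             start_time=0.0):
    t = np.arange(int(duration_s * fs)) / fs
    samples = mean + (pulse_pp / 2) * np.sin(2 * np.pi * f0 * t)
    return WaveformSignal("ICP", fs, start_time, samples)


@pytest.fixture
def abp_signal():
    return make_abp()


@pytest.fixture
def icp_signal():
    return make_icp()
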