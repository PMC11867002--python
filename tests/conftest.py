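"""Shared fixtures: small, fast synthetic recordings.

All test recordings use a 200 Hz sample rate so that the 155 ms after-effect
window is exactly 31 samples and the 6.45 Hz spectral grid is the natural
DFT grid of the window.
"""

import numpy as np
import pytest

from cycdbs.core import EpochSet
from cycdbs.synth import SimulationConfig, default_layout, simulate_subject


FS = 200.0


def fast_config(**overrides) -> SimulationConfig:
    """Desk-scale simulation defaults used throughout the test suite."""
    kw = dict(
        sample_rate=FS,
        duration=120.0,
        n_channels_per_hemisphere=8,
        n_subjects=6,
        seed=0,
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


@pytest.fixture(scope="session")
def layout():
    return default_layout(8)


@pytest.fixture(scope="session")
def stim_recording():
    """One 120 s recording with 20 Hz cyclic stimulation, induced mode."""
    return simulate_subject(fast_config(seed=11), 0, stim_frequency=20.0)


@pytest.fixture(scope="session")
def baseline_recording():
    """One 120 s DBS-OFF recording."""
    return simulate_subject(fast_config(seed=12), 0, stim_frequency=None)


def sinusoid_epochs(freq=20.0, n_trials=1, duration=4.0, amp=1.0, phases=None,
                    fs=FS) -> EpochSet:
    """Epochs of pure sinusoids, centered on t = 0."""
    t = np.arange(0, duration, 1.0 / fs)
    if phases is None:
        phases = np.zeros(n_trials)
    data = np.array([amp * np.cos(2 * np.pi * freq * t + p) for p in phases])[:, None, :]
    return EpochSet(data=data, times=t - duration / 2, sample_rate=fs,
                    alignment="consecutive")
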