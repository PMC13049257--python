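"""Shared fixtures: small phantoms and simulated acquisitions.

Everything is generated programmatically at session scope so expensive
simulations are shared across test modules.
"""

import numpy as np
import pytest

import wfmra as W


@pytest.fixture(scope="session")
def small_phantom():
    return W.make_phantom((32, 32, 16), voxel_size=3.0, seed=11)


@pytest.fixture(scope="session")
def small_design():
    """Pattern + schedule for the 32x16 phase-encode grid, 48 windows."""
    pattern = W.generate_pattern(
        (32, 16), n_patterns=3, target_lines=48 * 15, seeds=(21, 22, 23)
    )
    schedule = W.build_schedule(pattern, nsegments=16, seed=0)
    return pattern, schedule


@pytest.fixture(scope="session")
def static_kspace(small_phantom, small_design):
    """Noiseless, motion-free acquisition of the small phantom."""
    _, schedule = small_design
    trace = W.BreathingTrace(
        times=np.arange(schedule.n_windows, dtype=float),
        displacement=np.zeros(schedule.n_windows),
        pattern="regular",
        seed=0,
        amplitude_mm=1.0,
    )
    return W.simulate_acquisition(
        small_phantom,
        W.FatSpectralModel(),
        trace,
        schedule,
        W.AcquisitionParams(noise_sigma=0.0),
        seed=3,
    )


@pytest.fixture(scope="session")
def moving_acquisition(small_phantom, small_design):
    """Sinusoidal 10 mm (peak-to-peak) motion at 20 dB SNR."""
    _, schedule = small_design
    n = schedule.n_windows
    t = np.arange(n, dtype=float)
    trace = W.BreathingTrace(
        times=t,
        displacement=5.0 * np.sin(2 * np.pi * t / 3.8),
        pattern="regular",
        seed=0,
        amplitude_mm=5.0,
    )
    kset = W.simulate_acquisition(
        small_phantom,
        W.FatSpectralModel(),
        trace,
        schedule,
        W.AcquisitionParams(noise_sigma=0.1),
        seed=7,
    )
    return kset, trace
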