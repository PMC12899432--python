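"""Shared fixtures: small synthetic recordings and an exhaustive matching oracle."""

from functools import lru_cache

import numpy as np
import pytest

from stepkit import ImuRecording, SyntheticSpec, simulate

FS = 100.0


def make_recording(z_dyn, fs=FS, gyro=None, t0=0.0):
    """Recording with the dynamic signal on the gravity axis (x = y = 0)."""
    z = np.asarray(z_dyn, dtype=float)
    n = z.size
    accel = np.zeros((3, n))
    accel[2] = 9.81 + z
    t = t0 + np.arange(n) / fs
    return ImuRecording(timestamps=t, accel=accel, gyro=gyro, sampling_rate=fs)


def sinusoid_recording(freq_hz, duration_s, amplitude=2.0, fs=FS, phase=0.0):
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    return make_recording(amplitude * np.sin(2 * np.pi * freq_hz * t + phase), fs=fs)


def brute_force_matching(detected, reference, tol):
    """Maximum-cardinality one-to-one matching by exhaustive bitmask search.

    Independent of the greedy implementation: for every reference event try
    every compatible unmatched detection (or skipping), memoized on the
    remaining-detections bitmask.  Practical for up to ~10 events per side.
    """
    d = list(detected)
    r = list(reference)

    @lru_cache(maxsize=None)
    def best(j, mask):
        if j == len(r):
            return 0
        out = best(j + 1, mask)  # leave reference j unmatched
        for i in range(len(d)):
            if not mask & (1 << i) and abs(d[i] - r[j]) <= tol:
                out = max(out, 1 + best(j + 1, mask | (1 << i)))
        return out

    result = best(0, 0)
    best.cache_clear()
    return result


@pytest.fixture(scope="session")
def noiseless_walk():
    """A clean 30 s ankle walk at 1.6 Hz with ground truth."""
    return simulate(
        SyntheticSpec(
            scenario="natural_walk",
            mounting="ankle",
            duration_s=30.0,
            cadence_hz=1.6,
            noise_sd=0.0,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def noisy_walk():
    """A realistic 30 s upper-arm walk (noise SD 0.1 m/s^2)."""
    return simulate(
        SyntheticSpec(
            scenario="natural_walk",
            mounting="upper_arm",
            duration_s=30.0,
            cadence_hz=1.6,
            noise_sd=0.1,
            seed=21,
        )
    )


@pytest.fixture(scope="session")
def stationary_quiet():
    """Noiseless stationary recording: gravity only, empty ground truth."""
    return simulate(
        SyntheticSpec(scenario="stationary", duration_s=30.0, noise_sd=0.0, seed=11)
    )
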