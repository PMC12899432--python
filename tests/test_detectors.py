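"""Detector behavior: worked examples, invariants, and cross-detector properties."""

import numpy as np
import pytest

from stepkit import (
    DETECTORS,
    ImuRecording,
    PeakParams,
    ShoeParams,
    SyntheticSpec,
    ZeroCrossingParams,
    detect,
    detect_adaptive,
    detect_peaks,
    detect_shoe,
    detect_spectral,
    detect_stance_phases,
    detect_zero_crossing,
    match_steps,
    simulate,
)

from conftest import FS, make_recording, sinusoid_recording


def bump_train(step_times, amplitudes, duration_s, width_s=0.3, fs=FS):
    """Smooth raised-cosine bumps at given times — a clean impulse-train stand-in."""
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    z = np.zeros(n)
    for tc, amp in zip(step_times, amplitudes):
        sel = np.abs(t - tc) < width_s / 2
        z[sel] += amp * np.cos(np.pi * (t[sel] - tc) / width_s) ** 2
    return make_recording(z, fs=fs)


# ---------------------------------------------------------------------------
# Peak Detection
# ---------------------------------------------------------------------------


class TestPeakDetection:
    def test_constant_signal_yields_no_steps(self):
        rec = make_recording(np.zeros(1000))
        assert detect_peaks(rec).count == 0

    def test_counts_simulated_heel_strikes(self):
        """60 s of noiseless ankle gait at 1.5 Hz carries exactly 90 strikes."""
        rec, truth = simulate(
            SyntheticSpec(
                scenario="natural_walk",
                mounting="ankle",
                duration_s=60.0,
                cadence_hz=1.5,
                noise_sd=0.0,
                seed=0,
            )
        )
        assert truth.step_times.size == 90
        assert detect_peaks(rec).count == 90

    def test_refractory_interval_merges_close_peaks(self):
        rec = bump_train([5.0, 5.2], [2.0, 2.0], duration_s=10.0, width_s=0.15)
        result = detect_peaks(rec, PeakParams(min_step_interval_s=0.35))
        assert result.count == 1

    def test_missing_window_height(self):
        # peaks below the rolling-SD-scaled threshold must be rejected:
        # with multiplier large enough nothing survives
        rec = bump_train(np.arange(1.0, 29.0), np.ones(28), duration_s=30.0)
        assert detect_peaks(rec, PeakParams(threshold_multiplier=50.0)).count == 0


# ---------------------------------------------------------------------------
# Zero-Crossing
# ---------------------------------------------------------------------------


class TestZeroCrossing:
    def test_constant_signal_yields_no_steps(self):
        rec = make_recording(np.zeros(1000))
        assert detect_zero_crossing(rec).count == 0

    def test_one_step_per_full_hysteresis_cycle(self):
        rec = sinusoid_recording(1.0, 10.0, amplitude=1.0)
        assert detect_zero_crossing(rec).count == 10

    def test_subthreshold_oscillation_ignored(self):
        rec = sinusoid_recording(1.0, 10.0, amplitude=0.2)
        assert detect_zero_crossing(rec, ZeroCrossingParams(hysteresis_band=0.3)).count == 0

    def test_step_time_at_downward_zero_crossing(self):
        # sin(2*pi*t) crosses zero downward at t = 0.5, 1.5, ...
        rec = sinusoid_recording(1.0, 10.0, amplitude=1.0)
        times = detect_zero_crossing(rec).step_times
        np.testing.assert_allclose(times, 0.5 + np.arange(10), atol=0.03)


# ---------------------------------------------------------------------------
# Spectral Analysis
# ---------------------------------------------------------------------------


class TestSpectral:
    def test_worked_example_22_steps(self):
        """A 20 s recording dominated by 1.1 Hz gait frequency counts 22 steps."""
        rec = sinusoid_recording(1.1, 20.0)
        result = detect_spectral(rec)
        assert result.count == 22

    def test_constant_signal_warns_and_counts_zero(self):
        rec = make_recording(np.zeros(2000))
        result = detect_spectral(rec)
        assert result.count == 0
        assert any("in-band" in w for w in result.warnings)

    @pytest.mark.parametrize("freq", [0.9, 1.1, 1.3, 1.5, 1.7, 1.9, 2.0])
    @pytest.mark.parametrize("duration", [30.0, 60.0])
    def test_closed_form_count(self, freq, duration):
        """For a pure in-band sinusoid, count = round(f * T) exactly."""
        rec = sinusoid_recording(freq, duration)
        assert detect_spectral(rec).count == round(freq * duration)

    def test_short_recording_single_window_flagged(self):
        rec = sinusoid_recording(1.5, 5.0)
        result = detect_spectral(rec)
        assert any("single full-length window" in w for w in result.warnings)
        assert result.count == round(1.5 * 5.0)

    def test_uniform_placement_midpoints(self):
        rec = sinusoid_recording(1.5, 20.0)
        result = detect_spectral(rec)
        expected = (np.arange(result.count) + 0.5) * 20.0 / result.count
        np.testing.assert_allclose(result.step_times, expected, atol=1e-9)

    def test_reports_window_length_in_samples(self):
        rec = sinusoid_recording(1.5, 20.0)
        assert detect_spectral(rec).params_used["window_samples"] == 800


# ---------------------------------------------------------------------------
# Adaptive Threshold
# ---------------------------------------------------------------------------


class TestAdaptive:
    def test_constant_signal_yields_no_steps(self):
        rec = make_recording(np.zeros(1000))
        assert detect_adaptive(rec).count == 0

    def test_alternating_amplitudes_keep_only_large(self):
        """Amplitudes alternate 1.0/0.2: the mean-amplitude threshold (mean x 0.5)
        sits between the two classes, so only the large peaks survive."""
        times = np.arange(1.0, 29.0, 2.0)
        amps = np.where(np.arange(times.size) % 2 == 0, 1.0, 0.2)
        rec = bump_train(times, amps, duration_s=30.0, width_s=0.5)
        result = detect_adaptive(rec)
        # independent oracle: apply the amplitude filter by hand on the
        # preprocessed signal
        from scipy.signal import find_peaks

        from stepkit import preprocess

        x = preprocess(rec, 0.5)
        idx, _ = find_peaks(x)
        half = 40  # 0.8 s window at 100 Hz
        hand = np.array(
            [x[i] - x[max(i - half, 0) : i + half + 1].min() for i in idx]
        )
        keep = hand >= hand[hand >= 1e-6].mean() * 0.5
        expected_times = rec.timestamps[idx[keep & (hand >= 1e-6)]]
        np.testing.assert_allclose(np.sort(result.step_times), expected_times, atol=1e-9)
        # and the hand filter retains exactly the large-amplitude class
        np.testing.assert_allclose(expected_times, times[amps == 1.0], atol=0.06)

    def test_uniform_train_keeps_all(self):
        times = np.arange(1.0, 29.0, 1.0)
        rec = bump_train(times, np.ones(times.size), duration_s=30.0)
        assert detect_adaptive(rec).count == times.size


# ---------------------------------------------------------------------------
# SHOE
# ---------------------------------------------------------------------------


class TestShoe:
    def test_stationary_recording_is_stance_throughout(self):
        n = 2000
        gyro = np.zeros((3, n))
        rec = make_recording(np.zeros(n), gyro=gyro)
        result = detect_shoe(rec)
        assert result.count == 0
        assert not result.warnings  # stance path, not fallback
        phases = detect_stance_phases(rec)
        assert len(phases) == 1  # one uninterrupted stance phase

    def test_counts_stance_entries_of_alternating_gait(self):
        """30 s of 1 Hz stance/swing alternation has exactly 30 stance entries."""
        rec, truth = simulate(
            SyntheticSpec(
                scenario="natural_walk",
                mounting="ankle",
                duration_s=30.0,
                cadence_hz=1.0,
                noise_sd=0.0,
                seed=3,
            )
        )
        assert truth.step_times.size == 30
        result = detect_shoe(rec)
        assert result.count == 30
        assert not any("fallback" in w for w in result.warnings)

    def test_no_stance_window_triggers_fallback(self):
        # fast large oscillation everywhere: variance never settles
        n = 3000
        t = np.arange(n) / FS
        rng = np.random.default_rng(0)
        z = 3.0 * np.sin(2 * np.pi * 4.0 * t)
        gyro = rng.normal(150.0, 60.0, size=(3, n))
        rec = make_recording(z, gyro=gyro)
        result = detect_shoe(rec)
        assert any("fallback" in w for w in result.warnings)

    def test_missing_gyro_uses_acceleration_only_fallback(self):
        rec = sinusoid_recording(1.5, 20.0)
        result = detect_shoe(rec)
        assert any("no gyroscope" in w for w in result.warnings)
        assert any("fallback" in w for w in result.warnings)

    def test_scale_invariance_of_channels(self):
        """Min-max normalization makes SHOE invariant to positive rescaling."""
        rec, _ = simulate(
            SyntheticSpec(
                scenario="natural_walk",
                mounting="ankle",
                duration_s=20.0,
                cadence_hz=1.6,
                noise_sd=0.0,
                seed=5,
            )
        )
        base = detect_shoe(rec).step_times
        scaled = ImuRecording(
            timestamps=rec.timestamps,
            accel=rec.accel * 3.7,
            gyro=rec.gyro * 0.4,
            sampling_rate=rec.sampling_rate,
        )
        np.testing.assert_allclose(detect_shoe(scaled).step_times, base, atol=1e-9)

    def test_stance_phases_ordered_nonoverlapping(self):
        rec, _ = simulate(
            SyntheticSpec(
                scenario="natural_walk",
                mounting="ankle",
                duration_s=20.0,
                cadence_hz=1.3,
                noise_sd=0.0,
                seed=5,
            )
        )
        phases = detect_stance_phases(rec)
        assert phases
        for p in phases:
            assert p.start_s < p.end_s
        for a, b in zip(phases[:-1], phases[1:]):
            assert a.end_s < b.start_s


# ---------------------------------------------------------------------------
# cross-detector invariants
# ---------------------------------------------------------------------------

ALL_ALGORITHMS = sorted(DETECTORS)


@pytest.mark.parametrize("algorithm", ALL_ALGORITHMS)
def test_output_contract(algorithm, noisy_walk):
    """Sorted, unique, in-span step times; spacing respects the minimum interval."""
    rec, _ = noisy_walk
    result = detect(rec, algorithm)
    times = result.step_times
    assert np.all(np.diff(times) > 0)
    if times.size:
        assert times[0] >= rec.t_start and times[-1] <= rec.t_end
    min_int = result.params_used.get("min_step_interval_s")
    if algorithm != "spectral" and times.size > 1:
        assert np.diff(times).min() >= min_int - 1e-9


@pytest.mark.parametrize("algorithm", ALL_ALGORITHMS)
def test_time_shift_equivariance(algorithm, noisy_walk):
    """Shifting all timestamps by delta shifts every detection by delta."""
    rec, _ = noisy_walk
    delta = 123.456
    shifted = ImuRecording(
        timestamps=rec.timestamps + delta,
        accel=rec.accel,
        gyro=rec.gyro,
        sampling_rate=rec.sampling_rate,
    )
    base = detect(rec, algorithm).step_times
    moved = detect(shifted, algorithm).step_times
    np.testing.assert_allclose(moved, base + delta, atol=1e-6)


def test_cadence_ceiling_under_min_distance():
    """With min peak distance d, a 60 s recording yields at most 60/d steps."""
    n = int(60 * FS)
    t = np.arange(n) / FS
    rec = make_recording(3.0 * np.sin(2 * np.pi * 5.0 * t))
    d = 0.3
    result = detect_peaks(rec, PeakParams(min_step_interval_s=d))
    assert result.count <= 60.0 / d


@pytest.mark.parametrize("algorithm", ALL_ALGORITHMS)
def test_all_detectors_silent_on_quiet_recording(algorithm, stationary_quiet):
    rec, _ = stationary_quiet
    assert detect(rec, algorithm).count == 0


def test_unknown_algorithm_rejected(noisy_walk):
    rec, _ = noisy_walk
    with pytest.raises(Exception):
        detect(rec, "nonsense")
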