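"""Five IMU step-detection algorithms.

All detectors map an :class:`~stepkit.core.ImuRecording` plus a parameter
record to a :class:`~stepkit.core.StepDetectionResult` and are fully
deterministic.  They share the preprocessing chain of :mod:`stepkit.core`
(magnitude, Savitzky–Golay smoothing, median gravity removal) but differ
fundamentally in strategy:

``detect_peaks``
    Local maxima above a point-wise adaptive threshold (rolling SD x
    multiplier), with minimum spacing and prominence constraints.
``detect_zero_crossing``
    Hysteresis cycles of the median-centred signal: a step is one excursion
    above the positive band followed by one below the negative band.
``detect_spectral``
    STFT cadence estimation: the median in-band dominant frequency times the
    recording duration gives the count; step times are spread uniformly.
``detect_adaptive``
    Two-phase amplitude thresholding: all local maxima are candidates, then
    only those whose peak-to-local-minimum amplitude exceeds a sensitivity
    fraction of the mean amplitude are kept.
``detect_shoe``
    Stance-phase detection on a weighted accel+gyro combined signal, with a
    peak-detection fallback when no stance windows exist (typical for sensors
    not worn on the foot).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, spectrogram

from .core import (
    AdaptiveParams,
    ImuRecording,
    PeakParams,
    ShoeParams,
    SpectralParams,
    StepDetectionResult,
    ValidationError,
    ZeroCrossingParams,
    magnitude,
    preprocess,
    remove_gravity,
    smooth,
)

__all__ = [
    "StancePhase",
    "detect_peaks",
    "detect_zero_crossing",
    "detect_spectral",
    "detect_adaptive",
    "detect_shoe",
    "detect_stance_phases",
    "detect",
    "DETECTORS",
]


@dataclass
class StancePhase:
    """One contiguous stance interval found by the SHOE detector."""

    start_s: float
    end_s: float
    mean_combined: float


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _rolling_sd(x: np.ndarray, window_samples: int) -> np.ndarray:
    """Centred rolling standard deviation; the window shrinks at the edges."""
    s = pd.Series(x)
    return (
        s.rolling(window=max(window_samples, 1), center=True, min_periods=1)
        .std(ddof=0)
        .to_numpy()
    )


def _rolling_mean(x: np.ndarray, window_samples: int) -> np.ndarray:
    s = pd.Series(x)
    return (
        s.rolling(window=max(window_samples, 1), center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def _rolling_var(x: np.ndarray, window_samples: int) -> np.ndarray:
    s = pd.Series(x)
    return (
        s.rolling(window=max(window_samples, 1), center=True, min_periods=1)
        .var(ddof=0)
        .to_numpy()
    )


def _adaptive_peak_pick(
    x: np.ndarray,
    fs: float,
    min_step_interval_s: float,
    rolling_sd_window_s: float,
    threshold_multiplier: float,
    prominence: float,
) -> np.ndarray:
    """Shared peak-picking core: rolling-SD height threshold, distance, prominence."""
    thr = _rolling_sd(x, int(round(rolling_sd_window_s * fs))) * threshold_multiplier
    distance = max(int(round(min_step_interval_s * fs)), 1)
    idx, _ = find_peaks(x, height=thr, distance=distance, prominence=prominence)
    return idx


def _thin_sequential(times: np.ndarray, min_interval: float) -> np.ndarray:
    """Keep the first event of each run closer than ``min_interval``."""
    if times.size == 0:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= min_interval:
            kept.append(t)
    return np.asarray(kept)


def _result(times, algorithm, params, warnings, extra_params=None) -> StepDetectionResult:
    used = asdict(params)
    if extra_params:
        used.update(extra_params)
    return StepDetectionResult(
        step_times=np.asarray(times, dtype=float),
        algorithm=algorithm,
        params_used=used,
        warnings=list(warnings),
    )


# ---------------------------------------------------------------------------
# Peak Detection
# ---------------------------------------------------------------------------


def detect_peaks(rec: ImuRecording, params: Optional[PeakParams] = None) -> StepDetectionResult:
    """Detect steps as local maxima above a rolling-SD adaptive threshold.

    Each heel strike produces a characteristic peak in the preprocessed
    acceleration magnitude.  The height threshold adapts point-wise: it is the
    product of a centred rolling standard deviation (window
    ``rolling_sd_window_s``, shrunk at the edges) and
    ``threshold_multiplier``, so quiet recordings yield no detections without
    manual calibration.  Peaks must additionally be separated by
    ``min_step_interval_s`` and have the configured prominence.
    """
    p = params or PeakParams()
    x = preprocess(rec, p.smooth_window_s)
    idx = _adaptive_peak_pick(
        x,
        rec.sampling_rate,
        p.min_step_interval_s,
        p.rolling_sd_window_s,
        p.threshold_multiplier,
        p.prominence,
    )
    return _result(rec.timestamps[idx], "peak", p, [])


# ---------------------------------------------------------------------------
# Zero-Crossing
# ---------------------------------------------------------------------------


def detect_zero_crossing(
    rec: ImuRecording, params: Optional[ZeroCrossingParams] = None
) -> StepDetectionResult:
    """Detect steps as completed hysteresis cycles of the centred signal.

    A step is registered once the signal has risen above ``+hysteresis_band``
    and subsequently fallen below ``-hysteresis_band``; the step timestamp is
    the negative-going zero crossing between the two excursions (linearly
    interpolated between samples).  Detections closer than
    ``min_step_interval_s`` to the previous one are suppressed, but the cycle
    state machine keeps running so a suppressed cycle does not desynchronize
    later ones.
    """
    p = params or ZeroCrossingParams()
    x = preprocess(rec, p.smooth_window_s)
    t = rec.timestamps
    band = p.hysteresis_band

    steps: list[float] = []
    armed = False
    cross_time: Optional[float] = None
    last_step = -math.inf
    for i in range(x.size):
        if not armed:
            if x[i] >= band:
                armed = True
                cross_time = None
        else:
            if cross_time is None and i > 0 and x[i - 1] >= 0.0 > x[i]:
                # sub-sample zero crossing by linear interpolation
                frac = x[i - 1] / (x[i - 1] - x[i])
                cross_time = float(t[i - 1] + frac * (t[i] - t[i - 1]))
            if x[i] <= -band:
                tc = cross_time if cross_time is not None else float(t[i])
                if tc - last_step >= p.min_step_interval_s:
                    steps.append(tc)
                    last_step = tc
                armed = False
                cross_time = None
    return _result(steps, "zero_crossing", p, [])


# ---------------------------------------------------------------------------
# Spectral Analysis
# ---------------------------------------------------------------------------


def _interp_peak_freq(freqs: np.ndarray, power: np.ndarray, i: int) -> float:
    """Parabolic interpolation of the spectral peak around bin ``i``.

    Fitting a parabola to the log-power of the three bins around the argmax
    refines the dominant-frequency estimate well below the FFT bin width,
    which matters because the step count is the product of this frequency and
    the full recording duration.
    """
    if i <= 0 or i >= power.size - 1:
        return float(freqs[i])
    tiny = 1e-300
    a = math.log(power[i - 1] + tiny)
    b = math.log(power[i] + tiny)
    c = math.log(power[i + 1] + tiny)
    denom = a - 2.0 * b + c
    if denom >= 0 or not math.isfinite(denom):
        return float(freqs[i])
    delta = 0.5 * (a - c) / denom
    delta = max(-0.5, min(0.5, delta))
    return float(freqs[i] + delta * (freqs[1] - freqs[0]))


def detect_spectral(
    rec: ImuRecording, params: Optional[SpectralParams] = None
) -> StepDetectionResult:
    """Estimate cadence from the STFT and distribute steps uniformly.

    Overlapping Hann windows of ``window_s`` (hop = ``window_s * (1 -
    overlap)``) give per-window power spectra; each window's dominant
    frequency is the in-band power argmax refined by parabolic interpolation.
    The cadence is the median dominant frequency over windows with in-band
    power; ``count = round(cadence * duration)`` (half away from zero) and the
    step times are the midpoints of ``count`` equal bins.  A recording shorter
    than the analysis window is analysed as a single full-length window, and
    a recording with no in-band power yields zero steps — both flagged in
    ``warnings``.
    """
    p = params or SpectralParams()
    fs = rec.sampling_rate
    x = preprocess(rec, p.smooth_window_s)
    warnings: list[str] = []

    nperseg = int(round(p.window_s * fs))
    if nperseg > x.size:
        nperseg = x.size
        warnings.append(
            "recording shorter than the analysis window; using a single full-length window"
        )
    nperseg = max(nperseg, 8)
    noverlap = min(int(math.floor(nperseg * p.overlap)), nperseg - 1)
    freqs, _, sxx = spectrogram(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend=False,
        mode="psd",
    )

    lo, hi = p.freq_range
    in_band = (freqs >= lo) & (freqs <= hi)
    if not np.any(in_band):
        warnings.append("frequency band contains no FFT bins; no steps reported")
        return _result([], "spectral", p, warnings, {"window_samples": nperseg})
    band_idx = np.flatnonzero(in_band)

    dominants: list[float] = []
    for j in range(sxx.shape[1]):
        col = sxx[:, j]
        k = band_idx[int(np.argmax(col[band_idx]))]
        if col[k] <= p.in_band_power_floor:
            continue  # window has no gait content
        f_hat = _interp_peak_freq(freqs, col, int(k))
        dominants.append(min(max(f_hat, lo), hi))

    duration = rec.duration
    if not dominants:
        warnings.append("no analysis window had in-band power; step count set to 0")
        return _result([], "spectral", p, warnings, {"window_samples": nperseg})

    cadence = float(np.median(dominants))
    count = int(math.floor(cadence * duration + 0.5))  # round half away from zero
    if count <= 0:
        return _result([], "spectral", p, warnings, {"window_samples": nperseg})
    t0 = rec.t_start
    times = t0 + (np.arange(count) + 0.5) * duration / count
    times = np.clip(times, rec.t_start, rec.t_end)
    # clipping can only collide at pathologically short recordings
    times = np.unique(times)
    return _result(
        times,
        "spectral",
        p,
        warnings,
        {"window_samples": nperseg, "cadence_hz": cadence},
    )


# ---------------------------------------------------------------------------
# Adaptive Threshold
# ---------------------------------------------------------------------------


def detect_adaptive(
    rec: ImuRecording, params: Optional[AdaptiveParams] = None
) -> StepDetectionResult:
    """Two-phase amplitude-threshold detection.

    Phase 1 collects *all* local maxima of the preprocessed magnitude.  Each
    candidate's amplitude is its height above the minimum within a centred
    window of ``amplitude_window_s``.  Phase 2 keeps candidates whose
    amplitude reaches ``sensitivity`` times the mean candidate amplitude, then
    thins conflicts closer than ``min_step_interval_s`` keeping the
    larger-amplitude peak (ties go to the earlier one).
    """
    p = params or AdaptiveParams()
    x = preprocess(rec, p.smooth_window_s)
    fs = rec.sampling_rate
    idx, _ = find_peaks(x)
    if idx.size == 0:
        return _result([], "adaptive", p, [])

    half = max(int(round(p.amplitude_window_s * fs / 2)), 1)
    amps = np.empty(idx.size)
    for k, i in enumerate(idx):
        lo = max(i - half, 0)
        hi = min(i + half + 1, x.size)
        amps[k] = x[i] - x[lo:hi].min()
    real = amps >= p.amplitude_floor
    idx, amps = idx[real], amps[real]
    if idx.size == 0:
        return _result([], "adaptive", p, [])
    threshold = amps.mean() * p.sensitivity
    keep = amps >= threshold
    cand_idx = idx[keep]
    cand_amp = amps[keep]

    # thinning: greedy by descending amplitude, earlier peak wins ties
    order = np.lexsort((cand_idx, -cand_amp))
    t = rec.timestamps
    accepted: list[int] = []
    for k in order:
        i = cand_idx[k]
        if all(abs(t[i] - t[j]) >= p.min_step_interval_s for j in accepted):
            accepted.append(i)
    accepted.sort()
    return _result(
        t[np.asarray(accepted, dtype=int)] if accepted else [],
        "adaptive",
        p,
        [],
        {"amplitude_threshold": float(threshold)},
    )


# ---------------------------------------------------------------------------
# SHOE
# ---------------------------------------------------------------------------


def _minmax(x: np.ndarray) -> np.ndarray:
    rng = x.max() - x.min()
    if rng <= 1e-12:
        return np.zeros_like(x)
    return (x - x.min()) / rng


def _shoe_signals(rec: ImuRecording, p: ShoeParams):
    fs = rec.sampling_rate
    a_n = _minmax(smooth(magnitude(rec.accel), p.smooth_window_s, fs))
    if rec.gyro is None:
        return a_n, None, a_n
    g_n = _minmax(smooth(magnitude(rec.gyro), p.smooth_window_s, fs))
    combined = p.accel_weight * a_n + p.gyro_weight * g_n
    return a_n, g_n, combined


def _stance_mask(combined: np.ndarray, g_n: np.ndarray, fs: float, p: ShoeParams):
    win = max(int(round(p.stance_window_s * fs)), 2)
    stat = p.var_scale * _rolling_var(combined, win) + p.gyro_scale * _rolling_mean(
        g_n, win
    )
    return stat < p.threshold, stat


def detect_stance_phases(
    rec: ImuRecording, params: Optional[ShoeParams] = None
) -> list[StancePhase]:
    """Contiguous stance intervals of the SHOE stance statistic.

    Requires a gyroscope channel; returns an empty list when none is present
    (the detector then uses its fallback path instead).
    """
    p = params or ShoeParams()
    if rec.gyro is None:
        return []
    _, g_n, combined = _shoe_signals(rec, p)
    mask, _ = _stance_mask(combined, g_n, rec.sampling_rate, p)
    t = rec.timestamps
    phases: list[StancePhase] = []
    i = 0
    n = mask.size
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            phases.append(
                StancePhase(
                    start_s=float(t[i]),
                    end_s=float(t[j]),
                    mean_combined=float(combined[i : j + 1].mean()),
                )
            )
            i = j + 1
        else:
            i += 1
    return phases


def detect_shoe(rec: ImuRecording, params: Optional[ShoeParams] = None) -> StepDetectionResult:
    """Stance-phase step detection fusing accelerometer and gyroscope.

    Both magnitudes are smoothed and min–max normalized to [0, 1]; the
    combined signal is their 70/30 weighted sum.  Sliding windows are
    classified as stance when the stance statistic (see
    :class:`~stepkit.core.ShoeParams`) is below the threshold, and one step is
    registered at each transition from non-stance into stance (stance onset),
    thinned to the minimum step interval.

    Fallback: when the recording has no gyroscope, or no stance window is
    found (common for wrist/arm/thigh mounting, where the sensor never comes
    to rest), peak detection is applied to the combined signal and the result
    is flagged with a ``"fallback"`` warning.
    """
    p = params or ShoeParams()
    fs = rec.sampling_rate
    warnings: list[str] = []

    a_n, g_n, combined = _shoe_signals(rec, p)
    if g_n is None:
        warnings.append("no gyroscope channel; combined signal is normalized acceleration")
        warnings.append("fallback: peak detection on combined signal")
        idx = _adaptive_peak_pick(
            remove_gravity(combined), fs, p.min_step_interval_s, 2.0, 0.5, 0.05
        )
        return _result(rec.timestamps[idx], "shoe", p, warnings)

    mask, _ = _stance_mask(combined, g_n, fs, p)
    if not mask.any():
        warnings.append("fallback: no stance windows found; peak detection on combined signal")
        idx = _adaptive_peak_pick(
            remove_gravity(combined), fs, p.min_step_interval_s, 2.0, 0.5, 0.05
        )
        return _result(rec.timestamps[idx], "shoe", p, warnings)

    entries = np.flatnonzero(mask[1:] & ~mask[:-1]) + 1
    times = _thin_sequential(rec.timestamps[entries], p.min_step_interval_s)
    return _result(times, "shoe", p, warnings)


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

DETECTORS = {
    "peak": (detect_peaks, PeakParams),
    "zero_crossing": (detect_zero_crossing, ZeroCrossingParams),
    "spectral": (detect_spectral, SpectralParams),
    "adaptive": (detect_adaptive, AdaptiveParams),
    "shoe": (detect_shoe, ShoeParams),
}


def detect(rec: ImuRecording, algorithm: str, params=None) -> StepDetectionResult:
    """Run one detector by name (see :data:`DETECTORS` for valid names)."""
    try:
        fn, _ = DETECTORS[algorithm]
    except KeyError:
        raise ValidationError(
            f"unknown algorithm {algorithm!r}; expected one of {sorted(DETECTORS)}"
        ) from None
    return fn(rec, params)
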