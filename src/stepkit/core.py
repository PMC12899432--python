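"""Shared domain types and the signal-preprocessing chain.

Every detector in :mod:`stepkit.detectors` consumes the same three-stage
preprocessing of the raw accelerometer data:

1. **Magnitude** — the three-axis acceleration vector is collapsed to its
   Euclidean norm, giving an orientation-independent scalar signal.
2. **Smoothing** — a Savitzky–Golay filter removes high-frequency noise while
   preserving the amplitude and location of gait peaks (the reason this filter
   is preferred over a plain low-pass).
3. **Gravity compensation** — the *median* of the signal is subtracted to
   isolate the dynamic component.  The median is more robust than the mean to
   the transient high-amplitude events that steps themselves produce.

Units are standardized throughout the package: acceleration in m/s^2
(gravity included in the raw channels), angular rate in deg/s, time in
seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "STANDARD_GRAVITY",
    "ValidationError",
    "SchemaError",
    "MappingError",
    "ImuRecording",
    "StepDetectionResult",
    "GroundTruth",
    "PeakParams",
    "ZeroCrossingParams",
    "SpectralParams",
    "AdaptiveParams",
    "ShoeParams",
    "magnitude",
    "remove_gravity",
    "smooth",
    "preprocess",
]

#: Conventional standard gravity, used when converting accelerometer
#: readings declared in units of g.
STANDARD_GRAVITY = 9.80665


class ValidationError(ValueError):
    """Input violates a documented precondition or invariant."""


class SchemaError(ValidationError):
    """A CSV file does not conform to the expected column schema."""


class MappingError(ValidationError):
    """A column mapping is incomplete or declares unsupported units."""


def _as_2d_channels(arr, name: str) -> np.ndarray:
    a = np.asarray(arr, dtype=float)
    if a.ndim != 2 or a.shape[0] != 3:
        raise ValidationError(f"{name} must have shape (3, N), got {a.shape}")
    return a


@dataclass
class ImuRecording:
    """A uniformly sampled multi-axis inertial time series.

    Parameters
    ----------
    timestamps : ndarray, shape (N,)
        Sample times in seconds, monotone increasing and near-uniform.
    accel : ndarray, shape (3, N)
        Accelerometer channels in m/s^2, gravity included.
    gyro : ndarray, shape (3, N), optional
        Gyroscope channels in deg/s.
    mag : ndarray, shape (3, N), optional
        Magnetometer channels (carried through I/O, unused by detectors).
    sampling_rate : float
        Nominal sampling rate in Hz.  The median inter-sample interval must
        agree with ``1/sampling_rate`` to within 5 %.
    meta : dict
        Free-form metadata (sensor id, mounting location, scenario label).
    """

    timestamps: np.ndarray
    accel: np.ndarray
    gyro: Optional[np.ndarray] = None
    mag: Optional[np.ndarray] = None
    sampling_rate: float = 100.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.timestamps.ndim != 1 or self.timestamps.size < 1:
            raise ValidationError("timestamps must be a non-empty 1-D array")
        self.accel = _as_2d_channels(self.accel, "accel")
        n = self.timestamps.size
        if self.accel.shape[1] != n:
            raise ValidationError(
                f"accel has {self.accel.shape[1]} samples, timestamps have {n}"
            )
        for name in ("gyro", "mag"):
            ch = getattr(self, name)
            if ch is not None:
                ch = _as_2d_channels(ch, name)
                if ch.shape[1] != n:
                    raise ValidationError(
                        f"{name} has {ch.shape[1]} samples, timestamps have {n}"
                    )
                if not np.all(np.isfinite(ch)):
                    raise ValidationError(f"{name} contains non-finite values")
                setattr(self, name, ch)
        if not np.all(np.isfinite(self.timestamps)):
            raise ValidationError("timestamps contain non-finite values")
        if not np.all(np.isfinite(self.accel)):
            raise ValidationError("accel contains non-finite values")
        if n > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValidationError("timestamps must be strictly increasing")
        if not self.sampling_rate > 0:
            raise ValidationError("sampling_rate must be positive")
        if n > 1:
            med_dt = float(np.median(np.diff(self.timestamps)))
            nominal = 1.0 / self.sampling_rate
            if abs(med_dt - nominal) > 0.05 * nominal:
                raise ValidationError(
                    f"median sample interval {med_dt:.6g}s deviates more than "
                    f"5% from nominal {nominal:.6g}s"
                )

    @property
    def n_samples(self) -> int:
        return int(self.timestamps.size)

    @property
    def duration(self) -> float:
        """Recording length in seconds (sample count over sampling rate)."""
        return self.n_samples / self.sampling_rate

    @property
    def t_start(self) -> float:
        return float(self.timestamps[0])

    @property
    def t_end(self) -> float:
        return float(self.timestamps[-1])


@dataclass
class StepDetectionResult:
    """Ordered detected step times with provenance.

    ``step_times`` are strictly increasing and lie inside the recording span.
    ``count`` always equals ``len(step_times)``.
    """

    step_times: np.ndarray
    algorithm: str
    params_used: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    count: int = field(init=False)

    def __post_init__(self) -> None:
        self.step_times = np.asarray(self.step_times, dtype=float)
        if self.step_times.size > 1 and np.any(np.diff(self.step_times) <= 0):
            raise ValidationError("step_times must be strictly increasing")
        self.count = int(self.step_times.size)


@dataclass
class GroundTruth:
    """Annotated reference step times for one recording."""

    step_times: np.ndarray
    source: str = "manual_annotation"

    def __post_init__(self) -> None:
        self.step_times = np.asarray(self.step_times, dtype=float)
        if not np.all(np.isfinite(self.step_times)):
            raise ValidationError("ground-truth step times must be finite")
        if self.step_times.size > 1 and np.any(np.diff(self.step_times) <= 0):
            raise ValidationError("ground-truth step times must be strictly increasing")
        if self.source not in ("manual_annotation", "simulated"):
            raise ValidationError(f"unknown ground-truth source {self.source!r}")


# ---------------------------------------------------------------------------
# Detector parameter records (validation defaults)
# ---------------------------------------------------------------------------


def _require_positive(**kwargs) -> None:
    for k, v in kwargs.items():
        if not v > 0:
            raise ValidationError(f"{k} must be positive, got {v}")


@dataclass
class PeakParams:
    """Peak Detection parameters.

    The adaptive height threshold is the point-wise product of a rolling
    standard deviation (``rolling_sd_window_s`` wide) and
    ``threshold_multiplier``.
    """

    smooth_window_s: float = 0.6
    threshold_multiplier: float = 0.5
    min_step_interval_s: float = 0.35
    rolling_sd_window_s: float = 2.0
    prominence: float = 0.2

    def __post_init__(self) -> None:
        _require_positive(
            smooth_window_s=self.smooth_window_s,
            threshold_multiplier=self.threshold_multiplier,
            min_step_interval_s=self.min_step_interval_s,
            rolling_sd_window_s=self.rolling_sd_window_s,
        )


@dataclass
class ZeroCrossingParams:
    """Zero-Crossing parameters; ``hysteresis_band`` is in m/s^2."""

    smooth_window_s: float = 0.5
    min_step_interval_s: float = 0.4
    hysteresis_band: float = 0.3

    def __post_init__(self) -> None:
        _require_positive(
            smooth_window_s=self.smooth_window_s,
            min_step_interval_s=self.min_step_interval_s,
            hysteresis_band=self.hysteresis_band,
        )


@dataclass
class SpectralParams:
    """Spectral Analysis (STFT cadence estimation) parameters.

    ``freq_range`` bounds the physiological gait band in Hz; the dominant
    frequency search is restricted to it.  ``in_band_power_floor`` is the
    absolute spectral-power level below which a window is treated as having
    no gait content (guards against counting steps in numerically silent
    recordings).
    """

    window_s: float = 8.0
    overlap: float = 0.8
    freq_range: tuple = (0.8, 2.0)
    smooth_window_s: float = 0.5
    in_band_power_floor: float = 1e-12

    def __post_init__(self) -> None:
        _require_positive(window_s=self.window_s, smooth_window_s=self.smooth_window_s)
        if not 0 <= self.overlap < 1:
            raise ValidationError(f"overlap must be in [0, 1), got {self.overlap}")
        lo, hi = self.freq_range
        if not lo < hi:
            raise ValidationError(f"freq_range must satisfy lo < hi, got {self.freq_range}")


@dataclass
class AdaptiveParams:
    """Adaptive (amplitude) Threshold parameters.

    A candidate peak's amplitude is its height above the local minimum inside
    a centred window of ``amplitude_window_s``; the retention threshold is
    ``sensitivity`` times the mean candidate amplitude.  Candidates below
    ``amplitude_floor`` (m/s^2) are discarded outright so that numerically
    flat recordings do not promote rounding ripples into steps.
    """

    amplitude_window_s: float = 0.8
    sensitivity: float = 0.5
    min_step_interval_s: float = 0.4
    smooth_window_s: float = 0.5
    amplitude_floor: float = 1e-6

    def __post_init__(self) -> None:
        _require_positive(
            amplitude_window_s=self.amplitude_window_s,
            sensitivity=self.sensitivity,
            min_step_interval_s=self.min_step_interval_s,
            smooth_window_s=self.smooth_window_s,
        )


@dataclass
class ShoeParams:
    """SHOE (stance-phase) detector parameters.

    The combined signal is ``accel_weight``·(normalized accel magnitude) +
    ``gyro_weight``·(normalized gyro magnitude), each min–max scaled to
    [0, 1].  A sliding window is classified as stance when the statistic
    ``var_scale``·var(combined) + ``gyro_scale``·mean(normalized gyro) falls
    below ``threshold``.  The two scale factors map the (dimensionless)
    variance and mean onto the scale of the single printed threshold and are
    exposed because that mapping is a convention of this implementation.
    """

    stance_window_s: float = 0.3
    threshold: float = 9.0
    min_step_interval_s: float = 0.35
    accel_weight: float = 0.7
    gyro_weight: float = 0.3
    # shorter than the other detectors' smoothing: stance/swing contrast
    # lives at sub-gait-cycle timescales and must not be smeared away
    smooth_window_s: float = 0.2
    var_scale: float = 1000.0
    gyro_scale: float = 10.0

    def __post_init__(self) -> None:
        _require_positive(
            stance_window_s=self.stance_window_s,
            threshold=self.threshold,
            min_step_interval_s=self.min_step_interval_s,
            smooth_window_s=self.smooth_window_s,
        )
        if abs(self.accel_weight + self.gyro_weight - 1.0) > 1e-9:
            raise ValidationError("accel_weight + gyro_weight must equal 1")


# ---------------------------------------------------------------------------
# Preprocessing operations
# ---------------------------------------------------------------------------


def magnitude(accel) -> np.ndarray:
    """Element-wise Euclidean norm of a (3, N) acceleration array."""
    a = _as_2d_channels(accel, "accel")
    if not np.all(np.isfinite(a)):
        raise ValidationError("accel contains non-finite values")
    return np.sqrt(np.sum(a * a, axis=0))


def remove_gravity(signal) -> np.ndarray:
    """Subtract the median value, isolating the dynamic component."""
    x = np.asarray(signal, dtype=float)
    if x.size < 1:
        raise ValidationError("cannot remove gravity from an empty signal")
    return x - np.median(x)


def smooth(signal, window_s: float, rate: float, polyorder: int = 3) -> np.ndarray:
    """Savitzky–Golay smoothing with a window given in seconds.

    The window length in samples is ``round(window_s * rate)``, incremented by
    one if even (the filter requires an odd window).  Polynomial order
    defaults to 3, which preserves peak shape and location.
    """
    x = np.asarray(signal, dtype=float)
    _require_positive(window_s=window_s, rate=rate)
    win = int(round(window_s * rate))
    if win % 2 == 0:
        win += 1
    if win < polyorder + 2:
        raise ValidationError(
            f"smoothing window of {win} samples is shorter than polyorder+2 "
            f"({polyorder + 2})"
        )
    if win > x.size:
        # Short recordings: shrink the window to the largest odd length that
        # still fits; reject only if even that is too short.
        win = x.size if x.size % 2 == 1 else x.size - 1
        if win < polyorder + 2:
            raise ValidationError(
                f"signal of {x.size} samples is too short for order-{polyorder} smoothing"
            )
    return savgol_filter(x, window_length=win, polyorder=polyorder)


def preprocess(rec: ImuRecording, smooth_window_s: float) -> np.ndarray:
    """The shared chain: magnitude -> Savitzky–Golay smoothing -> median removal."""
    return remove_gravity(smooth(magnitude(rec.accel), smooth_window_s, rec.sampling_rate))
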