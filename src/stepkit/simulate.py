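"""Synthetic 9-axis gait-signal generator with ground truth.

The simulator emulates the signal morphologies a body-worn IMU produces at
different mounting sites during walking-type activities, so detectors and
metrics can be exercised end to end without any recorded data:

* **ankle** — a sharp biexponential impact transient at every heel strike
  riding on a swing oscillation at the cadence, plus strong swing-phase
  gyroscope bursts separated by quiet stance windows;
* **upper_arm** — smooth pendulum-like sinusoid locked to the cadence;
* **wrist** — the arm sinusoid plus sporadic gesture artifacts unrelated to
  stepping (part of the noise model: they appear only when ``noise_sd > 0``);
* **thigh** — attenuated impact transient plus sinusoid (pocket-carried
  phone morphology).

A gravity baseline of 9.81 m/s^2 sits on the z axis and the dominant dynamic
component is added along it, so the magnitude signal reflects the morphology
nearly linearly.  Step times are jittered around the cadence grid
(non-accumulating Gaussian jitter, SD = 2 % of the period, truncated at
10 %), and the exact generated heel-strike times are returned as ground
truth.  Stair descent uses larger impact amplitudes than ascent, jogging a
higher amplitude with shortened stance, and the TUG scenario strings
together sit - stand-up - walk - turn - walk - sit-down segments with ground
truth only inside the walking bouts.

All randomness flows from ``SyntheticSpec.seed``: the same spec always
produces bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import GroundTruth, ImuRecording, ValidationError

__all__ = [
    "SCENARIOS",
    "MOUNTINGS",
    "MORPHOLOGY",
    "SCENARIO_MODS",
    "TugSegments",
    "SyntheticSpec",
    "simulate",
    "simulate_walk",
    "simulate_tug",
    "simulate_stationary",
]

SCENARIOS = (
    "natural_walk",
    "fast_walk",
    "jog",
    "stairs_up",
    "stairs_down",
    "stairs_combined",
    "tug",
    "stationary",
)
MOUNTINGS = ("ankle", "wrist", "upper_arm", "thigh")

#: Per-mounting waveform parameters.  Amplitudes are in m/s^2 (accelerometer)
#: and deg/s (gyroscope); the sinusoid phase lead (radians) places the swing
#: oscillation peak slightly before the heel strike, as the limb decelerates
#: into ground contact.
MORPHOLOGY = {
    "ankle": dict(
        transient_amp=1.0,
        transient_rise_s=0.015,
        transient_decay_s=0.08,
        swing_amp=1.5,
        swing_phase_rad=0.35,
        gyro_amp=300.0,
    ),
    "thigh": dict(
        transient_amp=0.6,
        transient_rise_s=0.02,
        transient_decay_s=0.10,
        swing_amp=1.2,
        swing_phase_rad=0.25,
        gyro_amp=120.0,
    ),
    "upper_arm": dict(
        transient_amp=0.0,
        transient_rise_s=0.02,
        transient_decay_s=0.08,
        swing_amp=1.5,
        swing_phase_rad=0.0,
        gyro_amp=100.0,
    ),
    "wrist": dict(
        transient_amp=0.0,
        transient_rise_s=0.02,
        transient_decay_s=0.08,
        swing_amp=1.2,
        swing_phase_rad=0.0,
        gyro_amp=130.0,
        gesture_rate_hz=0.08,
        gesture_amp=1.0,
        gesture_width_s=0.35,
    ),
}

#: Per-scenario modifiers applied on top of the mounting morphology.
#: ``amp_scale`` multiplies all dynamic accelerometer amplitudes;
#: ``stance_frac`` is the fraction of the gait period spent in stance
#: (quiet gyroscope).  Stair descent is louder than ascent (gravitational
#: assistance); jogging is louder still with a shortened stance.
SCENARIO_MODS = {
    "natural_walk": dict(amp_scale=1.0, stance_frac=0.35),
    "fast_walk": dict(amp_scale=1.3, stance_frac=0.30),
    "jog": dict(amp_scale=2.0, stance_frac=0.20),
    "stairs_up": dict(amp_scale=0.85, stance_frac=0.40),
    "stairs_down": dict(amp_scale=1.35, stance_frac=0.35),
    "stairs_combined": dict(amp_scale=1.0, stance_frac=0.35),
}

GRAVITY = 9.81
JITTER_SD_FRAC = 0.02  # SD of step-time jitter, as a fraction of the period
JITTER_MAX_FRAC = 0.10  # truncation bound, keeps spacing >= 0.8 * period


@dataclass
class TugSegments:
    """Segment durations and bout size for the Timed Up and Go scenario."""

    sit_s: float = 2.0
    stand_s: float = 1.0
    turn_s: float = 1.5
    end_sit_s: float = 1.5
    steps_per_bout: int = 5


@dataclass
class SyntheticSpec:
    """Declarative description of one simulated recording.

    Defaults mirror the study conditions: 100 Hz sampling, 1.6 Hz cadence
    (the dominant gait frequency of normal walking), 60 s walking trials.
    ``noise_sd`` is the white accelerometer noise SD in m/s^2.
    """

    scenario: str = "natural_walk"
    mounting: str = "ankle"
    duration_s: float = 60.0
    cadence_hz: float = 1.6
    noise_sd: float = 0.1
    seed: int = 0
    sampling_rate: float = 100.0
    tug: TugSegments = field(default_factory=TugSegments)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValidationError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )
        if self.mounting not in MOUNTINGS:
            raise ValidationError(
                f"unknown mounting {self.mounting!r}; expected one of {MOUNTINGS}"
            )
        if not self.duration_s > 0:
            raise ValidationError("duration_s must be positive")
        if not self.cadence_hz > 0:
            raise ValidationError("cadence_hz must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")
        if not self.sampling_rate > 0:
            raise ValidationError("sampling_rate must be positive")


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


def _jittered_steps(
    rng: np.random.Generator, start: float, span: float, cadence: float
) -> np.ndarray:
    """Heel-strike times on the cadence grid with non-accumulating jitter.

    Nominal strikes sit at ``start + (k + 0.5) * period``; each is displaced
    by truncated Gaussian jitter so consecutive steps stay at least
    0.8 periods apart and the grid phase never drifts.
    """
    period = 1.0 / cadence
    n = int(math.floor(span / period + 0.5))
    if n <= 0:
        return np.empty(0)
    nominal = start + (np.arange(n) + 0.5) * period
    jit = rng.normal(0.0, JITTER_SD_FRAC * period, size=n)
    jit = np.clip(jit, -JITTER_MAX_FRAC * period, JITTER_MAX_FRAC * period)
    return nominal + jit


def _phase(t: np.ndarray, steps: np.ndarray, period: float) -> np.ndarray:
    """Gait phase in radians: 2*pi*k exactly at the k-th heel strike."""
    if steps.size == 1:
        return 2.0 * np.pi * (t - steps[0]) / period
    k = np.arange(steps.size, dtype=float)
    ph = 2.0 * np.pi * np.interp(t, steps, k)
    left = t < steps[0]
    ph[left] = 2.0 * np.pi * (t[left] - steps[0]) / period
    right = t > steps[-1]
    ph[right] = 2.0 * np.pi * ((steps.size - 1) + (t[right] - steps[-1]) / period)
    return ph


def _transient_shape(tau: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Unit-peak biexponential impact: fast rise, slower decay."""
    shape = np.exp(-tau / decay) - np.exp(-tau / rise)
    peak_tau = math.log(decay / rise) / (1.0 / rise - 1.0 / decay)
    peak = math.exp(-peak_tau / decay) - math.exp(-peak_tau / rise)
    return shape / peak


def _add_transients(
    out: np.ndarray,
    t: np.ndarray,
    steps: np.ndarray,
    amps: np.ndarray,
    rise: float,
    decay: float,
    fs: float,
) -> None:
    width = 6.0 * decay
    for t_k, a_k in zip(steps, amps):
        if a_k == 0.0:
            continue
        i0 = int(np.searchsorted(t, t_k))
        i1 = min(int(np.searchsorted(t, t_k + width)), t.size)
        if i1 <= i0:
            continue
        tau = t[i0:i1] - t_k
        out[i0:i1] += a_k * _transient_shape(tau, rise, decay)


def _gyro_bursts(
    t: np.ndarray,
    steps: np.ndarray,
    period: float,
    stance_frac: float,
    amp: float,
) -> np.ndarray:
    """Swing-phase angular-rate bursts, near zero during stance.

    Stance is a quiet window of ``stance_frac * period`` centred on each heel
    strike; every inter-stance gap (including a lead-in before the first
    step) carries a raised-sine burst peaking mid-swing.
    """
    g = np.zeros_like(t)
    if steps.size == 0:
        return g
    half = 0.5 * stance_frac * period
    swing_edges = []
    lead_start = max(float(t[0]), steps[0] - period + half)
    if steps[0] - half > lead_start:
        # the recording opens mid-swing: no rise ramp on the lead burst
        swing_edges.append((lead_start, steps[0] - half, "lead"))
    for a, b in zip(steps[:-1], steps[1:]):
        swing_edges.append((a + half, b - half, "mid"))
    tail_end = min(float(t[-1]), steps[-1] + period - half)
    if tail_end > steps[-1] + half:
        # the recording ends mid-swing: no fall ramp on the tail burst
        swing_edges.append((steps[-1] + half, tail_end, "tail"))
    ramp = 0.15
    for s0, s1, kind in swing_edges:
        if s1 <= s0:
            continue
        sel = (t >= s0) & (t <= s1) if kind == "tail" else (t >= s0) & (t < s1)
        u = (t[sel] - s0) / (s1 - s0)
        # flat-topped burst with smoothstep ramps: the limb accelerates into
        # a sustained rotation rate through mid-swing and decelerates into
        # ground contact
        if kind == "lead":
            edge = 1.0 - u
        elif kind == "tail":
            edge = u
        else:
            edge = np.minimum(u, 1.0 - u)
        v = np.clip(edge / ramp, 0.0, 1.0)
        g[sel] = amp * v * v * (3.0 - 2.0 * v)
    return g


def _walk_channels(
    t: np.ndarray,
    steps: np.ndarray,
    cadence: float,
    mounting: str,
    amp_scale,
    stance_frac: float,
    rng: np.random.Generator,
    noise_sd: float,
    fs: float,
):
    """Accel dynamic (z, x) and gyro magnitude channel for one walking bout."""
    morph = MORPHOLOGY[mounting]
    period = 1.0 / cadence
    scale = np.broadcast_to(np.asarray(amp_scale, dtype=float), steps.shape).copy()
    if noise_sd > 0 and steps.size:
        scale = scale * np.clip(1.0 + 0.05 * rng.normal(size=steps.size), 0.5, 1.5)

    z = np.zeros_like(t)
    x = np.zeros_like(t)
    gyro = np.zeros_like(t)
    if steps.size:
        mean_scale = float(scale.mean())
        ph = _phase(t, steps, period)
        z += morph["swing_amp"] * mean_scale * np.cos(ph + morph["swing_phase_rad"])
        x += 0.3 * morph["swing_amp"] * mean_scale * np.cos(0.5 * ph)
        _add_transients(
            z,
            t,
            steps,
            morph["transient_amp"] * scale,
            morph["transient_rise_s"],
            morph["transient_decay_s"],
            fs,
        )
        gyro = _gyro_bursts(t, steps, period, stance_frac, morph["gyro_amp"] * mean_scale)

    if mounting == "wrist" and noise_sd > 0 and t.size:
        span = float(t[-1] - t[0]) if t.size > 1 else 0.0
        n_gestures = rng.poisson(morph["gesture_rate_hz"] * span)
        centres = rng.uniform(t[0], t[-1], size=n_gestures)
        for c in np.sort(centres):
            sel = np.abs(t - c) < morph["gesture_width_s"]
            u = (t[sel] - c) / morph["gesture_width_s"]
            z[sel] += morph["gesture_amp"] * np.cos(0.5 * np.pi * u) ** 2
    return z, x, gyro


def _assemble(
    spec: SyntheticSpec,
    t: np.ndarray,
    z_dyn: np.ndarray,
    x_dyn: np.ndarray,
    gyro_mag: np.ndarray,
    rng: np.random.Generator,
    truth_times: np.ndarray,
) -> tuple[ImuRecording, GroundTruth]:
    n = t.size
    noise = spec.noise_sd
    accel = np.zeros((3, n))
    accel[0] = x_dyn
    accel[2] = GRAVITY + z_dyn
    if noise > 0:
        accel += rng.normal(0.0, noise, size=(3, n))
    gyro = np.zeros((3, n))
    gyro[0] = gyro_mag
    gyro[1] = 0.2 * gyro_mag
    if noise > 0:
        gyro += rng.normal(0.0, 20.0 * noise, size=(3, n))
    rec = ImuRecording(
        timestamps=t,
        accel=accel,
        gyro=gyro,
        sampling_rate=spec.sampling_rate,
        meta=dict(
            scenario=spec.scenario,
            mounting=spec.mounting,
            cadence_hz=spec.cadence_hz,
            noise_sd=spec.noise_sd,
            seed=spec.seed,
        ),
    )
    return rec, GroundTruth(step_times=truth_times, source="simulated")


def _time_grid(duration_s: float, fs: float) -> np.ndarray:
    n = int(round(duration_s * fs))
    return np.arange(n) / fs


# ---------------------------------------------------------------------------
# scenario entry points
# ---------------------------------------------------------------------------


def simulate_walk(spec: SyntheticSpec) -> tuple[ImuRecording, GroundTruth]:
    """Simulate a continuous walking-type scenario with ground truth.

    Valid scenarios: natural_walk, fast_walk, jog, stairs_up, stairs_down,
    stairs_combined.  For stairs_combined the first half of the steps uses the
    ascent amplitude and the second half the (larger) descent amplitude.
    """
    walk_scenarios = set(SCENARIO_MODS)
    if spec.scenario not in walk_scenarios:
        raise ValidationError(
            f"simulate_walk handles {sorted(walk_scenarios)}, got {spec.scenario!r}"
        )
    rng = np.random.default_rng(spec.seed)
    fs = spec.sampling_rate
    t = _time_grid(spec.duration_s, fs)
    mods = SCENARIO_MODS[spec.scenario]
    steps = _jittered_steps(rng, 0.0, spec.duration_s, spec.cadence_hz)

    if spec.scenario == "stairs_combined":
        up = SCENARIO_MODS["stairs_up"]["amp_scale"]
        down = SCENARIO_MODS["stairs_down"]["amp_scale"]
        amp = np.where(steps < 0.5 * spec.duration_s, up, down)
    else:
        amp = np.full(steps.shape, mods["amp_scale"])

    z, x, g = _walk_channels(
        t, steps, spec.cadence_hz, spec.mounting, amp, mods["stance_frac"], rng, spec.noise_sd, fs
    )
    return _assemble(spec, t, z, x, g, rng, steps)


def simulate_tug(spec: SyntheticSpec) -> tuple[ImuRecording, GroundTruth]:
    """Simulate a Timed Up and Go trial: sit, stand, walk, turn, walk, sit.

    Ground-truth steps exist only inside the two walking bouts; the stand-up
    and sit-down transients and the turning burst are distractor segments
    that violate the continuous-gait assumption of spectral cadence counting.
    Default segment sizes give a 10-15 s trial with 10 true steps, inside the
    4-20 step plausible range.
    """
    if spec.scenario != "tug":
        raise ValidationError(f"simulate_tug requires scenario='tug', got {spec.scenario!r}")
    rng = np.random.default_rng(spec.seed)
    fs = spec.sampling_rate
    seg = spec.tug
    period = 1.0 / spec.cadence_hz
    bout_len = seg.steps_per_bout * period

    t_stand = seg.sit_s
    t_walk1 = t_stand + seg.stand_s
    t_turn = t_walk1 + bout_len
    t_walk2 = t_turn + seg.turn_s
    t_sit = t_walk2 + bout_len
    total = t_sit + seg.end_sit_s
    t = _time_grid(total, fs)

    z = np.zeros_like(t)
    x = np.zeros_like(t)
    g = np.zeros_like(t)
    truth = []

    def bump(centre: float, width: float, amp: float) -> None:
        sel = np.abs(t - centre) < 0.5 * width
        u = (t[sel] - centre) / (0.5 * width)
        z[sel] += amp * np.cos(0.5 * np.pi * u) ** 2

    # stand-up / sit-down transients: large vertical surges
    bump(t_stand + 0.5 * seg.stand_s, 0.8 * seg.stand_s, 3.0)
    bump(t_sit + 0.4, 0.8, -0.5)
    bump(t_sit + 0.4, 0.5, 3.0)

    mods = SCENARIO_MODS["natural_walk"]
    for start in (t_walk1, t_walk2):
        sel = (t >= start) & (t < start + bout_len)
        if seg.steps_per_bout <= 0 or not np.any(sel):
            continue
        steps = _jittered_steps(rng, start, bout_len, spec.cadence_hz)
        zb, xb, gb = _walk_channels(
            t[sel],
            steps,
            spec.cadence_hz,
            spec.mounting,
            np.full(steps.shape, mods["amp_scale"]),
            mods["stance_frac"],
            rng,
            spec.noise_sd,
            fs,
        )
        z[sel] += zb
        x[sel] += xb
        g[sel] += gb
        truth.extend(steps.tolist())

    # turn: strong rotation, irregular low-amplitude sway below the gait band
    sel = (t >= t_turn) & (t < t_turn + seg.turn_s)
    u = (t[sel] - t_turn) / seg.turn_s
    g[sel] += 250.0 * np.sin(np.pi * u) ** 2
    z[sel] += 0.4 * np.sin(2.0 * np.pi * 0.6 * (t[sel] - t_turn))

    return _assemble(spec, t, z, x, g, rng, np.asarray(sorted(truth)))


def simulate_stationary(spec: SyntheticSpec) -> tuple[ImuRecording, GroundTruth]:
    """Gravity plus noise only; the ground truth is empty (negative control)."""
    if spec.scenario != "stationary":
        raise ValidationError(
            f"simulate_stationary requires scenario='stationary', got {spec.scenario!r}"
        )
    rng = np.random.default_rng(spec.seed)
    t = _time_grid(spec.duration_s, spec.sampling_rate)
    zero = np.zeros_like(t)
    return _assemble(spec, t, zero, zero, zero, rng, np.empty(0))


def simulate(spec: SyntheticSpec) -> tuple[ImuRecording, GroundTruth]:
    """Dispatch to the scenario-specific generator."""
    if spec.scenario == "stationary":
        return simulate_stationary(spec)
    if spec.scenario == "tug":
        return simulate_tug(spec)
    return simulate_walk(spec)
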