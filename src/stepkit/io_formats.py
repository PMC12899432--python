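"""CSV recording format and the external-dialect interpreter.

Canonical schema
----------------
Recordings are RFC-4180 CSV files (header row, UTF-8, ``.`` decimal
separator; gzip accepted by ``.gz`` extension) with columns::

    time_s, s1_ax, s1_ay, s1_az, s1_gx, s1_gy, s1_gz, s1_mx, s1_my, s1_mz,
    step_marker

Timestamps are seconds from the start of the recording (0-based);
acceleration is in m/s^2 with gravity included, angular rate in deg/s.
Absent gyroscope/magnetometer channels are written as empty fields and read
back as absent.  ``step_marker`` is 0/1; rows marked 1 carry the manually
annotated (or simulated) step times, i.e. the ground truth travels inside
the same file as the signal.  A second sensor's channels may be present
under the ``s2_`` prefix and are selected with ``read_recording(...,
sensor=2)``.

Interpreter
-----------
External datasets come in heterogeneous dialects (other column names, units
of g or rad/s, millisecond or sample-index timestamps).
:class:`ColumnMapping` declares how one dialect maps onto the canonical
schema; :func:`read_recording` applies the renames, unit conversions and
timestamp normalization, and :func:`resample` interpolates onto a uniform
grid at a target rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .core import (
    STANDARD_GRAVITY,
    GroundTruth,
    ImuRecording,
    MappingError,
    SchemaError,
    ValidationError,
)

__all__ = ["ColumnMapping", "read_recording", "write_recording", "resample"]

_AXES = ("ax", "ay", "az", "gx", "gy", "gz", "mx", "my", "mz")
_ACCEL_UNITS = ("m/s^2", "g")
_GYRO_UNITS = ("deg/s", "rad/s")
_TIME_UNITS = ("seconds", "milliseconds", "sample_index")


@dataclass
class ColumnMapping:
    """Declarative map from an external CSV dialect to the canonical schema.

    ``columns`` maps source column names to canonical field names: ``time``,
    the nine axis names (``ax``..``mz``), and optionally ``step_marker``.
    All three accelerometer axes must be mapped.
    """

    columns: dict
    accel_unit: str = "m/s^2"
    gyro_unit: str = "deg/s"
    timestamp_unit: str = "seconds"
    sampling_rate_hz: Optional[float] = None

    def __post_init__(self) -> None:
        canonical = set(self.columns.values())
        for axis in ("ax", "ay", "az"):
            if axis not in canonical:
                raise MappingError(f"mapping must cover accelerometer axis {axis!r}")
        allowed = set(_AXES) | {"time", "step_marker"}
        unknown = canonical - allowed
        if unknown:
            raise MappingError(f"mapping targets unknown canonical fields: {sorted(unknown)}")
        if self.accel_unit not in _ACCEL_UNITS:
            raise MappingError(
                f"accel_unit must be one of {_ACCEL_UNITS}, got {self.accel_unit!r}"
            )
        if self.gyro_unit not in _GYRO_UNITS:
            raise MappingError(
                f"gyro_unit must be one of {_GYRO_UNITS}, got {self.gyro_unit!r}"
            )
        if self.timestamp_unit not in _TIME_UNITS:
            raise MappingError(
                f"timestamp_unit must be one of {_TIME_UNITS}, got {self.timestamp_unit!r}"
            )
        if self.timestamp_unit == "sample_index" and not self.sampling_rate_hz:
            raise MappingError("sample_index timestamps require sampling_rate_hz")

    @classmethod
    def from_yaml(cls, path) -> "ColumnMapping":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict) or "columns" not in data:
            raise MappingError(f"mapping file {path} must define a 'columns' block")
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {
            "columns": dict(self.columns),
            "accel_unit": self.accel_unit,
            "gyro_unit": self.gyro_unit,
            "timestamp_unit": self.timestamp_unit,
        }
        if self.sampling_rate_hz is not None:
            data["sampling_rate_hz"] = self.sampling_rate_hz
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _channel_block(df: pd.DataFrame, cols: list, what: str, n: int):
    """Extract a (3, N) block, or None when the columns are absent/empty."""
    present = [c for c in cols if c in df.columns]
    if len(present) < 3:
        return None
    block = df[cols].to_numpy(dtype=float).T
    if np.all(np.isnan(block)):
        return None
    if np.any(np.isnan(block)):
        raise ValidationError(f"{what} channels are partially empty")
    return block


def _build_recording(
    t: np.ndarray,
    accel: np.ndarray,
    gyro,
    mag,
    meta: dict,
) -> ImuRecording:
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValidationError("timestamps are not strictly increasing")
    if t.size > 1:
        rate = 1.0 / float(np.median(np.diff(t)))
    else:
        rate = 100.0
    return ImuRecording(
        timestamps=t, accel=accel, gyro=gyro, mag=mag, sampling_rate=rate, meta=meta
    )


def read_recording(path, mapping: Optional[ColumnMapping] = None, sensor: int = 1):
    """Read a recording CSV; returns ``(ImuRecording, GroundTruth | None)``.

    Without a mapping the file must follow the canonical schema (``sensor``
    selects the ``s1_``/``s2_`` channel prefix).  With a mapping, columns are
    renamed, units converted to m/s^2 and deg/s, and timestamps normalized to
    seconds from the start of the recording.
    """
    path = Path(path)
    df = pd.read_csv(path)
    meta = {"source_file": str(path)}

    if mapping is None:
        prefix = f"s{sensor}_"
        if "time_s" not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column 'time_s'")
        for axis in ("ax", "ay", "az"):
            if prefix + axis not in df.columns:
                raise SchemaError(f"{path}: missing mandatory column '{prefix}{axis}'")
        t = df["time_s"].to_numpy(dtype=float)
        accel = df[[prefix + a for a in ("ax", "ay", "az")]].to_numpy(dtype=float).T
        gyro = _channel_block(df, [prefix + a for a in ("gx", "gy", "gz")], "gyro", t.size)
        mag = _channel_block(df, [prefix + a for a in ("mx", "my", "mz")], "mag", t.size)
        rec = _build_recording(t, accel, gyro, mag, meta)
        truth = None
        if "step_marker" in df.columns:
            marker = df["step_marker"].fillna(0).to_numpy()
            times = t[marker == 1]
            if times.size:
                truth = GroundTruth(step_times=times, source="manual_annotation")
        return rec, truth

    inv = dict(mapping.columns)
    for src in inv:
        if src not in df.columns:
            raise SchemaError(f"{path}: mapped source column {src!r} not present")
    df = df.rename(columns=inv)

    if mapping.timestamp_unit == "sample_index":
        t = np.arange(len(df)) / float(mapping.sampling_rate_hz)
    else:
        if "time" not in df.columns:
            raise SchemaError(f"{path}: mapping does not provide a 'time' column")
        t = df["time"].to_numpy(dtype=float)
        if mapping.timestamp_unit == "milliseconds":
            t = t / 1000.0
        t = t - t[0]

    accel = df[["ax", "ay", "az"]].to_numpy(dtype=float).T
    if mapping.accel_unit == "g":
        accel = accel * STANDARD_GRAVITY
    gyro = _channel_block(df, ["gx", "gy", "gz"], "gyro", t.size)
    if gyro is not None and mapping.gyro_unit == "rad/s":
        gyro = gyro * 180.0 / math.pi
    mag = _channel_block(df, ["mx", "my", "mz"], "mag", t.size)
    rec = _build_recording(t, accel, gyro, mag, meta)
    truth = None
    if "step_marker" in df.columns:
        marker = df["step_marker"].fillna(0).to_numpy()
        times = t[marker == 1]
        if times.size:
            truth = GroundTruth(step_times=times, source="manual_annotation")
    return rec, truth


def write_recording(rec: ImuRecording, truth: Optional[GroundTruth], path) -> None:
    """Write a recording (and optional ground truth) in the canonical schema.

    Column order is fixed, values carry 9 significant digits, absent channels
    become empty fields, and the ground truth is stored as the
    ``step_marker`` column (1 on the sample nearest each step time) — two
    writes of the same recording are byte-identical.
    """
    path = Path(path)
    n = rec.n_samples
    data = {"time_s": rec.timestamps}
    for block, names in (
        (rec.accel, ("ax", "ay", "az")),
        (rec.gyro, ("gx", "gy", "gz")),
        (rec.mag, ("mx", "my", "mz")),
    ):
        for k, name in enumerate(names):
            data[f"s1_{name}"] = block[k] if block is not None else np.full(n, np.nan)
    marker = np.zeros(n, dtype=int)
    if truth is not None and truth.step_times.size:
        idx = np.searchsorted(rec.timestamps, truth.step_times)
        for j, t_step in zip(idx, truth.step_times):
            j = min(j, n - 1)
            if j > 0 and abs(rec.timestamps[j - 1] - t_step) < abs(rec.timestamps[j] - t_step):
                j -= 1
            marker[j] = 1
    data["step_marker"] = marker
    df = pd.DataFrame(data)
    try:
        df.to_csv(path, index=False, float_format="%.9g", na_rep="")
    except OSError as exc:
        raise OSError(f"failed to write recording to {path}: {exc}") from exc


def resample(rec: ImuRecording, target_hz: float) -> ImuRecording:
    """Linearly interpolate every channel onto a uniform grid at ``target_hz``.

    The grid spans ``[t_first, t_last]`` inclusively with
    ``round(span * target_hz) + 1`` samples.  Ground truth times are not
    affected by resampling (they are timestamps, not samples).
    """
    if not target_hz > 0:
        raise ValidationError("target_hz must be positive")
    if rec.n_samples < 2:
        raise ValidationError("resampling needs at least two samples")
    t = rec.timestamps
    span = float(t[-1] - t[0])
    n = int(round(span * target_hz)) + 1
    tq = t[0] + np.arange(n) / target_hz

    def interp_block(block):
        if block is None:
            return None
        return np.vstack([np.interp(tq, t, block[k]) for k in range(3)])

    return ImuRecording(
        timestamps=tq,
        accel=interp_block(rec.accel),
        gyro=interp_block(rec.gyro),
        mag=interp_block(rec.mag),
        sampling_rate=target_hz,
        meta=dict(rec.meta, resampled_from_hz=rec.sampling_rate),
    )
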