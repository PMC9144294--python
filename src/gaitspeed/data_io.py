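"""Reading, validating and unit-converting raw IMU recordings.

The on-disk layout is one numeric array per subject with 20 columns per time
instant: columns 1–9 are accelerometer counts (1:3 thigh, 4:6 shin, 7:9
foot), columns 10–18 gyroscope counts (10:12 thigh, 13:15 shin, 16:18 foot),
column 19 the reference speed in km/h and column 20 the timestamp in seconds.
Raw counts convert to physical units with fixed multipliers (0.0024 → m/s²,
0.061 → deg/s); the sensors saturate at ±80 m/s² and ±2000 deg/s, and
saturated stretches are kept — they carry information about fast running and
any downstream method must cope with them.

Column indices are documented 1-based to match the dataset description but
stored 0-based; this module owns the translation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.io

__all__ = [
    "ACCEL_MULTIPLIER", "GYRO_MULTIPLIER", "ACCEL_LIMIT", "GYRO_LIMIT",
    "PLACEMENTS", "FormatError", "RawRecording", "SensorSelection",
    "load_recording", "convert_units", "select_channels",
]

ACCEL_MULTIPLIER = 0.0024   # raw count -> m/s^2
GYRO_MULTIPLIER = 0.061     # raw count -> deg/s
ACCEL_LIMIT = 80.0          # m/s^2, sensor dynamic range
GYRO_LIMIT = 2000.0         # deg/s

PLACEMENTS = ("thigh", "shin", "foot")

# 0-based column blocks per placement
_ACCEL_COLS = {"thigh": slice(0, 3), "shin": slice(3, 6), "foot": slice(6, 9)}
_GYRO_COLS = {"thigh": slice(9, 12), "shin": slice(12, 15), "foot": slice(15, 18)}
SPEED_COL = 18
TIME_COL = 19
N_COLS = 20


class FormatError(ValueError):
    """Raised when a file does not match the 20-column recording layout."""


@dataclass(frozen=True)
class RawRecording:
    """One subject's recording in the standard 20-column layout."""

    raw_matrix: np.ndarray          # (n_samples, 20)
    subject_id: str
    units_converted: bool = False

    def __post_init__(self):
        m = np.asarray(self.raw_matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != N_COLS:
            raise FormatError(
                f"recording must have {N_COLS} columns, got shape {m.shape}")
        if not np.all(np.isfinite(m)):
            raise FormatError("recording contains non-finite values")
        t = m[:, TIME_COL]
        if np.any(np.diff(t) < 0):
            raise FormatError("time column must be non-decreasing")
        object.__setattr__(self, "raw_matrix", m)

    @property
    def n_samples(self) -> int:
        return self.raw_matrix.shape[0]

    @property
    def time(self) -> np.ndarray:
        return self.raw_matrix[:, TIME_COL]

    @property
    def speed(self) -> np.ndarray:
        return self.raw_matrix[:, SPEED_COL]


@dataclass(frozen=True)
class SensorSelection:
    """Non-empty subset of sensor placements, kept in thigh–shin–foot order."""

    placements: tuple[str, ...] = field(default=PLACEMENTS)

    def __post_init__(self):
        norm = tuple(p for p in PLACEMENTS if p in set(self.placements))
        unknown = set(self.placements) - set(PLACEMENTS)
        if unknown:
            raise ValueError(f"unknown placements: {sorted(unknown)}")
        if not norm:
            raise ValueError("sensor selection must be non-empty")
        object.__setattr__(self, "placements", norm)

    @property
    def n_channels(self) -> int:
        return 6 * len(self.placements)

    def channel_names(self) -> list[str]:
        names = [f"{p}_acc_{ax}" for p in self.placements for ax in "xyz"]
        names += [f"{p}_gyr_{ax}" for p in self.placements for ax in "xyz"]
        return names


def load_recording(path: str | os.PathLike, subject_id: str) -> RawRecording:
    """Load one subject's array from CSV or a MAT container.

    Format is chosen by extension: ``.mat`` goes through :mod:`scipy.io`
    (taking the first non-metadata variable), anything else is parsed as
    comma-delimited text with no header.  The returned recording is flagged
    unconverted; call :func:`convert_units` before selecting channels.
    """
    path = os.fspath(path)
    if path.lower().endswith(".mat"):
        contents = scipy.io.loadmat(path)
        arrays = {k: v for k, v in contents.items() if not k.startswith("__")}
        if not arrays:
            raise FormatError(f"no data array found in {path}")
        matrix = np.asarray(next(iter(arrays.values())), dtype=float)
    else:
        try:
            matrix = np.loadtxt(path, delimiter=",", ndmin=2)
        except ValueError as exc:
            raise FormatError(f"could not parse {path} as numeric CSV: {exc}") from exc
    return RawRecording(raw_matrix=matrix, subject_id=subject_id, units_converted=False)


def convert_units(rec: RawRecording) -> RawRecording:
    """Scale raw counts to physical units (m/s² and deg/s).

    Speed (km/h) and time (s) columns are untouched.  Converting twice is a
    state error — the multipliers are not idempotent.
    """
    if rec.units_converted:
        raise ValueError("recording already unit-converted")
    m = rec.raw_matrix.copy()
    m[:, 0:9] *= ACCEL_MULTIPLIER
    m[:, 9:18] *= GYRO_MULTIPLIER
    return replace(rec, raw_matrix=m, units_converted=True)


def select_channels(rec: RawRecording, sel: SensorSelection) -> np.ndarray:
    """Extract the (C, n_samples) channel matrix for a sensor selection.

    Channel order is deterministic: accelerometer triads for each selected
    placement in thigh–shin–foot order, then the gyroscope triads in the same
    placement order.  C = 6 × |placements|.
    """
    if not rec.units_converted:
        raise ValueError("convert_units must be applied before channel selection")
    blocks = [rec.raw_matrix[:, _ACCEL_COLS[p]] for p in sel.placements]
    blocks += [rec.raw_matrix[:, _GYRO_COLS[p]] for p in sel.placements]
    return np.concatenate(blocks, axis=1).T
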