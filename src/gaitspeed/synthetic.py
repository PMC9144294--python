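"""Phenomenological generator of per-subject IMU gait recordings.

The generator produces the statistical structure that speed estimation from
leg-worn IMUs exploits, without attempting biomechanical fidelity: each
channel is a sum of harmonics of the instantaneous step frequency, the step
frequency follows a subject-specific increasing law f(v) with distinct
walking and running regimes, harmonic amplitudes grow with speed, and the
physical signal saturates at the sensor limits (±80 m/s², ±2000 deg/s)
before being converted back to integer raw counts.  Sampling is irregular
around a nominal 400 Hz, as in the real acquisition chain.

By default the foot channels carry the strongest speed-dependent signal and
the thigh the weakest (with proportionally more measurement noise), matching
the qualitative sensor-placement ordering observed on real recordings.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import scipy.io

from .data_io import (ACCEL_LIMIT, ACCEL_MULTIPLIER, GYRO_LIMIT, GYRO_MULTIPLIER,
                      PLACEMENTS, RawRecording)

__all__ = ["GaitModelParams", "SpeedProfile", "generate_speed_profile",
           "synthesize_recording", "synthesize_cohort", "apply_saturation",
           "write_recording_csv", "write_recording_mat"]

GRAVITY = 9.81  # m/s^2

# relative strength of the speed-dependent signal per placement
_PLACEMENT_GAIN = {"thigh": 0.25, "shin": 0.55, "foot": 1.0}
# extra noise for less informative placements
_PLACEMENT_NOISE = {"thigh": 2.0, "shin": 1.3, "foot": 1.0}


@dataclass(frozen=True)
class GaitModelParams:
    """Subject-level parameters of the harmonic gait model.

    The step-frequency law is piecewise linear in speed v (km/h):
    f(v) = walk_base + walk_slope·v below ``switch_speed`` and
    f(v) = run_base + run_slope·v above it, both strictly increasing.
    Accelerometer amplitudes are in m/s², gyroscope in deg/s.
    """

    walk_base: float = 1.2       # Hz
    walk_slope: float = 0.09     # Hz per km/h
    run_base: float = 2.3        # Hz
    run_slope: float = 0.035     # Hz per km/h
    switch_speed: float = 8.0    # km/h, walk/run regime boundary
    accel_amp0: float = 1.5      # m/s^2 at standstill
    accel_amp_slope: float = 3.2  # m/s^2 per km/h (foot; scaled down per placement)
    gyro_amp0: float = 60.0      # deg/s
    gyro_amp_slope: float = 90.0  # deg/s per km/h
    n_harmonics: int = 3
    harmonic_decay: float = 0.5
    accel_noise_std: float = 0.3  # m/s^2
    gyro_noise_std: float = 8.0   # deg/s
    nominal_rate: float = 400.0   # Hz
    jitter_std: float = 0.1       # fraction of the nominal sample interval
    placement_gain: dict = field(default_factory=lambda: dict(_PLACEMENT_GAIN))
    placement_noise: dict = field(default_factory=lambda: dict(_PLACEMENT_NOISE))

    def __post_init__(self):
        if self.walk_slope <= 0 or self.run_slope <= 0:
            raise ValueError("step-frequency law must be strictly increasing")
        if min(self.accel_amp0, self.gyro_amp0, self.accel_amp_slope,
               self.gyro_amp_slope) < 0:
            raise ValueError("amplitudes must be non-negative")

    def step_frequency(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        walk = self.walk_base + self.walk_slope * v
        run = self.run_base + self.run_slope * v
        return np.where(v <= self.switch_speed, walk, run)

    @classmethod
    def for_subject(cls, rng: np.random.Generator, **overrides) -> "GaitModelParams":
        """Draw subject-specific variations of the default gait law."""
        params = dict(
            walk_base=rng.normal(1.2, 0.12),
            walk_slope=max(0.03, rng.normal(0.09, 0.015)),
            run_base=rng.normal(2.3, 0.18),
            run_slope=max(0.01, rng.normal(0.035, 0.008)),
            switch_speed=rng.normal(8.0, 0.7),
            accel_amp0=max(0.2, rng.normal(1.5, 0.3)),
            accel_amp_slope=max(1.0, rng.normal(3.2, 0.5)),
            gyro_amp0=max(10.0, rng.normal(60.0, 12.0)),
            gyro_amp_slope=max(30.0, rng.normal(90.0, 15.0)),
        )
        params.update(overrides)
        return cls(**params)


@dataclass(frozen=True)
class SpeedProfile:
    """Piecewise-linear ground-truth speed trace (km/h ≥ 0, bounded slope)."""

    knot_times: np.ndarray   # s, strictly increasing, starting at 0
    knot_speeds: np.ndarray  # km/h
    ramp_limit: float        # km/h per s

    @property
    def duration(self) -> float:
        return float(self.knot_times[-1])

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.knot_times, self.knot_speeds)


def generate_speed_profile(duration: float, rng: np.random.Generator,
                           speed_range: tuple[float, float] = (1.0, 24.0),
                           dwell_range: tuple[float, float] = (4.0, 10.0),
                           ramp_limit: float = 1.5) -> SpeedProfile:
    """Alternate steady dwells and bounded ramps covering walking and running.

    Target speeds are drawn uniformly over ``speed_range`` (spanning both
    gait regimes); each dwell holds the speed for 4–10 s and ramps move
    between targets at exactly the configured |dv/dt| limit.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    times = [0.0]
    speeds = [float(rng.uniform(*speed_range))]
    while times[-1] < duration:
        # dwell
        dwell = float(rng.uniform(*dwell_range))
        times.append(times[-1] + dwell)
        speeds.append(speeds[-1])
        # ramp to a new target
        target = float(rng.uniform(*speed_range))
        ramp = abs(target - speeds[-1]) / ramp_limit
        times.append(times[-1] + max(ramp, 1e-6))
        speeds.append(target)
    # truncate to the requested duration
    t = np.asarray(times)
    v = np.asarray(speeds)
    v_end = float(np.interp(duration, t, v))
    keep = t < duration
    t = np.concatenate([t[keep], [duration]])
    v = np.concatenate([v[keep], [v_end]])
    return SpeedProfile(knot_times=t, knot_speeds=np.maximum(v, 0.0),
                        ramp_limit=ramp_limit)


def apply_saturation(x: np.ndarray, limit: float) -> np.ndarray:
    """Clip physical values to the sensor's dynamic range [−limit, +limit]."""
    if limit <= 0:
        raise ValueError("limit must be positive")
    return np.clip(x, -limit, limit)


def _jittered_timestamps(duration: float, params: GaitModelParams,
                         rng: np.random.Generator) -> np.ndarray:
    dt = 1.0 / params.nominal_rate
    n = int(np.floor(duration * params.nominal_rate))
    steps = dt * (1.0 + params.jitter_std * rng.standard_normal(n))
    steps = np.maximum(steps, 0.05 * dt)  # keep time strictly increasing
    t = np.concatenate([[0.0], np.cumsum(steps)])
    return t[t <= duration]


def synthesize_recording(params: GaitModelParams, profile: SpeedProfile,
                         rng: np.random.Generator,
                         subject_id: str = "synthetic") -> RawRecording:
    """Render a 20-column raw-count recording from the gait model.

    Columns 1–9 are accelerometer counts (thigh, shin, foot triads), 10–18
    gyroscope counts, 19 the ground-truth speed (km/h), 20 the jittered
    timestamps (s).  Physical signals are clipped at the sensor limits before
    inverse unit conversion and rounding to integer counts, so saturation and
    quantization are both exercised downstream.
    """
    t = _jittered_timestamps(profile.duration, params, rng)
    n = t.size
    v = profile(t)
    f = params.step_frequency(v)
    # cumulative gait phase 2π∫f dt (trapezoid on the irregular grid)
    dphi = np.diff(t) * 0.5 * (f[1:] + f[:-1])
    phase = 2.0 * np.pi * np.concatenate([[0.0], np.cumsum(dphi)])

    matrix = np.zeros((n, 20))
    for p_idx, placement in enumerate(PLACEMENTS):
        gain = params.placement_gain[placement]
        noise_factor = params.placement_noise[placement]
        for axis in range(3):
            acc_col = 3 * p_idx + axis
            gyr_col = 9 + 3 * p_idx + axis
            acc = np.zeros(n)
            gyr = np.zeros(n)
            # static gravity split over axes (accelerometers measure it)
            grav_dir = rng.normal(size=1)[0]
            acc += GRAVITY * 0.5 * np.tanh(grav_dir)
            for harm in range(1, params.n_harmonics + 1):
                decay = params.harmonic_decay ** (harm - 1)
                phi_a = rng.uniform(0, 2 * np.pi)
                phi_g = rng.uniform(0, 2 * np.pi)
                amp_a = decay * (params.accel_amp0 + gain * params.accel_amp_slope * v)
                amp_g = decay * (params.gyro_amp0 + gain * params.gyro_amp_slope * v)
                acc += amp_a * np.sin(harm * phase + phi_a)
                gyr += amp_g * np.sin(harm * phase + phi_g)
            acc += noise_factor * params.accel_noise_std * rng.standard_normal(n)
            gyr += noise_factor * params.gyro_noise_std * rng.standard_normal(n)
            acc = apply_saturation(acc, ACCEL_LIMIT)
            gyr = apply_saturation(gyr, GYRO_LIMIT)
            matrix[:, acc_col] = np.round(acc / ACCEL_MULTIPLIER)
            matrix[:, gyr_col] = np.round(gyr / GYRO_MULTIPLIER)
    matrix[:, 18] = v
    matrix[:, 19] = t
    return RawRecording(raw_matrix=matrix, subject_id=subject_id,
                        units_converted=False)


def synthesize_cohort(n_subjects: int, duration: float,
                      seed: int) -> list[RawRecording]:
    """Generate a cohort of subjects with distinct gait laws (one seed each)."""
    root = np.random.default_rng(seed)
    recs = []
    for i in range(n_subjects):
        rng = np.random.default_rng(root.integers(2 ** 31))
        params = GaitModelParams.for_subject(rng)
        profile = generate_speed_profile(duration, rng)
        recs.append(synthesize_recording(params, profile, rng,
                                         subject_id=f"S{i + 1:02d}"))
    return recs


def write_recording_csv(rec: RawRecording, path: str | os.PathLike) -> None:
    """Write the 20-column matrix as headerless CSV (exact float round-trip)."""
    np.savetxt(os.fspath(path), rec.raw_matrix, delimiter=",", fmt="%.17g")


def write_recording_mat(rec: RawRecording, path: str | os.PathLike) -> None:
    """Write the matrix as a MAT container with a single ``data`` variable."""
    scipy.io.savemat(os.fspath(path), {"data": rec.raw_matrix})
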