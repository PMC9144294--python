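"""Training-set augmentation for IMU windows.

Two transforms, applied only to training folds and never touching labels:

* **sensor rotation** — one randomly chosen sensor's accelerometer and
  gyroscope triads are rotated by a single small random rotation (angle
  ~ N(0, 2.5°), axis uniform on the sphere), held constant over the window;
  this emulates a slightly different physical mounting of that sensor.
* **relative noise** — every sample x is replaced by x·(1 + η) with
  η ~ N(0, 0.01) independently per element, i.e. white noise at 1% of the
  observed value, which discourages the models from keying on single samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .preprocess import WindowSet

__all__ = ["AugmentConfig", "random_rotation", "rotate_sensor",
           "add_relative_noise", "augment_batch"]


@dataclass(frozen=True)
class AugmentConfig:
    rotation_angle_std: float = 2.5    # degrees
    relative_noise_std: float = 0.01   # fraction of the observed value
    copies_per_window: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.rotation_angle_std < 0 or self.relative_noise_std < 0:
            raise ValueError("augmentation noise scales must be >= 0")
        if self.copies_per_window < 0:
            raise ValueError("copies_per_window must be >= 0")


def random_rotation(angle_std: float, rng: np.random.Generator) -> np.ndarray:
    """Rotation matrix with angle ~ N(0, angle_std°) about a uniform axis."""
    if angle_std < 0:
        raise ValueError("angle_std must be >= 0")
    angle = np.deg2rad(rng.normal(0.0, angle_std))
    axis = rng.normal(size=3)
    norm = np.linalg.norm(axis)
    if norm == 0.0:  # probability zero; fall back to a fixed axis
        axis = np.array([1.0, 0.0, 0.0])
        norm = 1.0
    return Rotation.from_rotvec(angle * axis / norm).as_matrix()


def _triad_rows(placement_index: int, n_placements: int) -> tuple[slice, slice]:
    acc = slice(3 * placement_index, 3 * placement_index + 3)
    gyr = slice(3 * (n_placements + placement_index), 3 * (n_placements + placement_index) + 3)
    return acc, gyr


def rotate_sensor(window: np.ndarray, placement_index: int, R: np.ndarray) -> np.ndarray:
    """Apply one rotation to a sensor's accel and gyro triads of a (C, T) window.

    ``placement_index`` counts sensors in the window's channel order (the
    window holds 3 accel rows per sensor followed by 3 gyro rows per sensor).
    Other sensors' channels are untouched.
    """
    C = window.shape[0]
    if C % 6 != 0:
        raise ValueError(f"window must hold whole sensors (6 channels each), got C={C}")
    n_placements = C // 6
    if not 0 <= placement_index < n_placements:
        raise ValueError(f"placement index {placement_index} outside window with "
                         f"{n_placements} sensors")
    out = window.copy()
    acc, gyr = _triad_rows(placement_index, n_placements)
    out[acc] = R @ window[acc]
    out[gyr] = R @ window[gyr]
    return out


def add_relative_noise(window: np.ndarray, rel_std: float,
                       rng: np.random.Generator) -> np.ndarray:
    """x -> x·(1 + η), η ~ N(0, rel_std) i.i.d. per element; zeros stay zero."""
    if rel_std < 0:
        raise ValueError("rel_std must be >= 0")
    if rel_std == 0:
        return window.copy()
    return window * (1.0 + rng.normal(0.0, rel_std, size=window.shape))


def augment_batch(ws: WindowSet, cfg: AugmentConfig) -> WindowSet:
    """Return the original windows plus ``copies_per_window`` augmented copies.

    Each copy rotates one uniformly chosen sensor, then adds relative noise.
    Labels and subject ids are carried over unchanged.  Deterministic for a
    fixed ``cfg.seed``.
    """
    if len(ws) == 0:
        raise ValueError("cannot augment an empty WindowSet")
    if cfg.copies_per_window == 0:
        return ws
    rng = np.random.default_rng(cfg.seed)
    n_placements = ws.X.shape[1] // 6
    pieces_X = [ws.X]
    pieces_y = [ws.y]
    pieces_s = [ws.subject_ids]
    for _ in range(cfg.copies_per_window):
        Xa = np.empty_like(ws.X)
        for i in range(len(ws)):
            sensor = int(rng.integers(n_placements))
            R = random_rotation(cfg.rotation_angle_std, rng)
            w = rotate_sensor(ws.X[i], sensor, R)
            Xa[i] = add_relative_noise(w, cfg.relative_noise_std, rng)
        pieces_X.append(Xa)
        pieces_y.append(ws.y.copy())
        pieces_s.append(ws.subject_ids.copy())
    return WindowSet(np.concatenate(pieces_X), np.concatenate(pieces_y),
                     np.concatenate(pieces_s), ws.h)
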