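"""Resampling to a uniform grid and fixed-length windowing.

Recordings arrive with irregular ~400 Hz timestamps; all models consume an
isochronal 512 Hz signal cut into 2 s windows (T = 1024 samples) whose label
is the reference speed at the window's middle sample.  Interpolation is
piecewise-linear per channel, which cannot overshoot on saturated plateaus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_io import RawRecording, SensorSelection, select_channels

__all__ = ["DEFAULT_RATE", "WINDOW_SECONDS", "UniformRecording", "WindowSet",
           "resample_uniform", "make_windows", "windows_from_recordings"]

DEFAULT_RATE = 512.0     # Hz
WINDOW_SECONDS = 2.0


@dataclass(frozen=True)
class UniformRecording:
    """Isochronal multichannel signal with a per-sample speed trace."""

    signal: np.ndarray      # (C, n), physical units
    speed: np.ndarray       # (n,), km/h
    rate: float             # Hz
    subject_id: str

    def __post_init__(self):
        if self.signal.shape[1] != self.speed.shape[0]:
            raise ValueError("signal and speed traces must be sample-aligned")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]


@dataclass(frozen=True)
class WindowSet:
    """Stack of fixed-length windows with center-sample speed labels."""

    X: np.ndarray               # (N, C, T)
    y: np.ndarray               # (N,), km/h
    subject_ids: np.ndarray     # (N,), str
    h: int                      # half-window length in samples

    def __post_init__(self):
        if not (len(self.X) == len(self.y) == len(self.subject_ids)):
            raise ValueError("X, y and subject_ids must have equal length")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def window_length(self) -> int:
        return self.X.shape[2] if self.X.ndim == 3 else 2 * self.h

    def subset(self, idx) -> "WindowSet":
        return WindowSet(self.X[idx], self.y[idx], self.subject_ids[idx], self.h)

    @staticmethod
    def concatenate(sets: list["WindowSet"]) -> "WindowSet":
        sets = [s for s in sets if len(s) > 0]
        if not sets:
            raise ValueError("nothing to concatenate")
        h = sets[0].h
        return WindowSet(
            np.concatenate([s.X for s in sets]),
            np.concatenate([s.y for s in sets]),
            np.concatenate([s.subject_ids for s in sets]),
            h,
        )


def resample_uniform(rec: RawRecording, rate: float = DEFAULT_RATE,
                     sel: SensorSelection | None = None) -> UniformRecording:
    """Interpolate selected channels and the speed trace onto a uniform grid.

    The grid spans [t_first, t_last] at spacing 1/rate.  Duplicate timestamps
    are collapsed (first occurrence kept) before interpolation.  ``sel``
    defaults to all three placements (18 channels).
    """
    if sel is None:
        sel = SensorSelection()
    if rec.n_samples < 2:
        raise ValueError("resampling needs at least 2 samples")
    t = rec.time
    keep = np.concatenate([[True], np.diff(t) > 0])
    t = t[keep]
    if t.size < 2:
        raise ValueError("fewer than 2 distinct timestamps")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time not strictly increasing after de-duplication")

    channels = select_channels(rec, sel)[:, keep]
    speed = rec.speed[keep]

    n_out = int(np.floor((t[-1] - t[0]) * rate)) + 1
    grid = t[0] + np.arange(n_out) / rate
    signal = np.empty((channels.shape[0], n_out))
    for c in range(channels.shape[0]):
        signal[c] = np.interp(grid, t, channels[c])
    speed_out = np.interp(grid, t, speed)
    return UniformRecording(signal=signal, speed=speed_out, rate=rate,
                            subject_id=rec.subject_id)


def make_windows(rec: UniformRecording, window_s: float = WINDOW_SECONDS,
                 stride: int | None = None) -> WindowSet:
    """Cut fixed-length windows; the label is the speed at index T/2.

    N = floor((n − T)/stride) + 1.  A recording shorter than one window
    yields an empty set with a warning rather than an exception, so that
    per-subject loops over heterogeneous recordings do not abort.
    """
    T = int(round(rec.rate * window_s))
    h = T // 2
    if stride is None:
        stride = h
    if stride < 1:
        raise ValueError("stride must be >= 1")
    n = rec.n_samples
    if n < T:
        warnings.warn(f"recording {rec.subject_id!r} shorter than one window "
                      f"({n} < {T}); returning empty WindowSet")
        C = rec.n_channels
        return WindowSet(np.empty((0, C, T)), np.empty(0),
                         np.empty(0, dtype=object), h)
    starts = np.arange(0, n - T + 1, stride)
    X = np.stack([rec.signal[:, s:s + T] for s in starts])
    y = rec.speed[starts + h]
    sid = np.full(len(starts), rec.subject_id, dtype=object)
    return WindowSet(X=X, y=y, subject_ids=sid, h=h)


def windows_from_recordings(recs: list[UniformRecording], window_s: float = WINDOW_SECONDS,
                            stride: int | None = None) -> dict[str, WindowSet]:
    """Window each uniform recording, keyed by subject id."""
    return {r.subject_id: make_windows(r, window_s=window_s, stride=stride) for r in recs}
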