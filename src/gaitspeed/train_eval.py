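"""Training protocol and subject-wise evaluation.

The evaluation follows leave-one-subject-out cross-validation: for each fold
one subject's windows are held out entirely, the remaining subjects' windows
are split 85/15 into training and validation by contiguous blocks (random
windows would leak when windows overlap), augmentation is applied to the
training part only, training stops once the validation error has not
improved for ``patience`` consecutive epochs, and the held-out subject is
evaluated exactly once with the best-validation weights.  The headline
metric is the two-level mean absolute error: mean over subjects of the
per-subject mean |y − ŷ|, in km/h.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .augment import AugmentConfig, augment_batch
from .data_io import PLACEMENTS, RawRecording, SensorSelection, convert_units
from .model import (ALPHA_GRID, BETA_GRID, ENCODER_GRID, SINE_HIDDEN_GRID,
                    EarlyStopping, SVAERegressor)
from .preprocess import WindowSet, make_windows, resample_uniform

__all__ = ["HyperParams", "CVResult", "EarlyStopping", "split_train_val",
           "train_model", "random_search", "mean_absolute_error",
           "constant_mean_baseline", "loocv", "sensor_combination_study"]


@dataclass(frozen=True)
class HyperParams:
    """One point of the searchable configuration space."""

    decoder: str = "sine"
    conv_channels: int = 4
    hidden_size: int = 128
    hidden_depth: int = 1
    latent_len: int = 64
    n_sine: int = 10
    alpha: float = 0.1
    beta: float = 1e-5
    normalize_tau: bool = False
    n_conv_layers: int = 3
    kernel_size: int = 9
    conv_stride: int = 4
    lr: float = 1e-3
    lr_decay: float = 1.0
    weight_averaging: bool = False
    swa_start: float = 0.5
    batch_size: int = 64
    max_epochs: int = 50
    patience: int = 20
    seed: int = 0

    def make_estimator(self, **overrides) -> SVAERegressor:
        kwargs = asdict(self)
        kwargs.update(overrides)
        return SVAERegressor(**kwargs)


@dataclass
class CVResult:
    """Per-subject and pooled leave-one-subject-out errors."""

    per_subject_mae: dict[str, float]
    mean_mae: float
    predictions: dict[str, tuple[np.ndarray, np.ndarray]]  # subject -> (y, y_hat)
    histories: dict[str, dict] = field(default_factory=dict)
    hyperparams: HyperParams | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [{"subject": s, "mae_kmh": m, "n_windows": len(self.predictions[s][0])}
                for s, m in self.per_subject_mae.items()]
        rows.append({"subject": "mean", "mae_kmh": self.mean_mae,
                     "n_windows": sum(len(v[0]) for v in self.predictions.values())})
        return pd.DataFrame(rows)


def split_train_val(windows: WindowSet, frac: float = 0.85,
                    rng: np.random.Generator | None = None) -> tuple[WindowSet, WindowSet]:
    """Split into train/validation by contiguous per-subject blocks.

    For each subject a contiguous run of ~(1−frac) of its windows, at a
    random position, becomes validation; the rest train.  Contiguity matters
    because overlapping windows shared across the split would leak samples.
    """
    if len(windows) < 2:
        raise ValueError("need at least 2 windows to split")
    if not 0 < frac < 1:
        raise ValueError("frac must be in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(0)
    train_idx: list[int] = []
    val_idx: list[int] = []
    subjects = pd.unique(windows.subject_ids)
    for s in subjects:
        idx = np.flatnonzero(windows.subject_ids == s)
        n_val = int(round((1.0 - frac) * len(idx)))
        if n_val == 0 or n_val == len(idx):
            train_idx.extend(idx)
            continue
        start = int(rng.integers(0, len(idx) - n_val + 1))
        val_idx.extend(idx[start:start + n_val])
        train_idx.extend(np.delete(idx, np.arange(start, start + n_val)))
    if not val_idx:  # degenerate tiny sets: put one window in validation
        val_idx = [train_idx.pop()]
    return windows.subset(np.array(sorted(train_idx))), windows.subset(np.array(sorted(val_idx)))


def train_model(train: WindowSet, val: WindowSet, hp: HyperParams,
                patience: int | None = None) -> tuple[SVAERegressor, dict]:
    """Fit one estimator with early stopping on the validation windows."""
    if len(train) == 0 or len(val) == 0:
        raise ValueError("train and validation sets must be non-empty")
    est = hp.make_estimator(patience=patience if patience is not None else hp.patience)
    est.fit(train.X, train.y, X_val=val.X, y_val=val.y)
    return est, est.history_


def random_search(n_draws: int = 15, rng: np.random.Generator | None = None,
                  decoder: str = "sine",
                  grids: dict[str, list] | None = None,
                  **fixed) -> list[HyperParams]:
    """Uniform independent draws from the hyper-parameter grids.

    The default grids are the protocol's search ranges for the SVAE: encoder
    convolution channels {1,2,4,8,16}, hidden size {128,256,512}, hidden
    depth {1,2}, latent length {64,128,256}, sine components {10,50,100},
    α ∈ {0.1,…,1e-4} and β ∈ {1e-4,…,1e-7}.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    space = dict(ENCODER_GRID)
    space["alpha"] = ALPHA_GRID
    space["beta"] = BETA_GRID
    if decoder == "sine":
        space["n_sine"] = SINE_HIDDEN_GRID
    if grids:
        space.update(grids)
    draws = []
    for _ in range(n_draws):
        choice = {k: vals[rng.integers(len(vals))] for k, vals in space.items()}
        choice.update(fixed)
        draws.append(HyperParams(decoder=decoder, **choice))
    return draws


def mean_absolute_error(per_subject: dict[str, tuple[np.ndarray, np.ndarray]]) -> float:
    """Two-level MAE: mean over subjects of mean_t |y_t − ŷ_t| (km/h)."""
    if not per_subject:
        raise ValueError("need at least one subject")
    maes = []
    for s, (y, y_hat) in per_subject.items():
        y, y_hat = np.asarray(y, dtype=float), np.asarray(y_hat, dtype=float)
        if y.shape != y_hat.shape:
            raise ValueError(f"subject {s}: prediction/truth length mismatch")
        maes.append(np.mean(np.abs(y - y_hat)))
    return float(np.mean(maes))


def constant_mean_baseline(subject_windows: dict[str, WindowSet]) -> float:
    """MAE of predicting, per fold, the mean training speed (trivial floor)."""
    per_subject = {}
    for s, ws in subject_windows.items():
        train_y = np.concatenate([w.y for t, w in subject_windows.items() if t != s])
        per_subject[s] = (ws.y, np.full(len(ws), train_y.mean()))
    return mean_absolute_error(per_subject)


def loocv(subject_windows: dict[str, WindowSet], hp: HyperParams,
          augment_cfg: AugmentConfig | None = None,
          eval_windows: dict[str, WindowSet] | None = None,
          frac: float = 0.85, verbose: bool = False) -> CVResult:
    """Leave-one-subject-out evaluation.

    In each fold the test subject's windows never enter training or
    validation; augmentation (if configured) touches the training part only.
    ``eval_windows`` may hold a separately windowed copy of each subject for
    testing (typically non-overlapping, stride = T) while ``subject_windows``
    uses the overlapping training stride.
    """
    if eval_windows is None:
        eval_windows = subject_windows
    if set(eval_windows) != set(subject_windows):
        raise ValueError("eval_windows must cover the same subjects")
    subjects = list(subject_windows)
    if len(subjects) < 2:
        raise ValueError("leave-one-out needs at least 2 subjects")
    per_subject_mae: dict[str, float] = {}
    predictions: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    histories: dict[str, dict] = {}
    for fold, test_subject in enumerate(subjects):
        pool = WindowSet.concatenate(
            [subject_windows[s] for s in subjects if s != test_subject])
        rng = np.random.default_rng(hp.seed * 10007 + fold)
        train, val = split_train_val(pool, frac=frac, rng=rng)
        if augment_cfg is not None and augment_cfg.copies_per_window > 0:
            train = augment_batch(train, augment_cfg)
        est = hp.make_estimator(seed=hp.seed * 10007 + fold)
        est.fit(train.X, train.y, X_val=val.X, y_val=val.y)
        test = eval_windows[test_subject]
        y_hat = est.predict(test.X)
        per_subject_mae[test_subject] = float(np.mean(np.abs(test.y - y_hat)))
        predictions[test_subject] = (test.y.copy(), y_hat)
        histories[test_subject] = est.history_
        if verbose:
            print(f"fold {fold + 1}/{len(subjects)}: test={test_subject} "
                  f"MAE={per_subject_mae[test_subject]:.3f} km/h "
                  f"({est.n_epochs_} epochs)")
    return CVResult(per_subject_mae=per_subject_mae,
                    mean_mae=mean_absolute_error(predictions),
                    predictions=predictions, histories=histories, hyperparams=hp)


def sensor_combination_study(recordings: list[RawRecording], hp: HyperParams,
                             stride: int | None = None,
                             augment_cfg: AugmentConfig | None = None,
                             subsets: list[tuple[str, ...]] | None = None,
                             verbose: bool = False) -> pd.DataFrame:
    """LOOCV error for every non-empty subset of sensor placements.

    Uses one shared hyper-parameter setting across subsets (as when reusing
    the best single-sensor configuration).  Returns a table keyed by subset
    with the channel count and pooled MAE.
    """
    if subsets is None:
        subsets = [c for r in range(1, 4)
                   for c in itertools.combinations(PLACEMENTS, r)]
    converted = [r if r.units_converted else convert_units(r) for r in recordings]
    rows = []
    results: dict[tuple[str, ...], CVResult] = {}
    for subset in subsets:
        sel = SensorSelection(placements=subset)
        subject_windows = {}
        for rec in converted:
            uni = resample_uniform(rec, sel=sel)
            subject_windows[rec.subject_id] = make_windows(uni, stride=stride)
        res = loocv(subject_windows, hp, augment_cfg=augment_cfg, verbose=verbose)
        results[subset] = res
        rows.append({"placements": "+".join(subset),
                     "n_channels": sel.n_channels,
                     "mean_mae_kmh": res.mean_mae})
    frame = pd.DataFrame(rows)
    frame.attrs["results"] = results
    return frame
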