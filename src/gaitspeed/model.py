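"""Semi-supervised variational autoencoder for instantaneous gait-speed regression.

The model sees a raw multichannel IMU window ``X`` (C channels × T samples)
and learns jointly to (i) reconstruct it through a low-dimensional Gaussian
latent code and (ii) predict the speed label ``y`` from that code.  The
encoder is a stack of strided 1-D convolutions followed by dense layers,
emitting the posterior mean μ(X) and standard deviation σ(X).  A latent draw
uses the reparameterization z = μ + σ∘ε with ε ~ N(0, I).

Two decoders are provided:

* **sine decoder** — the window is reconstructed as a sum of H weighted
  sine waves whose channel-specific amplitudes A = W₁z, shared frequencies
  Ω = W₂z and phases Φ = W₃z are all linear in the latent code:

      X̂[c, τ] = Σ_k A[c, k] · sin(Ω_k · τ + Φ_k),

  with τ running over the T centered sample offsets.  This bakes the
  quasi-periodicity of gait into the decoder with a single layer.
* **LSTM–deconvolution decoder** — a conventional mirror of the encoder:
  a dense map to a short latent sequence, an LSTM, then transposed
  convolutions back up to T samples.

The joint training loss per window is

    L = α·‖y − h(z)‖² + ‖X − f(z)‖² + β·KL(N(μ, diag σ²) ‖ N(0, I)),

with the same latent draw z feeding both the prediction head h and the
decoder f.  α → 0, β → 0 recovers a plain autoencoder; large α recovers a
feed-forward regressor.

:class:`SVAERegressor` wraps all of this behind the scikit-learn estimator
protocol (``fit(X, y)`` / ``predict(X)``), standardizing channels and labels
internally and supporting early stopping on a validation set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .nn import Adam, Conv1d, ConvTranspose1d, LSTM, Linear, Module, Tensor

__all__ = [
    "EncoderConfig", "LatentCode", "Encoder", "SineDecoder", "LSTMCNNDecoder",
    "PredictionHead", "EarlyStopping", "reparameterize", "kl_gaussian",
    "feedforward_loss", "svae_loss", "SVAERegressor",
]

# hyper-parameter grids used by the random search
ENCODER_GRID = {
    "conv_channels": [1, 2, 4, 8, 16],
    "hidden_size": [128, 256, 512],
    "hidden_depth": [1, 2],
    "latent_len": [64, 128, 256],
}
SINE_HIDDEN_GRID = [10, 50, 100]
ALPHA_GRID = [0.1, 0.01, 0.001, 0.0001]
BETA_GRID = [1e-4, 1e-5, 1e-6, 1e-7]


@dataclass(frozen=True)
class EncoderConfig:
    conv_channels: int = 4
    hidden_size: int = 128
    hidden_depth: int = 1
    latent_len: int = 64
    n_conv_layers: int = 3
    kernel_size: int = 9
    conv_stride: int = 4


@dataclass(frozen=True)
class LatentCode:
    """Gaussian posterior parameters; sigma is stored via log σ, hence > 0."""

    mu: np.ndarray
    log_sigma: np.ndarray

    @property
    def sigma(self) -> np.ndarray:
        return np.exp(self.log_sigma)


def reparameterize(mu: np.ndarray, sigma: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """z = μ + σ∘ε elementwise; shapes must match."""
    mu, sigma, eps = np.asarray(mu), np.asarray(sigma), np.asarray(eps)
    if not (mu.shape == sigma.shape == eps.shape):
        raise ValueError(f"shape mismatch: mu {mu.shape}, sigma {sigma.shape}, eps {eps.shape}")
    return mu + sigma * eps


def kl_gaussian(mu: np.ndarray, sigma: np.ndarray) -> float:
    """Closed-form KL(N(μ, diag σ²) ‖ N(0, I)) = ½ Σ (μ² + σ² − 1 − ln σ²)."""
    mu, sigma = np.asarray(mu, dtype=float), np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    return float(0.5 * np.sum(mu ** 2 + sigma ** 2 - 1.0 - 2.0 * np.log(sigma)))


def feedforward_loss(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Squared-error prediction loss ‖y − ŷ‖²₂."""
    return float(np.sum((np.asarray(y, dtype=float) - np.asarray(y_hat, dtype=float)) ** 2))


def svae_loss(X: np.ndarray, y: float, X_hat: np.ndarray, y_hat: float,
              mu: np.ndarray, sigma: np.ndarray,
              alpha: float, beta: float) -> tuple[float, dict[str, float]]:
    """Joint loss for one window: α·pred + recon + β·KL, at one shared z.

    Returns the total and the three addends individually (for logging and
    for verifying the α→0, β→0 limits).  α = β = 0 is allowed and recovers
    the plain autoencoder loss.
    """
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be non-negative")
    pred = feedforward_loss(np.atleast_1d(y), np.atleast_1d(y_hat))
    recon = float(np.sum((np.asarray(X, dtype=float) - np.asarray(X_hat, dtype=float)) ** 2))
    kl = kl_gaussian(mu, sigma)
    total = alpha * pred + recon + beta * kl
    return total, {"prediction": pred, "reconstruction": recon, "kl": kl}


class EarlyStopping:
    """Stop when the monitored error has not improved for ``patience`` checks.

    ``update`` records one validation evaluation and returns True once the
    count of consecutive non-improving checks reaches the patience; the best
    value and its index are retained so the caller can restore that
    checkpoint.
    """

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best_value = np.inf
        self.best_index: int | None = None
        self.bad_count = 0
        self.n_checks = 0

    def update(self, value: float) -> bool:
        if value < self.best_value:
            self.best_value = value
            self.best_index = self.n_checks
            self.bad_count = 0
        else:
            self.bad_count += 1
        self.n_checks += 1
        return self.bad_count >= self.patience

    @property
    def improved(self) -> bool:
        """Whether the most recent check set a new best."""
        return self.best_index == self.n_checks - 1


# --------------------------------------------------------------------------
# network modules
# --------------------------------------------------------------------------

class Encoder(Module):
    """Strided-convolution + dense encoder emitting (μ, log σ)."""

    def __init__(self, n_channels: int, window_length: int, cfg: EncoderConfig,
                 rng: np.random.Generator):
        self.cfg = cfg
        self.convs: list[Conv1d] = []
        c_in, t = n_channels, window_length
        for _ in range(cfg.n_conv_layers):
            if t < cfg.kernel_size:
                raise ValueError(
                    f"window length {window_length} too short for "
                    f"{cfg.n_conv_layers} conv layers (kernel {cfg.kernel_size}, "
                    f"stride {cfg.conv_stride})")
            self.convs.append(Conv1d(c_in, cfg.conv_channels, cfg.kernel_size,
                                     cfg.conv_stride, rng))
            c_in = cfg.conv_channels
            t = Conv1d.out_length(t, cfg.kernel_size, cfg.conv_stride)
        self.flat_dim = c_in * t
        self.hidden: list[Linear] = []
        d = self.flat_dim
        for _ in range(cfg.hidden_depth):
            self.hidden.append(Linear(d, cfg.hidden_size, rng))
            d = cfg.hidden_size
        self.mu_head = Linear(d, cfg.latent_len, rng)
        self.log_sigma_head = Linear(d, cfg.latent_len, rng)
        # start with a near-unit posterior scale
        self.log_sigma_head.bias.data[:] = -1.0

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        if not np.all(np.isfinite(x.data)):
            raise ValueError("encoder input must be finite")
        h = x
        for conv in self.convs:
            h = conv(h).relu()
        B = h.shape[0]
        h = h.reshape(B, self.flat_dim)
        for lin in self.hidden:
            h = lin(h).relu()
        return self.mu_head(h), self.log_sigma_head(h)

    def encode(self, X: np.ndarray) -> LatentCode:
        """Deterministic forward map for one (C, T) window or a (B, C, T) batch."""
        X = np.asarray(X, dtype=float)
        single = X.ndim == 2
        if single:
            X = X[None]
        mu, log_sigma = self.forward(Tensor(X))
        if single:
            return LatentCode(mu.data[0], log_sigma.data[0])
        return LatentCode(mu.data, log_sigma.data)


class SineDecoder(Module):
    """Weighted-sine-wave decoder: X̂ = (W₁z) ∘ sin((W₂z)·τ + W₃z).

    ``n_components`` (H) is the decoder's hidden-layer size: per window the
    latent code generates H sinusoids with shared frequencies/phases and
    channel-specific amplitudes, summed per channel.  τ is the vector of
    centered sample offsets −T/2 … T/2−1 (optionally normalized to [−1, 1)).
    ``affine=False`` drops the bias terms so that z = 0 maps to the all-zero
    window.
    """

    def __init__(self, latent_len: int, n_channels: int, window_length: int,
                 n_components: int, rng: np.random.Generator,
                 affine: bool = True, normalize_tau: bool = False):
        self.C = n_channels
        self.T = window_length
        self.H = n_components
        self.normalize_tau = normalize_tau
        h = window_length // 2
        tau = np.arange(window_length, dtype=float) - h
        if normalize_tau:
            tau = tau / h
        self._tau = tau
        self.amp_map = Linear(latent_len, n_channels * n_components, rng, bias=affine)
        self.freq_map = Linear(latent_len, n_components, rng, bias=affine)
        self.phase_map = Linear(latent_len, n_components, rng, bias=affine)
        # frequency-spread initialization: start the components across the
        # band human gait occupies (fundamental ~0.7 Hz slow walk up to the
        # ~12 Hz harmonics of fast running) instead of clustered near zero,
        # so reconstruction gradients are informative from the first step.
        # With τ normalized to [−1, 1) over a 2 s window, ω = 2π·f[Hz].
        scale = 1.0 if normalize_tau else 2.0 / window_length
        self.freq_map.weight.data *= scale
        if affine:
            f_init = np.linspace(0.75, 12.0, n_components)
            self.freq_map.bias.data[:] = 2.0 * np.pi * f_init * scale

    def forward(self, z: Tensor) -> Tensor:
        B = z.shape[0]
        A = self.amp_map(z).reshape(B, self.C, self.H)
        omega = self.freq_map(z).reshape(B, self.H, 1)
        phi = self.phase_map(z).reshape(B, self.H, 1)
        ang = omega * Tensor(self._tau) + phi          # (B, H, T)
        return A @ ang.sin()                           # (B, C, T)

    def decode(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        single = z.ndim == 1
        out = self.forward(Tensor(z[None] if single else z)).data
        return out[0] if single else out

    def set_constant(self, A: np.ndarray, omega: np.ndarray, phi: np.ndarray) -> None:
        """Pin the decoder to fixed sinusoid parameters regardless of z.

        Zeroes the linear weights and writes (A, Ω, Φ) into the biases; the
        decoder then emits Σ_k A[c,k]·sin(Ω_k τ + Φ_k) for every latent code.
        Requires ``affine=True``.
        """
        A = np.asarray(A, dtype=float).reshape(self.C * self.H)
        for lin in (self.amp_map, self.freq_map, self.phase_map):
            if lin.bias is None:
                raise ValueError("set_constant requires an affine decoder")
            lin.weight.data[:] = 0.0
        self.amp_map.bias.data[:] = A
        self.freq_map.bias.data[:] = np.asarray(omega, dtype=float)
        self.phase_map.bias.data[:] = np.asarray(phi, dtype=float)


class LSTMCNNDecoder(Module):
    """Conventional decoder: dense → short sequence → LSTM → deconvolutions."""

    def __init__(self, latent_len: int, n_channels: int, window_length: int,
                 cfg: EncoderConfig, rng: np.random.Generator):
        self.C = n_channels
        self.T = window_length
        k = cfg.conv_channels
        # smallest seed length whose deconv pyramid reaches >= T
        t0 = window_length
        for _ in range(cfg.n_conv_layers):
            t0 = max(1, -(-(t0 - cfg.kernel_size) // cfg.conv_stride) + 1)
        self.t0 = max(t0, 2)
        self.seed_map = Linear(latent_len, k * self.t0, rng)
        self.lstm = LSTM(k, k, rng)
        self.deconvs: list[ConvTranspose1d] = []
        for i in range(cfg.n_conv_layers):
            c_out = n_channels if i == cfg.n_conv_layers - 1 else k
            self.deconvs.append(ConvTranspose1d(k if i == 0 else k, c_out,
                                                cfg.kernel_size, cfg.conv_stride, rng))
        self.k = k

    def forward(self, z: Tensor) -> Tensor:
        B = z.shape[0]
        h = self.seed_map(z).reshape(B, self.t0, self.k)
        h = self.lstm(h)                               # (B, t0, k)
        h = h.swapaxes(1, 2)                           # (B, k, t0)
        for i, dec in enumerate(self.deconvs):
            h = dec(h)
            if i < len(self.deconvs) - 1:
                h = h.relu()
        L = h.shape[2]
        if L < self.T:
            raise ValueError(f"decoder produced {L} < {self.T} samples")
        lo = (L - self.T) // 2
        return h[:, :, lo:lo + self.T]

    def decode(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        single = z.ndim == 1
        out = self.forward(Tensor(z[None] if single else z)).data
        return out[0] if single else out


class PredictionHead(Module):
    """Latent-to-speed regressor: one hidden dense layer, scalar output."""

    def __init__(self, latent_len: int, rng: np.random.Generator, hidden: int = 32):
        self.lin1 = Linear(latent_len, hidden, rng)
        self.lin2 = Linear(hidden, 1, rng)

    def forward(self, z: Tensor) -> Tensor:
        return self.lin2(self.lin1(z).relu())[:, 0]

    def predict(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        single = z.ndim == 1
        out = self.forward(Tensor(z[None] if single else z)).data
        return float(out[0]) if single else out


# --------------------------------------------------------------------------
# estimator
# --------------------------------------------------------------------------

class _SVAENetwork(Module):
    def __init__(self, n_channels: int, window_length: int, cfg: EncoderConfig,
                 decoder: str, n_sine: int, rng: np.random.Generator,
                 normalize_tau: bool):
        self.encoder = Encoder(n_channels, window_length, cfg, rng)
        if decoder == "sine":
            self.decoder = SineDecoder(cfg.latent_len, n_channels, window_length,
                                       n_sine, rng, normalize_tau=normalize_tau)
        elif decoder == "lstm_cnn":
            self.decoder = LSTMCNNDecoder(cfg.latent_len, n_channels, window_length,
                                          cfg, rng)
        else:
            raise ValueError(f"unknown decoder kind {decoder!r}")
        self.head = PredictionHead(cfg.latent_len, rng)


class SVAERegressor(BaseEstimator, RegressorMixin):
    """Gait-speed regressor built on the semi-supervised VAE.

    Parameters mirror the searchable hyper-parameters: ``decoder`` selects the
    sine or LSTM–deconvolution reconstruction path, ``alpha`` weights the
    prediction term and ``beta`` the KL term of the joint loss.  Channels and
    labels are standardized internally on the training data.  ``fit`` accepts
    an optional validation set for early stopping (patience counted in epochs,
    best-validation weights restored).

    Fitted attributes: ``network_``, ``channel_mean_``, ``channel_std_``,
    ``y_mean_``, ``y_std_``, ``history_``, ``n_epochs_``.
    """

    def __init__(self, decoder: str = "sine", conv_channels: int = 4,
                 hidden_size: int = 128, hidden_depth: int = 1,
                 latent_len: int = 64, n_sine: int = 10,
                 alpha: float = 0.1, beta: float = 1e-5,
                 n_conv_layers: int = 3, kernel_size: int = 9, conv_stride: int = 4,
                 normalize_tau: bool = False,
                 lr: float = 1e-3, lr_decay: float = 1.0, batch_size: int = 64,
                 max_epochs: int = 50, patience: int = 20,
                 weight_averaging: bool = False, swa_start: float = 0.5,
                 seed: int = 0):
        self.decoder = decoder
        self.conv_channels = conv_channels
        self.hidden_size = hidden_size
        self.hidden_depth = hidden_depth
        self.latent_len = latent_len
        self.n_sine = n_sine
        self.alpha = alpha
        self.beta = beta
        self.n_conv_layers = n_conv_layers
        self.kernel_size = kernel_size
        self.conv_stride = conv_stride
        self.normalize_tau = normalize_tau
        self.lr = lr
        self.lr_decay = lr_decay
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.weight_averaging = weight_averaging
        self.swa_start = swa_start
        self.seed = seed

    # -- internals ---------------------------------------------------------
    def _encoder_config(self) -> EncoderConfig:
        return EncoderConfig(conv_channels=self.conv_channels,
                             hidden_size=self.hidden_size,
                             hidden_depth=self.hidden_depth,
                             latent_len=self.latent_len,
                             n_conv_layers=self.n_conv_layers,
                             kernel_size=self.kernel_size,
                             conv_stride=self.conv_stride)

    def _standardize_X(self, X: np.ndarray) -> np.ndarray:
        return (X - self.channel_mean_[None, :, None]) / self.channel_std_[None, :, None]

    def _batch_loss(self, Xs: np.ndarray, ys: np.ndarray,
                    eps: np.ndarray) -> tuple[Tensor, dict[str, float]]:
        net = self.network_
        mu, log_sigma = net.encoder(Tensor(Xs))
        sigma = log_sigma.exp()
        z = mu + sigma * Tensor(eps)
        X_hat = net.decoder(z)
        y_hat = net.head(z)
        B, C, T = Xs.shape
        # reconstruction uses mean reduction over window elements (the usual
        # MSE convention); with standardized channels this puts the α-weighted
        # prediction term and the reconstruction term on comparable scales
        recon = ((Tensor(Xs) - X_hat) ** 2).sum() * (1.0 / (B * C * T))
        pred = ((Tensor(ys) - y_hat) ** 2).sum() * (1.0 / B)
        kl = ((mu ** 2 + sigma ** 2 - 1.0 - 2.0 * log_sigma) * 0.5).sum() * (1.0 / B)
        total = self.alpha * pred + recon + self.beta * kl
        comps = {"prediction": float(pred.data), "reconstruction": float(recon.data),
                 "kl": float(kl.data)}
        return total, comps

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 3:
            raise ValueError(f"X must be (n_windows, n_channels, window_length), got {X.shape}")
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise ValueError("training data must be finite")
        n, C, T = X.shape
        self._window_length_ = T
        rng = np.random.default_rng(self.seed)

        self.channel_mean_ = X.mean(axis=(0, 2))
        std = X.std(axis=(0, 2))
        self.channel_std_ = np.where(std > 1e-12, std, 1.0)
        self.y_mean_ = float(y.mean())
        self.y_std_ = float(y.std()) if y.std() > 1e-12 else 1.0
        self.y_min_, self.y_max_ = float(y.min()), float(y.max())

        Xs = self._standardize_X(X)
        ys = (y - self.y_mean_) / self.y_std_
        has_val = X_val is not None and y_val is not None and len(X_val) > 0
        if has_val:
            Xv = self._standardize_X(np.asarray(X_val, dtype=float))
            yv = (np.asarray(y_val, dtype=float) - self.y_mean_) / self.y_std_

        self.network_ = _SVAENetwork(C, T, self._encoder_config(), self.decoder,
                                     self.n_sine, rng, self.normalize_tau)
        params = self.network_.parameters()
        opt = Adam(params, lr=self.lr)
        L = self.latent_len

        history = {"train_loss": [], "val_mse": [],
                   "prediction": [], "reconstruction": [], "kl": []}
        best_state = self.network_.state_dict()
        stopper = EarlyStopping(self.patience)
        # tail weight averaging (Polyak/SWA): running mean of the weights
        # over the later epochs; flattens the solution found by a short run
        swa_state: list[np.ndarray] | None = None
        swa_count = 0
        swa_from = int(np.ceil(self.swa_start * self.max_epochs))
        for epoch in range(self.max_epochs):
            opt.lr = self.lr * self.lr_decay ** epoch
            order = rng.permutation(n)
            epoch_loss = 0.0
            comps_sum = {"prediction": 0.0, "reconstruction": 0.0, "kl": 0.0}
            n_batches = 0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                eps = rng.standard_normal((len(idx), L))
                opt.zero_grad()
                loss, comps = self._batch_loss(Xs[idx], ys[idx], eps)
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"training diverged at epoch {epoch}: loss={loss.data!r}, "
                        f"components={comps}")
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data)
                for k in comps_sum:
                    comps_sum[k] += comps[k]
                n_batches += 1
            history["train_loss"].append(epoch_loss / n_batches)
            for k in comps_sum:
                history[k].append(comps_sum[k] / n_batches)

            if self.weight_averaging and epoch >= swa_from:
                cur = self.network_.state_dict()
                if swa_state is None:
                    swa_state = cur
                else:
                    swa_state = [(a * swa_count + c) / (swa_count + 1)
                                 for a, c in zip(swa_state, cur)]
                swa_count += 1

            if has_val:
                val_mse = float(np.mean((self._predict_standardized(Xv) - yv) ** 2))
                history["val_mse"].append(val_mse)
                stop = stopper.update(val_mse)
                if stopper.improved:
                    best_state = self.network_.state_dict()
                if stop:
                    break
        if has_val:
            self.network_.load_state_dict(best_state)
            if self.weight_averaging and swa_state is not None:
                # adopt the averaged weights only if validation agrees
                best_val = float(np.mean((self._predict_standardized(Xv) - yv) ** 2))
                self.network_.load_state_dict(swa_state)
                swa_val = float(np.mean((self._predict_standardized(Xv) - yv) ** 2))
                history["swa_val_mse"] = swa_val
                if swa_val >= best_val:
                    self.network_.load_state_dict(best_state)
        elif self.weight_averaging and swa_state is not None:
            self.network_.load_state_dict(swa_state)
        self.history_ = history
        self.n_epochs_ = len(history["train_loss"])
        return self

    def _predict_standardized(self, Xs: np.ndarray) -> np.ndarray:
        preds = []
        for start in range(0, len(Xs), self.batch_size):
            mu, _ = self.network_.encoder(Tensor(Xs[start:start + self.batch_size]))
            preds.append(self.network_.head(Tensor(mu.data)).data)
        return np.concatenate(preds)

    def predict(self, X) -> np.ndarray:
        """Predict speed (km/h) from windows, using the posterior mean z = μ.

        Predictions are clipped to the training label range: speeds outside
        the range seen in training are extrapolations the model has no
        support for.
        """
        if not hasattr(self, "network_"):
            raise RuntimeError("estimator is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        Xs = self._standardize_X(X)
        y = self._predict_standardized(Xs) * self.y_std_ + self.y_mean_
        return np.clip(y, self.y_min_, self.y_max_)

    def encode(self, X) -> LatentCode:
        """Posterior (μ, σ) of windows; requires a fitted estimator."""
        if not hasattr(self, "network_"):
            raise RuntimeError("estimator is not fitted")
        X = np.asarray(X, dtype=float)
        single = X.ndim == 2
        Xs = self._standardize_X(X[None] if single else X)
        code = self.network_.encoder.encode(Xs)
        if single:
            return LatentCode(code.mu[0], code.log_sigma[0])
        return code

    # -- checkpointing -----------------------------------------------------
    def save(self, path: str) -> None:
        """Serialize weights + the full hyper-parameter record to ``.npz``."""
        if not hasattr(self, "network_"):
            raise RuntimeError("estimator is not fitted")
        state = self.network_.state_dict()
        meta = dict(self.get_params())
        np.savez(path,
                 hyperparams=json.dumps(meta),
                 n_arrays=len(state),
                 channel_mean=self.channel_mean_, channel_std=self.channel_std_,
                 y_mean=self.y_mean_, y_std=self.y_std_,
                 y_min=self.y_min_, y_max=self.y_max_,
                 n_channels=self.channel_mean_.shape[0],
                 window_length=self._window_length_,
                 **{f"p{i}": a for i, a in enumerate(state)})

    @classmethod
    def load(cls, path: str) -> "SVAERegressor":
        with np.load(path, allow_pickle=False) as data:
            est = cls(**json.loads(str(data["hyperparams"])))
            est.channel_mean_ = data["channel_mean"]
            est.channel_std_ = data["channel_std"]
            est.y_mean_ = float(data["y_mean"])
            est.y_std_ = float(data["y_std"])
            est.y_min_ = float(data["y_min"])
            est.y_max_ = float(data["y_max"])
            C = int(data["n_channels"])
            T = int(data["window_length"])
            rng = np.random.default_rng(est.seed)
            est.network_ = _SVAENetwork(C, T, est._encoder_config(), est.decoder,
                                        est.n_sine, rng, est.normalize_tau)
            state = [data[f"p{i}"] for i in range(int(data["n_arrays"]))]
            est.network_.load_state_dict(state)
            est._window_length_ = T
        return est
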