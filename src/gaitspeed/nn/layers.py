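"""Neural-network building blocks on top of the autodiff core.

Modules own :class:`~gaitspeed.nn.autodiff.Tensor` parameters (created with
``requires_grad=True``) and expose ``parameters()`` for the optimizer plus
``state_dict``/``load_state_dict`` for checkpointing.  Initialization is
Glorot-uniform, drawn from an explicit ``numpy.random.Generator`` so that a
model built twice from the same seed is bit-identical.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, conv1d, conv_transpose1d

__all__ = ["Module", "Linear", "Conv1d", "ConvTranspose1d", "LSTM", "Sequential", "ReLU"]


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape)


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError(f"state has {len(state)} arrays, module has {len(params)} parameters")
        for p, arr in zip(params, state):
            if p.data.shape != arr.shape:
                raise ValueError(f"shape mismatch: {p.data.shape} vs {arr.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        self.weight = Tensor(_glorot(rng, (in_features, out_features), in_features, out_features),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.modules:
            x = m(x)
        return x


class Conv1d(Module):
    """Valid strided 1-D convolution, input (B, C_in, T)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int, rng: np.random.Generator):
        fan_in = in_channels * kernel_size
        fan_out = out_channels * kernel_size
        self.weight = Tensor(_glorot(rng, (out_channels, in_channels, kernel_size), fan_in, fan_out),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)
        self.stride = stride
        self.kernel_size = kernel_size

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, self.stride)

    @staticmethod
    def out_length(t: int, kernel_size: int, stride: int) -> int:
        return (t - kernel_size) // stride + 1


class ConvTranspose1d(Module):
    """Transposed strided 1-D convolution, input (B, C_in, T)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int, rng: np.random.Generator):
        fan_in = in_channels * kernel_size
        fan_out = out_channels * kernel_size
        self.weight = Tensor(_glorot(rng, (in_channels, out_channels, kernel_size), fan_in, fan_out),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)
        self.stride = stride
        self.kernel_size = kernel_size

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose1d(x, self.weight, self.bias, self.stride)

    @staticmethod
    def out_length(t: int, kernel_size: int, stride: int) -> int:
        return (t - 1) * stride + kernel_size


class LSTM(Module):
    """Single-layer LSTM returning the full hidden-state sequence.

    Input (B, T, F), output (B, T, H).  Gates follow the standard equations
    with a single packed weight per direction; forget-gate bias starts at 1.
    """

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        self.hidden_size = hidden_size
        g = 4 * hidden_size
        self.w_ih = Tensor(_glorot(rng, (input_size, g), input_size, g), requires_grad=True)
        self.w_hh = Tensor(_glorot(rng, (hidden_size, g), hidden_size, g), requires_grad=True)
        b = np.zeros(g)
        b[hidden_size:2 * hidden_size] = 1.0  # forget gate
        self.bias = Tensor(b, requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        H = self.hidden_size
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        outs: list[Tensor] = []
        for t in range(T):
            xt = x[:, t, :]
            gates = xt @ self.w_ih + h @ self.w_hh + self.bias
            i = gates[:, 0:H].sigmoid()
            f = gates[:, H:2 * H].sigmoid()
            g = gates[:, 2 * H:3 * H].tanh()
            o = gates[:, 3 * H:4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outs.append(h.reshape(B, 1, H))
        return concat(outs, axis=1)
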