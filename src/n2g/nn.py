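"""Neural-network building blocks over the autograd engine.

Layers mirror the conventions of mainstream deep-learning frameworks
(fan-in-scaled uniform init, batch-norm running statistics, stacked
bidirectional LSTM) but run on plain NumPy so the pipeline is fully
self-contained and CPU-only.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autograd import Tensor, concat, stack


class Parameter(Tensor):
    """A trainable tensor; `is_bias` marks additive (bias-like) parameters."""

    __slots__ = ("is_bias",)

    def __init__(self, data, is_bias: bool = False):
        super().__init__(data, requires_grad=True)
        self.is_bias = is_bias


class Module:
    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, arr in self._buffers().items():
            state[name] = arr.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        buffers = self._buffers()
        for name, arr in state.items():
            if name in params:
                params[name].data = np.asarray(arr, dtype=np.float64).copy()
            elif name in buffers:
                buffers[name][...] = np.asarray(arr, dtype=np.float64)
            else:
                raise KeyError(f"unexpected state entry {name!r}")

    def _buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {}
        for name in getattr(self, "_buffer_names", ()):
            out[prefix + name] = getattr(self, name)
        for name, m in self._modules.items():
            out.update(m._buffers(prefix + name + "."))
        return out

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _uniform(rng: np.random.Generator, shape, bound: float) -> np.ndarray:
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool,
                 rng: np.random.Generator):
        super().__init__()
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Parameter(_uniform(rng, (out_features, in_features), bound))
        if bias:
            self.bias = Parameter(_uniform(rng, (out_features,), bound), is_bias=True)
        else:
            self.bias = None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight.transpose()
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv1d(Module):
    """Grouped 1-D convolution, stride 1, never biased.

    `padding="same"` zero-pads so the time length is preserved.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 groups: int, rng: np.random.Generator,
                 padding: str = "valid"):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must divide groups")
        fan_in = (in_channels // groups) * kernel_size
        bound = 1.0 / np.sqrt(fan_in)
        self.weight = Parameter(
            _uniform(rng, (out_channels, in_channels // groups, kernel_size), bound))
        self.groups = groups
        if padding == "same":
            self.pad = ((kernel_size - 1) // 2, kernel_size // 2)
        elif padding == "valid":
            self.pad = (0, 0)
        else:
            raise ValueError("padding must be 'same' or 'valid'")

    def forward(self, x: Tensor) -> Tensor:
        return x.conv1d(self.weight, groups=self.groups, pad=self.pad)


class BatchNorm1d(Module):
    """Batch norm over (batch, time) per channel; scale-only (no beta shift).

    The additive shift is a bias-like parameter and is therefore omitted:
    only the squeeze-and-excitation block may carry biases.
    """

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, num_features: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        super().__init__()
        self.weight = Parameter(np.ones(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        # x: [N, C, L]
        if self.training:
            mean = x.mean(axis=(0, 2), keepdims=True)
            centered = x - mean
            var = centered.square().mean(axis=(0, 2), keepdims=True)
            n = x.shape[0] * x.shape[2]
            with np.errstate(invalid="ignore"):
                self.running_mean *= (1 - self.momentum)
                self.running_mean += self.momentum * mean.data.reshape(-1)
                unbiased = var.data.reshape(-1) * (n / max(n - 1, 1))
                self.running_var *= (1 - self.momentum)
                self.running_var += self.momentum * unbiased
            xhat = centered / (var + self.eps).sqrt()
        else:
            mean = self.running_mean.reshape(1, -1, 1)
            std = np.sqrt(self.running_var + self.eps).reshape(1, -1, 1)
            xhat = (x - Tensor(mean)) * Tensor(1.0 / std)
        return xhat * self.weight.reshape(1, -1, 1)


class LSTMCellParams(Module):
    """Weights of one LSTM direction (gate order: input, forget, cell, output)."""

    def __init__(self, input_size: int, hidden_size: int, bias: bool,
                 rng: np.random.Generator):
        super().__init__()
        bound = 1.0 / np.sqrt(hidden_size)
        self.w_ih = Parameter(_uniform(rng, (4 * hidden_size, input_size), bound))
        self.w_hh = Parameter(_uniform(rng, (4 * hidden_size, hidden_size), bound))
        if bias:
            self.b = Parameter(_uniform(rng, (4 * hidden_size,), bound), is_bias=True)
        else:
            self.b = None
        self.hidden_size = hidden_size

    def run(self, xs: list[Tensor]) -> list[Tensor]:
        """Run over a list of [N, input_size] steps; returns hidden states."""
        n = xs[0].shape[0]
        hs = Tensor(np.zeros((n, self.hidden_size)))
        cs = Tensor(np.zeros((n, self.hidden_size)))
        h = self.hidden_size
        outputs = []
        w_ih_t = self.w_ih.transpose()
        w_hh_t = self.w_hh.transpose()
        for x in xs:
            gates = x @ w_ih_t + hs @ w_hh_t
            if self.b is not None:
                gates = gates + self.b
            i = gates[:, 0 * h:1 * h].sigmoid()
            f = gates[:, 1 * h:2 * h].sigmoid()
            g = gates[:, 2 * h:3 * h].tanh()
            o = gates[:, 3 * h:4 * h].sigmoid()
            cs = f * cs + i * g
            hs = o * cs.tanh()
            outputs.append(hs)
        return outputs


class BiLSTM(Module):
    """Stacked bidirectional LSTM: [N, C, T] -> [N, 2*hidden, T]."""

    def __init__(self, input_size: int, hidden_size: int, num_layers: int,
                 bias: bool, rng: np.random.Generator):
        super().__init__()
        self.num_layers = num_layers
        self.hidden_size = hidden_size
        for layer in range(num_layers):
            in_size = input_size if layer == 0 else 2 * hidden_size
            setattr(self, f"fwd{layer}",
                    LSTMCellParams(in_size, hidden_size, bias, rng))
            setattr(self, f"bwd{layer}",
                    LSTMCellParams(in_size, hidden_size, bias, rng))

    def forward(self, x: Tensor) -> Tensor:
        t_len = x.shape[2]
        steps = [x[:, :, t] for t in range(t_len)]
        for layer in range(self.num_layers):
            fwd: LSTMCellParams = getattr(self, f"fwd{layer}")
            bwd: LSTMCellParams = getattr(self, f"bwd{layer}")
            f_out = fwd.run(steps)
            b_out = bwd.run(steps[::-1])[::-1]
            steps = [concat([f, b], axis=1) for f, b in zip(f_out, b_out)]
        return stack(steps, axis=2)  # [N, 2*hidden, T]


class Adam:
    """ADAM with conventional moment defaults; only the learning rate is tuned."""

    def __init__(self, params: list[Parameter], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
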