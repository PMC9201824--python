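"""Layer modules built on the autograd core.

A tiny module system in the familiar style: a :class:`Module` owns
:class:`Parameter` tensors and child modules, exposes ``parameters()`` /
``named_parameters()`` for the optimiser and checkpointing, and a
``train()`` / ``eval()`` mode switch that controls batch-norm statistics and
dropout.  Layers that draw randomness at forward time (spatial dropout) pull
it from a generator box shared across the whole network so a single seed
drives a training run.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class RngBox:
    """Shared mutable holder for the forward-time random generator."""

    def __init__(self, generator: np.random.Generator | None = None):
        self.generator = generator or np.random.default_rng(0)

    def reseed(self, seed) -> None:
        self.generator = np.random.default_rng(seed)


class Module:
    def __init__(self):
        self.training = True

    # -- traversal ----------------------------------------------------------
    def children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, ModuleList):
                for i, child in enumerate(value):
                    yield f"{name}.{i}", child

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self.children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self.children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    # -- persistence --------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray) and name.startswith("running_"):
                yield prefix + name, value
        for name, child in self.children():
            yield from child.named_buffers(prefix + name + ".")

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            if key in params:
                if params[key].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for parameter {key!r}")
                params[key].data = np.array(value, dtype=params[key].data.dtype)
            elif key in buffers:
                buffers[key][...] = value
            else:
                raise KeyError(f"unexpected key in state dict: {key!r}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(list):
    """Plain list of modules that participates in parameter traversal."""


def _he_init(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    std = np.sqrt(2.0 / max(fan_in, 1))
    return rng.normal(0.0, std, size=shape).astype(dtype)


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size,
        rng: np.random.Generator,
        stride=1,
        padding=0,
        dilation=1,
        bias: bool = True,
        dtype=np.float32,
    ):
        super().__init__()
        kh, kw = (kernel_size, kernel_size) if np.isscalar(kernel_size) else kernel_size
        self.stride, self.padding, self.dilation = stride, padding, dilation
        fan_in = in_channels * kh * kw
        self.weight = Parameter(_he_init(rng, (out_channels, in_channels, kh, kw), fan_in, dtype))
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(
            x, self.weight, self.bias, stride=self.stride, padding=self.padding, dilation=self.dilation
        )


class ConvTranspose2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride=2,
        padding=1,
        output_padding=1,
        bias: bool = True,
        dtype=np.float32,
    ):
        super().__init__()
        self.stride, self.padding, self.output_padding = stride, padding, output_padding
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(
            _he_init(rng, (in_channels, out_channels, kernel_size, kernel_size), fan_in, dtype)
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv_transpose2d(
            x,
            self.weight,
            self.bias,
            stride=self.stride,
            padding=self.padding,
            output_padding=self.output_padding,
        )


class BatchNorm2d(Module):
    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.gamma = Parameter(np.ones(num_features, dtype=dtype))
        self.beta = Parameter(np.zeros(num_features, dtype=dtype))
        self.running_mean = np.zeros(num_features, dtype=dtype)
        self.running_var = np.ones(num_features, dtype=dtype)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: Tensor) -> Tensor:
        return ag.batch_norm2d(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            training=self.training,
            momentum=self.momentum,
            eps=self.eps,
        )


class PReLU(Module):
    """Parametric ReLU; a single shared slope by default, per-channel optional."""

    def __init__(self, num_parameters: int = 1, init: float = 0.25, dtype=np.float32):
        super().__init__()
        self.alpha = Parameter(np.full(num_parameters, init, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return ag.prelu(x, self.alpha)


class Dropout2d(Module):
    def __init__(self, p: float, rng_box: RngBox):
        super().__init__()
        self.p = float(p)
        self.rng_box = rng_box

    def forward(self, x: Tensor) -> Tensor:
        return ag.dropout2d(x, self.p, self.rng_box.generator, self.training)


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.layers = ModuleList(modules)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
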