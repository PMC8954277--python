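"""Trainable layers: dense, batch-norm, 1-D convolution, inception blocks.

All layers follow the lineage of the architectures they come from: He-normal
initialization, ReLU nonlinearities, and batch normalization after every
convolution or dense layer except logit layers.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class providing parameter collection and train/eval switching."""

    def __init__(self) -> None:
        self.training = True

    def _children(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
        for child in self._children():
            params.extend(child.parameters())
        return params

    def buffers(self) -> list[np.ndarray]:
        out = []
        for name, value in self.__dict__.items():
            if isinstance(value, np.ndarray) and name.startswith("running_"):
                out.append(value)
        for child in self._children():
            out.extend(child.buffers())
        return out

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for child in self._children():
            child.set_training(flag)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Dense(Module):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / c_in), size=(c_in, c_out))
        self.weight = Tensor(w.astype(dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=dtype), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ag.matmul(x, self.weight) + self.bias


class BatchNorm(Module):
    """Normalize over all axes but the last (channel) axis."""

    def __init__(self, channels: int, momentum: float = 0.9,
                 eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.gamma = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        axes = tuple(range(x.ndim - 1))
        if self.training:
            mu = ag.mean_(x, axis=axes, keepdims=True)
            centered = x - mu
            var = ag.mean_(ag.mul(centered, centered), axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean[:] = (m * self.running_mean
                                    + (1 - m) * mu.data.reshape(-1))
            self.running_var[:] = (m * self.running_var
                                   + (1 - m) * var.data.reshape(-1))
            inv = ag.power(var + np.asarray(self.eps, dtype=x.data.dtype), -0.5)
            xhat = ag.mul(centered, inv)
        else:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean) * inv.astype(x.data.dtype)
        return ag.mul(xhat, self.gamma) + self.beta


class Conv1d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, dilation: int = 1,
                 dtype=np.float32):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / (kernel * c_in)),
                       size=(kernel, c_in, c_out))
        self.weight = Tensor(w.astype(dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=dtype), requires_grad=True)
        self.dilation = dilation

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv1d(x, self.weight, self.bias, dilation=self.dilation)


class ConvBNRelu(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, dilation: int = 1):
        super().__init__()
        self.conv = Conv1d(c_in, c_out, kernel, rng, dilation)
        self.bn = BatchNorm(c_out)

    def forward(self, x: Tensor) -> Tensor:
        return ag.relu(self.bn(self.conv(x)))


class Inception1d(Module):
    """Parallel 1-D convolutions (kernels 1/3/5/7 by default), outputs concatenated."""

    def __init__(self, c_in: int, filters_per_branch: int,
                 rng: np.random.Generator,
                 kernels: tuple[int, ...] = (1, 3, 5, 7), dilation: int = 1):
        super().__init__()
        self.branches = [ConvBNRelu(c_in, filters_per_branch, k, rng, dilation)
                         for k in kernels]
        self.c_out = filters_per_branch * len(kernels)

    def forward(self, x: Tensor) -> Tensor:
        return ag.concat([b(x) for b in self.branches], axis=-1)


class PointwiseMLP(Module):
    """Shared per-point MLP: dense + BN + ReLU stages applied on the last axis."""

    def __init__(self, c_in: int, widths: list[int], rng: np.random.Generator):
        super().__init__()
        self.stages = []
        prev = c_in
        for w in widths:
            self.stages.append(Dense(prev, w, rng))
            self.stages.append(BatchNorm(w))
            prev = w
        self.c_out = prev

    def forward(self, x: Tensor) -> Tensor:
        for i in range(0, len(self.stages), 2):
            x = ag.relu(self.stages[i + 1](self.stages[i](x)))
        return x


def max_pool2(x: Tensor) -> Tensor:
    """Length-2 max pooling along axis 1; truncates an odd trailing row."""
    b, n, c = x.shape
    if n < 2:
        return x
    if n % 2:
        x = ag.getitem(x, (slice(None), slice(0, n - 1), slice(None)))
        n -= 1
    x = ag.reshape(x, (b, n // 2, 2, c))
    return ag.max_(x, axis=2)
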