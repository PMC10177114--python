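"""Layers and the optimizer built on the autodiff core.

Layout convention is NHWC throughout.  A ``CBA`` unit is the backbone's
building block: convolution -> batch normalization -> ReLU.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, batchnorm, conv2d

__all__ = ["Module", "Conv2d", "BatchNorm2d", "CBA", "SGD"]


class Module:
    """Base class: recursive parameter/state traversal and train/eval mode."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for v in vars(self).values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def set_training(self, training: bool) -> None:
        for m in self.modules():
            m._training = training

    @property
    def training(self) -> bool:
        return getattr(self, "_training", True)

    def state_arrays(self, prefix: str = "") -> dict[str, np.ndarray]:
        """Flat name -> array mapping of parameters and buffers (for checkpoints)."""
        out: dict[str, np.ndarray] = {}
        for name, v in vars(self).items():
            if name.startswith("_"):
                continue
            key = f"{prefix}{name}"
            if isinstance(v, Tensor):
                out[key] = v.data
            elif isinstance(v, np.ndarray):
                out[key] = v
            elif isinstance(v, Module):
                out.update(v.state_arrays(f"{key}."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.state_arrays(f"{key}.{i}."))
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, v in vars(self).items():
            if name.startswith("_"):
                continue
            key = f"{prefix}{name}"
            if isinstance(v, Tensor):
                v.data = np.asarray(state[key], dtype=np.float32).reshape(v.data.shape)
            elif isinstance(v, np.ndarray):
                setattr(self, name, np.asarray(state[key], dtype=v.dtype).reshape(v.shape))
            elif isinstance(v, Module):
                v.load_state_arrays(state, f"{key}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state_arrays(state, f"{key}.{i}.")


class Conv2d(Module):
    """Strided 2-D convolution with SAME(ceil) padding and He-normal init."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng()
        fan_in = kernel * kernel * in_channels
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, std, size=(kernel, kernel, in_channels, out_channels)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride)


class BatchNorm2d(Module):
    """Per-channel batch normalization over (N, H, W) with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            out, mu, var = batchnorm(x, self.gamma, self.beta, self.eps)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            return out
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        scale = self.gamma.data * inv
        shift = self.beta.data - self.running_mean * scale
        return x * Tensor(scale) + Tensor(shift)


class CBA(Module):
    """Convolution -> batch norm -> ReLU."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int = 3,
        stride: int = 1,
        rng: np.random.Generator | None = None,
    ):
        # bias is redundant under batch norm
        self.conv = Conv2d(in_channels, out_channels, kernel, stride, bias=False, rng=rng)
        self.bn = BatchNorm2d(out_channels)

    def __call__(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()


class SGD:
    """Momentum SGD with an optional externally scheduled learning rate."""

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.data -= lr * v
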