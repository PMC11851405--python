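"""Layer primitives built on the autodiff tensor engine."""
from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv3d

__all__ = ["Module", "Conv3d", "Linear", "InstanceNorm3d"]


class Module:
    """Base class: parameter discovery by attribute walk, flat state dicts."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for _, p in self.named_parameters():
            if id(p) not in seen:
                seen.add(id(p))
                params.append(p)
        return params

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield key, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{key}.{i}.")
                    elif isinstance(item, (list, tuple)):
                        for j, sub in enumerate(item):
                            if isinstance(sub, Module):
                                yield from sub.named_parameters(prefix=f"{key}.{i}.{j}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{key}.{i}", item
            elif isinstance(value, dict):
                for k, item in value.items():
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{key}.{k}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{key}.{k}", item

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state dict mismatch: missing={sorted(missing)}, "
                           f"unexpected={sorted(extra)}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv3d(Module):
    """3D convolution with He-normal initialization."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 stride: int = 1, padding: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        k = kernel_size
        if padding is None:
            padding = k // 2
        fan_in = in_channels * k ** 3
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, scale, (out_channels, in_channels, k, k, k)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / in_features)
        self.weight = Tensor(rng.normal(0.0, scale, (in_features, out_features)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class InstanceNorm3d(Module):
    """Per-sample, per-channel normalization over the spatial axes.

    Chosen over batch statistics because volumetric patches are trained with
    very small batches, where batch moments are high-variance.
    """

    def __init__(self, channels: int, eps: float = 1e-5, affine: bool = True):
        self.eps = eps
        if affine:
            self.gamma = Tensor(np.ones((1, channels, 1, 1, 1)), requires_grad=True)
            self.beta = Tensor(np.zeros((1, channels, 1, 1, 1)), requires_grad=True)
        else:
            self.gamma = self.beta = None

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3, 4), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3, 4), keepdims=True)
        y = xc * (var + self.eps) ** -0.5
        if self.gamma is not None:
            y = y * self.gamma + self.beta
        return y
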