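"""Neural-network building blocks on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter, Tensor

__all__ = ["Module", "Linear", "LayerNorm", "GroupNorm2d", "Conv2d", "Sequential"]


class Module:
    """Base class; collects :class:`Parameter` attributes recursively."""

    def parameters(self):
        params = []
        seen = set()
        stack = [self]
        while stack:
            obj = stack.pop()
            if id(obj) in seen:
                continue
            seen.add(id(obj))
            for value in vars(obj).values():
                if isinstance(value, Parameter):
                    params.append(value)
                elif isinstance(value, Module):
                    stack.append(value)
                elif isinstance(value, (list, tuple)):
                    stack.extend(v for v in value if isinstance(v, Module))
                    params.extend(v for v in value if isinstance(v, Parameter))
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        """Flat mapping name -> array, following attribute paths."""
        out = {}
        self._collect_state(out, "")
        return out

    def _collect_state(self, out, prefix):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                out[key] = value.data
            elif isinstance(value, Module):
                value._collect_state(out, key + ".")
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        v._collect_state(out, f"{key}.{i}.")
                    elif isinstance(v, Parameter):
                        out[f"{key}.{i}"] = v.data

    def load_state_dict(self, state: dict):
        current = self.state_dict()
        if set(current) != set(state):
            raise ValueError("state dict keys do not match model structure")
        # rebind in place so Parameter objects keep identity
        self._assign_state(state, "")

    def _assign_state(self, state, prefix):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                value.data = np.asarray(state[key], dtype=np.float64).reshape(value.data.shape)
            elif isinstance(value, Module):
                value._assign_state(state, key + ".")
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        v._assign_state(state, f"{key}.{i}.")
                    elif isinstance(v, Parameter):
                        v.data = np.asarray(state[f"{key}.{i}"], dtype=np.float64).reshape(v.data.shape)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.weight = Parameter(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    """Normalisation over the trailing feature axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xn = xc * ((var + self.eps) ** -0.5)
        return xn * self.gamma + self.beta


class GroupNorm2d(Module):
    """Group normalisation for NCHW feature maps."""

    def __init__(self, n_channels: int, n_groups: int = 4, eps: float = 1e-5):
        while n_channels % n_groups:
            n_groups -= 1
        self.n_groups = n_groups
        self.gamma = Parameter(np.ones((1, n_channels, 1, 1)))
        self.beta = Parameter(np.zeros((1, n_channels, 1, 1)))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        g = self.n_groups
        v = x.reshape(N, g, C // g * H * W)
        mu = v.mean(axis=-1, keepdims=True)
        vc = v - mu
        var = (vc * vc).mean(axis=-1, keepdims=True)
        vn = vc * ((var + self.eps) ** -0.5)
        return vn.reshape(N, C, H, W) * self.gamma + self.beta


class Conv2d(Module):
    def __init__(self, n_in: int, n_out: int, kernel: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (n_in * kernel * kernel))
        self.weight = Parameter(rng.normal(0.0, scale, size=(n_out, n_in, kernel, kernel)))
        self.bias = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias)


class Sequential(Module):
    def __init__(self, *stages):
        self.stages = list(stages)

    def __call__(self, x):
        for stage in self.stages:
            x = stage(x) if isinstance(stage, Module) else stage(x)
        return x
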