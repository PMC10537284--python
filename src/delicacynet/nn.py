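"""Network building blocks on top of the autodiff core.

Modules follow the familiar container pattern: a :class:`Module` owns
parameters and submodules, exposes ``parameters()`` for the optimizer and
``state_dict``/``load_state_dict`` for checkpointing.  Initialization is
fan-in-scaled uniform, drawn from a generator passed in explicitly so every
model build is seeded.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = [
    "Module",
    "Parameter",
    "Linear",
    "LayerNorm",
    "Dropout",
    "gelu_t",
    "softmax_t",
    "Adam",
]


def Parameter(data: np.ndarray) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


def uniform_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Module:
    """Parameter container with named-state serialization."""

    def parameters(self) -> list[Tensor]:
        params = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def named_state(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                state[key] = v.data
            elif isinstance(v, Module):
                state.update(v.named_state(prefix=key + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        state.update(item.named_state(prefix=f"{key}.{i}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        state[f"{key}.{i}"] = item.data
        return state

    def load_state(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                v.data = np.asarray(state[key], dtype=v.data.dtype).reshape(v.data.shape)
            elif isinstance(v, Module):
                v.load_state(state, prefix=key + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state(state, prefix=f"{key}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        item.data = np.asarray(state[f"{key}.{i}"], dtype=item.data.dtype).reshape(item.data.shape)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def astype(self, dtype) -> "Module":
        """Cast every parameter in place (e.g. to float32 for speed)."""
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        return self


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        self.w = Parameter(uniform_init(rng, (d_in, d_out), d_in))
        self.b = Parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.w
        if self.b is not None:
            out = out + self.b
        return out


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered**2.0).mean(axis=-1, keepdims=True)
        return centered * (var + self.eps) ** (-0.5) * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; identity in eval mode or at rate 0."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0,1), got {rate}")
        self.rate = rate

    def __call__(self, x: Tensor, train: bool, rng: np.random.Generator | None = None) -> Tensor:
        if not train or self.rate == 0.0:
            return x
        if rng is None:
            raise ValueError("dropout in train mode needs an rng")
        mask = ((rng.random(x.shape) >= self.rate) / (1.0 - self.rate)).astype(x.data.dtype)
        return x * Tensor(mask)


def gelu_t(x: Tensor) -> Tensor:
    """GELU via the exact Gaussian CDF: x * Phi(x) with Phi erf-based."""
    phi = ((x * (2.0**-0.5)).erf() + 1.0) * 0.5
    return x * phi


def softmax_t(x: Tensor, axis: int = -1) -> Tensor:
    # shift by the (detached) max: softmax is shift-invariant so gradients are exact
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
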