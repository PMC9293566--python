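"""Thin layer/optimizer abstractions on top of :mod:`timnet.grad`."""

from __future__ import annotations

import numpy as np

from .grad import Tensor, add, conv2d, layer_norm, matmul

__all__ = ["Parameter", "Module", "Conv2d", "Linear", "LayerNorm", "Adam"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Container with recursive parameter discovery by attribute name."""

    def named_parameters(self, prefix: str = "") -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                out[key] = value
            elif isinstance(value, Module):
                out.update(value.named_parameters(f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(f"{key}.{i}."))
                    elif isinstance(item, Parameter):
                        out[f"{key}.{i}"] = item
        return out

    def parameters(self) -> list[Parameter]:
        return list(self.named_parameters().values())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise ValueError(f"checkpoint/config mismatch: missing={sorted(missing)}, unexpected={sorted(extra)}")
        for name, p in params.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"checkpoint/config mismatch for {name}: {p.data.shape} vs {state[name].shape}")
            p.data = state[name].astype(np.float32)

    def state(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, rng: np.random.Generator, cin: int, cout: int, k: int, padding: int | None = None, bias: bool = True):
        self.padding = (k - 1) // 2 if padding is None else padding
        self.weight = Parameter(he_init(rng, (cout, cin, k, k), cin * k * k))
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.padding)


class Linear(Module):
    def __init__(self, rng: np.random.Generator, nin: int, nout: int, bias: bool = True):
        self.weight = Parameter(he_init(rng, (nin, nout), nin))
        self.bias = Parameter(np.zeros(nout)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = matmul(x, self.weight)
        if self.bias is not None:
            y = add(y, self.bias)
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta, self.eps)


class Adam:
    """Adam with the standard bias-corrected first/second moments."""

    def __init__(self, params: list[Parameter], lr: float = 1.5e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

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
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
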