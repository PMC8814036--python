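"""Minimal feed-forward neural-network primitives (numpy, manual backprop).

Just enough machinery for the translation model: dense layers, a couple of
activations, and Adam.  Layers cache their forward inputs, accumulate
parameter gradients on ``backward`` and return the gradient with respect to
their input, so input-level gradients (needed for expected-gradient
attribution) come for free.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Linear", "ReLU", "Tanh", "Softplus", "Sequential", "Adam"]


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


class Linear:
    """y = x @ W + b with Glorot-uniform init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        if zero_init:
            w = np.zeros((n_in, n_out))
        else:
            lim = np.sqrt(6.0 / (n_in + n_out))
            w = rng.uniform(-lim, lim, size=(n_in, n_out))
        self.W = Param(w)
        self.b = Param(np.zeros(n_out))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.W.value.T

    def params(self) -> list[Param]:
        return [self.W, self.b]


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.where(self._mask, g, 0.0)

    def params(self) -> list[Param]:
        return []


class Tanh:
    def __init__(self) -> None:
        self._y: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * (1.0 - self._y ** 2)

    def params(self) -> list[Param]:
        return []


class Softplus:
    def __init__(self) -> None:
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return np.logaddexp(0.0, x)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g / (1.0 + np.exp(-self._x))

    def params(self) -> list[Param]:
        return []


class Sequential:
    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out


class Adam:
    """Adam with parameter groups carrying their own learning rate."""

    def __init__(self, groups: list[tuple[list[Param], float]],
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.groups = groups
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [[np.zeros_like(p.value) for p in ps] for ps, _ in groups]
        self._v = [[np.zeros_like(p.value) for p in ps] for ps, _ in groups]

    def zero_grad(self) -> None:
        for ps, _ in self.groups:
            for p in ps:
                p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for gi, (ps, lr) in enumerate(self.groups):
            for pi, p in enumerate(ps):
                m = self._m[gi][pi]
                v = self._v[gi][pi]
                m *= b1
                m += (1 - b1) * p.grad
                v *= b2
                v += (1 - b2) * p.grad ** 2
                mhat = m / (1 - b1 ** self.t)
                vhat = v / (1 - b2 ** self.t)
                p.value -= lr * mhat / (np.sqrt(vhat) + self.eps)
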