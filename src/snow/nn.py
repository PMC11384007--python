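"""Fully connected layers and the Adam optimizer used by the model networks.

Layers hold :class:`~snow.autodiff.Tensor` parameters and offer two forward
paths: a graph-building path for training and a plain-ndarray path for
inference, where no gradients are needed and numpy is markedly faster.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, affine, relu

__all__ = ["Linear", "MLP", "Adam"]


class Linear:
    """Affine map with He-scaled Gaussian initialization (ReLU networks)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, gain: float = 2.0):
        scale = np.sqrt(gain / n_in)
        self.W = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return affine(x, self.W, self.b)

    def forward_np(self, x: np.ndarray) -> np.ndarray:
        return x @ self.W.data + self.b.data

    @property
    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


class MLP:
    """Stack of ReLU hidden layers with a linear output layer."""

    def __init__(self, n_in: int, hidden: list[int], n_out: int, rng: np.random.Generator):
        dims = [n_in, *hidden, n_out]
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            x = relu(layer(x))
        return self.layers[-1](x)

    def forward_np(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers[:-1]:
            x = np.maximum(layer.forward_np(x), 0.0)
        return self.layers[-1].forward_np(x)

    @property
    def parameters(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.parameters]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters)


class Adam:
    """Adam with L2 weight decay folded into the gradient (coupled form)."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 5e-4,
        betas: tuple[float, float] = (0.8, 0.9),
        eps: float = 1e-8,
        weight_decay: float = 1e-4,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            mhat = self.m[i] / (1.0 - self.b1**self.t)
            vhat = self.v[i] / (1.0 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
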