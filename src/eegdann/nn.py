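"""Parameters, linear layers and the RMSprop optimizer used by the models."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, add, matmul

__all__ = ["Parameter", "Linear", "RMSprop", "glorot_uniform"]


class Parameter(Tensor):
    """A tensor that persists across steps and receives gradients."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear:
    """Affine map ``x @ W + b`` with Glorot-uniform init."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True):
        self.weight = Parameter(glorot_uniform(rng, (in_dim, out_dim)))
        self.bias = Parameter(np.zeros(out_dim)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = matmul(x, self.weight)
        if self.bias is not None:
            y = add(y, self.bias)
        return y

    @property
    def parameters(self) -> list[Parameter]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])


class RMSprop:
    """RMSprop with optional L2 weight decay folded into the gradient.

    ``alpha`` is the squared-gradient smoothing constant and ``eps`` the
    denominator guard; both follow common deep-learning library defaults.
    """

    def __init__(self, params: list[Parameter], lr: float = 5e-4,
                 alpha: float = 0.99, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.alpha = float(alpha)
        self.eps = float(eps)
        self.weight_decay = float(weight_decay)
        self._sq = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, sq in zip(self.params, self._sq):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            sq *= self.alpha
            sq += (1.0 - self.alpha) * g * g
            p.data -= self.lr * g / (np.sqrt(sq) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
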