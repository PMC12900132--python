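"""Gradient-reversal scheduling and the two adversarial discriminators.

The gradient reversal layer (GRL) is an identity map whose backward pass
multiplies gradients by ``-coeff``.  Rather than a fixed reversal
strength, ``coeff`` follows a sigmoid ramp in the training iteration::

    coeff = 2 (hi - lo) / (1 + exp(-alpha * iter_num / max_iters)) - (hi - lo) + lo

which equals ``lo`` at iteration zero and rises monotonically toward
(but never reaching) ``hi``, so adversarial pressure is weak while the
extractor is still learning basic class structure and strong later.

Two discriminators sit behind GRLs: a binary domain discriminator
(source vs target membership) and a multi-class individual discriminator
(which subject produced the segment).  Both are two-layer perceptrons
with Leaky ReLU hidden activations; widths are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .exceptions import ConfigurationError
from .nn import Linear, Parameter

__all__ = [
    "GRLSchedule",
    "grl_coefficient",
    "reverse_gradient",
    "DomainDiscriminator",
    "IndividualDiscriminator",
]


@dataclass
class GRLSchedule:
    """State of the dynamic reversal-strength ramp."""

    hi: float = 0.9
    lo: float = 0.5
    alpha: float = 10.0
    iter_num: int = 0
    max_iters: int = 1000

    def __post_init__(self):
        if self.max_iters <= 0:
            raise ConfigurationError("max_iters must be positive")
        if self.hi < self.lo:
            raise ConfigurationError("hi must be >= lo")
        if self.alpha <= 0:
            raise ConfigurationError("alpha must be positive")

    @property
    def coeff(self) -> float:
        return grl_coefficient(self)

    def step(self) -> None:
        self.iter_num += 1


def grl_coefficient(schedule: GRLSchedule) -> float:
    """Current reversal strength of the sigmoid ramp."""
    span = schedule.hi - schedule.lo
    progress = schedule.iter_num / schedule.max_iters
    return float(2.0 * span / (1.0 + np.exp(-schedule.alpha * progress))
                 - span + schedule.lo)


def reverse_gradient(features: Tensor, coeff: float) -> Tensor:
    """Identity forward; backward gradient scaled by ``-coeff``."""
    return ad.gradient_reversal(features, coeff)


class DomainDiscriminator:
    """Two-layer perceptron emitting P(source) per row."""

    def __init__(self, feature_dim: int, rng: np.random.Generator,
                 hidden: int = 128, negative_slope: float = 0.01):
        self.negative_slope = float(negative_slope)
        self.fc1 = Linear(feature_dim, hidden, rng)
        self.fc2 = Linear(hidden, 1, rng)

    @property
    def parameters(self) -> list[Parameter]:
        return self.fc1.parameters + self.fc2.parameters

    def __call__(self, features: Tensor) -> Tensor:
        h = ad.leaky_relu(self.fc1(features), self.negative_slope)
        logits = self.fc2(h)
        return ad.sigmoid(logits.reshape(features.shape[0]))


class IndividualDiscriminator:
    """Two-layer perceptron emitting a subject-membership distribution."""

    def __init__(self, feature_dim: int, n_individuals: int,
                 rng: np.random.Generator, hidden: int = 128,
                 negative_slope: float = 0.01):
        if n_individuals < 2:
            raise ConfigurationError("individual discriminator needs >= 2 subjects")
        self.n_individuals = n_individuals
        self.negative_slope = float(negative_slope)
        self.fc1 = Linear(feature_dim, hidden, rng)
        self.fc2 = Linear(hidden, n_individuals, rng)

    @property
    def parameters(self) -> list[Parameter]:
        return self.fc1.parameters + self.fc2.parameters

    def __call__(self, features: Tensor) -> tuple[Tensor, Tensor]:
        """Return ``(logits, softmax probabilities)`` per row."""
        h = ad.leaky_relu(self.fc1(features), self.negative_slope)
        logits = self.fc2(h)
        return logits, ad.softmax(logits, axis=-1)
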