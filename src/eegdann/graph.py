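"""Learnable-adjacency Chebyshev graph-convolution feature extractor.

EEG channels are graph nodes; the adjacency matrix ``A`` is itself a
learnable parameter rather than being derived from electrode geometry.
Before every use it is symmetrized, rectified and symmetrically
normalized::

    A' = ReLU((A + A^T) / 2),   D_ii = sum_j A'_ij,   L = D^{-1/2} A' D^{-1/2}

Chebyshev polynomials of the normalized operator, ``T_0 = I``, ``T_1 = L``,
``T_k = 2 L T_{k-1} - T_{k-2}``, define the spectral filter bank, and each
graph-convolution layer computes ``LeakyReLU(sum_k T_k(L) X W_k)``.  The
bank is rebuilt from the live adjacency on every forward pass so gradients
reach ``A``.

The module exposes both a functional surface operating on plain arrays
(:func:`init_adjacency`, :func:`normalize_adjacency`,
:func:`chebyshev_stack`, :func:`graph_conv_forward`) and the stateful
:class:`ChebGraphExtractor` / :class:`MLPExtractor` used during training.
The functional forms delegate to the same differentiable code path, so
there is a single normalization and recursion implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .exceptions import ConfigurationError
from .nn import Linear, Parameter, glorot_uniform

__all__ = [
    "AdjacencyState",
    "ChebyshevBank",
    "GraphConvLayer",
    "init_adjacency",
    "normalize_adjacency",
    "chebyshev_stack",
    "graph_conv_forward",
    "ChebGraphExtractor",
    "MLPExtractor",
]

#: Guard against division blow-up when ReLU isolates a node (zero degree).
DEGREE_EPSILON = 1e-8


# ---------------------------------------------------------------------
# differentiable core
# ---------------------------------------------------------------------

def normalized_laplacian(raw: Tensor, epsilon: float = DEGREE_EPSILON) -> Tensor:
    """Symmetrize, rectify and symmetrically normalize a raw adjacency."""
    if raw.ndim != 2 or raw.shape[0] != raw.shape[1]:
        raise ValueError(f"adjacency must be square; got shape {raw.shape}")
    n = raw.shape[0]
    sym = (raw + raw.T) * 0.5
    rect = ad.relu(sym)
    degree = rect.sum(axis=1)
    dinv = ad.maximum(degree, epsilon) ** -0.5
    return rect * dinv.reshape(n, 1) * dinv.reshape(1, n)


def chebyshev_tensors(laplacian: Tensor, order: int) -> list[Tensor]:
    """``[T_0(L) ... T_{K-1}(L)]`` by the three-term recursion."""
    if order < 1:
        raise ConfigurationError("Chebyshev order must be >= 1")
    n = laplacian.shape[0]
    terms = [Tensor(np.eye(n))]
    if order >= 2:
        terms.append(laplacian)
    for _ in range(2, order):
        terms.append(2.0 * (laplacian @ terms[-1]) - terms[-2])
    return terms


# ---------------------------------------------------------------------
# functional (array) surface
# ---------------------------------------------------------------------

@dataclass
class AdjacencyState:
    """Raw learnable channel-graph weights and their derived matrices."""

    raw_weights: np.ndarray
    rectified: np.ndarray
    degree: np.ndarray
    normalized: np.ndarray


@dataclass
class ChebyshevBank:
    order: int
    polynomials: list[np.ndarray]


@dataclass
class GraphConvLayer:
    """Weights ``W_k`` (one per Chebyshev term, each ``F_in x F_out``)."""

    weights: list[np.ndarray]
    negative_slope: float = 0.01


def init_adjacency(n_channels: int, seed: int,
                   bound: float | None = None) -> AdjacencyState:
    """Random symmetric adjacency, entries i.i.d. uniform then symmetrized.

    The default bound is ``1 / sqrt(n_channels)`` (Xavier-style for a
    square matrix); symmetrization ``(W + W^T) / 2`` keeps every entry
    inside the same open interval.
    """
    if n_channels < 2:
        raise ConfigurationError("adjacency needs at least 2 channels")
    if bound is None:
        bound = 1.0 / np.sqrt(n_channels)
    rng = np.random.default_rng(seed)
    w = rng.uniform(-bound, bound, size=(n_channels, n_channels))
    raw = (w + w.T) / 2.0
    return normalize_adjacency(raw)


def normalize_adjacency(raw, epsilon: float = DEGREE_EPSILON) -> AdjacencyState:
    raw = raw.raw_weights if isinstance(raw, AdjacencyState) else np.asarray(raw, float)
    if raw.ndim != 2 or raw.shape[0] != raw.shape[1]:
        raise ValueError(f"adjacency must be square; got shape {raw.shape}")
    sym = (raw + raw.T) / 2.0
    rect = np.maximum(sym, 0.0)
    degree = rect.sum(axis=1)
    normalized = normalized_laplacian(Tensor(raw), epsilon).data
    return AdjacencyState(raw_weights=raw, rectified=rect, degree=degree,
                          normalized=normalized)


def chebyshev_stack(normalized: np.ndarray, order: int) -> ChebyshevBank:
    terms = chebyshev_tensors(Tensor(np.asarray(normalized, float)), order)
    return ChebyshevBank(order=order, polynomials=[t.data for t in terms])


def graph_conv_forward(x: np.ndarray, bank: ChebyshevBank,
                       layer: GraphConvLayer) -> np.ndarray:
    """Apply one graph-convolution layer to a batch of channel signals."""
    if len(layer.weights) != bank.order:
        raise ValueError(
            f"layer has {len(layer.weights)} weight matrices but bank order is {bank.order}"
        )
    x = np.asarray(x, float)
    f_in = layer.weights[0].shape[0]
    if x.ndim != 3 or x.shape[2] != f_in:
        raise ValueError(
            f"input must be (batch, channels, {f_in}); got shape {x.shape}"
        )
    z = _conv_sum(Tensor(x), [Tensor(t) for t in bank.polynomials],
                  [Tensor(w) for w in layer.weights])
    return ad.leaky_relu(z, layer.negative_slope).data


def _conv_sum(x: Tensor, terms: list[Tensor], weights: list[Tensor]) -> Tensor:
    z = (terms[0] @ x) @ weights[0]
    for t, w in zip(terms[1:], weights[1:]):
        z = z + (t @ x) @ w
    return z


# ---------------------------------------------------------------------
# stateful extractors
# ---------------------------------------------------------------------

class ChebGraphExtractor:
    """Stack of Chebyshev graph-convolution layers over a learned adjacency.

    Output of the last layer is flattened channel-wise, giving a feature
    vector of size ``n_channels * out_dim``.
    """

    def __init__(self, n_channels: int, n_bands: int, rng: np.random.Generator,
                 order: int = 3, n_layers: int = 1, out_dim: int = 32,
                 negative_slope: float = 0.01, init_bound: float | None = None,
                 epsilon: float = DEGREE_EPSILON):
        if n_channels < 2:
            raise ConfigurationError("extractor needs at least 2 channels")
        if order < 1:
            raise ConfigurationError("Chebyshev order must be >= 1")
        if n_layers < 1:
            raise ConfigurationError("need at least one graph-conv layer")
        self.n_channels = n_channels
        self.n_bands = n_bands
        self.order = order
        self.negative_slope = float(negative_slope)
        self.epsilon = float(epsilon)
        bound = 1.0 / np.sqrt(n_channels) if init_bound is None else init_bound
        w = rng.uniform(-bound, bound, size=(n_channels, n_channels))
        self.adjacency = Parameter((w + w.T) / 2.0)
        self.layers: list[list[Parameter]] = []
        f_in = n_bands
        for _ in range(n_layers):
            self.layers.append([
                Parameter(glorot_uniform(rng, (f_in, out_dim)))
                for _ in range(order)
            ])
            f_in = out_dim
        self.out_dim = out_dim

    @property
    def feature_dim(self) -> int:
        return self.n_channels * self.out_dim

    @property
    def parameters(self) -> list[Parameter]:
        return [self.adjacency] + [w for layer in self.layers for w in layer]

    def laplacian(self) -> Tensor:
        return normalized_laplacian(self.adjacency, self.epsilon)

    def __call__(self, x: Tensor) -> Tensor:
        if x.ndim != 3 or x.shape[1] != self.n_channels or x.shape[2] != self.n_bands:
            raise ValueError(
                f"input must be (batch, {self.n_channels}, {self.n_bands}); got {x.shape}"
            )
        # The bank is rebuilt every call so gradients flow into the adjacency.
        terms = chebyshev_tensors(self.laplacian(), self.order)
        h = x
        for layer in self.layers:
            h = ad.leaky_relu(_conv_sum(h, terms, layer), self.negative_slope)
        return h.reshape(x.shape[0], self.feature_dim)

    def pre_flatten(self, x: Tensor) -> Tensor:
        """Per-channel output before flattening (used for equivariance checks)."""
        terms = chebyshev_tensors(self.laplacian(), self.order)
        h = x
        for layer in self.layers:
            h = ad.leaky_relu(_conv_sum(h, terms, layer), self.negative_slope)
        return h

    def learned_adjacency(self) -> np.ndarray:
        """Current symmetrized adjacency (before rectification)."""
        a = self.adjacency.data
        return (a + a.T) / 2.0


class MLPExtractor:
    """Ablation extractor: two linear layers on the flattened feature vector.

    Matches the graph extractor's output dimensionality so discriminators
    and classifier heads are interchangeable between the two.
    """

    def __init__(self, n_channels: int, n_bands: int, rng: np.random.Generator,
                 hidden: int = 128, out_dim: int = 32,
                 negative_slope: float = 0.01):
        self.n_channels = n_channels
        self.n_bands = n_bands
        self.negative_slope = float(negative_slope)
        self.fc1 = Linear(n_channels * n_bands, hidden, rng)
        self.fc2 = Linear(hidden, n_channels * out_dim, rng)
        self.out_dim = out_dim

    @property
    def feature_dim(self) -> int:
        return self.n_channels * self.out_dim

    @property
    def parameters(self) -> list[Parameter]:
        return self.fc1.parameters + self.fc2.parameters

    def __call__(self, x: Tensor) -> Tensor:
        flat = x.reshape(x.shape[0], self.n_channels * self.n_bands)
        h = ad.leaky_relu(self.fc1(flat), self.negative_slope)
        return ad.leaky_relu(self.fc2(h), self.negative_slope)

    def learned_adjacency(self) -> None:
        return None
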