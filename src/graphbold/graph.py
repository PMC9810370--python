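"""Transition operators and graph convolutions on weighted brain graphs.

The information flow on the structural graph is modeled as a random-walk
diffusion: a row-stochastic transition operator ``T = D^-1 A`` is built from
the weighted adjacency, and graph filters are truncated power series
``sum_k theta_k T^k x`` (diffusion convolution).  A trainable adaptive
adjacency ``A_adap = tanh(V) / N`` can replace or supplement the fixed
operator (hybrid convolution).

Functions here operate on plain numpy arrays; the forecaster modules wrap
the same arithmetic in autodiff layers (:class:`GraphConvLayer`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from ._tensor import Tensor, sparse_apply
from .nn import Module, glorot

__all__ = [
    "WeightedAdjacency",
    "TransitionOperator",
    "DiffusionFilter",
    "transition_matrix",
    "diffusion_convolution",
    "adaptive_adjacency",
    "graph_conv_hybrid",
    "GraphConvLayer",
]

_ACTIVATIONS = {
    "identity": lambda y: y,
    "relu": lambda y: np.maximum(y, 0.0),
    "tanh": np.tanh,
    "sigmoid": lambda y: 0.5 * (1.0 + np.tanh(0.5 * y)),
}


@dataclass
class WeightedAdjacency:
    """Nonnegative weighted coupling between N regions.

    kind: "SC" (structural), "CE" (connectome-embedding similarity) or
    "synthetic" (simulation ground truth).  SC/synthetic must be symmetric.
    """

    weights: np.ndarray
    kind: str = "SC"

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.all(np.isfinite(w)):
            raise ValueError("adjacency contains non-finite entries")
        if self.kind in ("SC", "synthetic"):
            if np.any(w < 0):
                raise ValueError(f"{self.kind} adjacency must be nonnegative")
            if not np.allclose(w, w.T, atol=1e-9):
                raise ValueError(f"{self.kind} adjacency must be symmetric")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class TransitionOperator:
    """Row-stochastic random-walk operator T = D^-1 A.

    Rows of zero-degree nodes are all zero (such a node keeps only its own
    k=0 contribution in a diffusion filter).
    """

    matrix: sp.csr_matrix
    degree: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    def dense(self) -> np.ndarray:
        return self.matrix.toarray()


@dataclass
class DiffusionFilter:
    """Power-series filter coefficients theta[k, q, m] for k = 0..K."""

    theta: np.ndarray  # (K+1, Q, M)
    activation: str = "identity"

    def __post_init__(self):
        self.theta = np.atleast_3d(np.asarray(self.theta, dtype=float))
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")

    @property
    def K(self) -> int:
        return self.theta.shape[0] - 1


def transition_matrix(A: WeightedAdjacency | np.ndarray,
                      clip_negative: bool = True) -> TransitionOperator:
    """Row-normalize a weighted adjacency into a transition operator.

    Correlation-based adjacencies (kind="CE") may carry negative entries;
    by default these are clipped to zero before normalization so the
    operator stays stochastic (pass ``clip_negative=False`` to take
    absolute values instead).
    """
    if isinstance(A, WeightedAdjacency):
        w = A.weights
    else:
        w = np.asarray(A, dtype=float)
    if np.any(w < 0):
        w = np.where(w < 0, 0.0, w) if clip_negative else np.abs(w)
    degree = w.sum(axis=1)
    inv = np.where(degree > 0, 1.0 / np.where(degree > 0, degree, 1.0), 0.0)
    T = sp.csr_matrix(inv[:, None] * w)
    return TransitionOperator(matrix=T, degree=degree)


def _as_channels(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return x[:, None], True
    return x, False


def diffusion_convolution(x: np.ndarray, T: TransitionOperator,
                          filt: DiffusionFilter) -> np.ndarray:
    """y^q = sigma( sum_m sum_k theta[k,q,m] T^k x[:, m] ).

    T^k x is computed by k repeated sparse products, never by materializing
    T^k.  Input x: (N,) or (N, M); output: (N, Q) (or (N,) if both the
    input and the filter are single-channel).
    """
    xc, squeeze = _as_channels(x)
    N, M = xc.shape
    if T.n_nodes != N:
        raise ValueError("input rows do not match operator size")
    theta = filt.theta  # (K+1, Q, M)
    if theta.shape[2] != M:
        raise ValueError("filter input channels do not match data")
    z = xc
    y = np.zeros((N, theta.shape[1]))
    for k in range(theta.shape[0]):
        if k > 0:
            z = T.matrix @ z
        y += z @ theta[k].T
    y = _ACTIVATIONS[filt.activation](y)
    if squeeze and y.shape[1] == 1:
        return y[:, 0]
    return y


def adaptive_adjacency(V: np.ndarray) -> np.ndarray:
    """A_adap = tanh(V) / N; entries strictly inside (-1/N, 1/N)."""
    V = np.asarray(V, dtype=float)
    if V.ndim != 2 or V.shape[0] != V.shape[1]:
        raise ValueError("V must be square")
    return np.tanh(V) / V.shape[0]


def graph_conv_hybrid(x: np.ndarray,
                      T: TransitionOperator | None,
                      A_adap: np.ndarray | None,
                      filt: DiffusionFilter | None = None,
                      filt_adap: DiffusionFilter | None = None,
                      activation: str = "identity") -> np.ndarray:
    """Hybrid convolution summing fixed-operator and adaptive power series.

    y^q = sigma( sum_k theta[k] T^k x + sum_k theta_adap[k] A_adap^k x );
    with only one operator supplied, reduces to the corresponding single
    power series.
    """
    if T is None and A_adap is None:
        raise ValueError("at least one of T, A_adap must be provided")
    xc, squeeze = _as_channels(x)
    N = xc.shape[0]
    y = None
    if T is not None:
        if filt is None:
            raise ValueError("filter coefficients required with T")
        y = diffusion_convolution(xc, T, DiffusionFilter(filt.theta, "identity"))
    if A_adap is not None:
        if filt_adap is None:
            raise ValueError("adaptive filter coefficients required with A_adap")
        theta = filt_adap.theta
        z = xc
        ya = np.zeros((N, theta.shape[1]))
        for k in range(theta.shape[0]):
            if k > 0:
                z = A_adap @ z
            ya += z @ theta[k].T
        y = ya if y is None else y + ya
    y = _ACTIVATIONS[activation](y)
    if squeeze and y.shape[1] == 1:
        return y[:, 0]
    return y


class GraphConvLayer(Module):
    """Trainable diffusion/hybrid graph convolution (autodiff).

    Maps (..., N, M) -> (..., N, Q) with
    y = sum_k theta[k] ( T^k x ) [+ sum_k theta_adap[k] A_adap^k x] + b.
    `supports` is a list of sparse transition operators; `adaptive` is the
    shared trainable V matrix (owned by the parent model) or None.  The
    nonlinearity is left to the caller: recurrent gates and feedforward
    stacks apply their own.
    """

    def __init__(self, in_channels: int, out_channels: int, K: int,
                 supports: list[sp.csr_matrix],
                 adaptive: Tensor | None,
                 rng: np.random.Generator):
        super().__init__()
        self.K = K
        self.supports = [sp.csr_matrix(S) for S in supports]
        self.adaptive = adaptive
        n_branches = len(self.supports) + (1 if adaptive is not None else 0)
        if n_branches == 0:
            # K=0-style purely local mixing still has the k=0 term
            n_terms = 1
        else:
            n_terms = 1 + n_branches * K
        fan_in = in_channels * n_terms
        self.theta = Tensor(
            glorot(rng, fan_in, out_channels, shape=(n_terms, in_channels, out_channels)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        terms = [x]  # k = 0 (identity) term, shared across operator families
        for S in self.supports:
            z = x
            for _ in range(self.K):
                z = sparse_apply(S, z)
                terms.append(z)
        if self.adaptive is not None:
            A = self.adaptive.tanh() * (1.0 / self.adaptive.shape[0])
            z = x
            for _ in range(self.K):
                z = A @ z
                terms.append(z)
        out = None
        for i, z in enumerate(terms):
            contrib = z @ self.theta[i]
            out = contrib if out is None else out + contrib
        return out + self.bias
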