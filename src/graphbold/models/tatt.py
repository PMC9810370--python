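"""Stacked causal temporal-attention forecaster (TAtt).

Each layer scores the relevance of earlier time points to the current one
with ReLU-projected queries/keys, delta(t_i, t_j) = g(x_i) . g(x_j) / D,
normalizes the scores over admissible predecessors with a causal softmax,
and rebuilds the hidden state from the relevance-weighted projected past,
with residual connections and batch normalization.  All parameters are
shared across regions and time steps; the model performs no spatial
mixing, so it is exactly permutation-equivariant in the region axis.

The strict predecessor set t_j < t_i is empty at the first step, so the
mask is relaxed to t_j <= t_i (every row of the score matrix is then a
well-defined probability distribution).
"""

from __future__ import annotations

import numpy as np

from .._tensor import Tensor, concat
from ..nn import BatchNorm, Linear, Module
from .base import ForecastModel

__all__ = ["temporal_relevance", "TemporalAttentionLayer", "TAtt"]

_NEG = -1e30


def _causal_softmax(scores: Tensor) -> Tensor:
    """Row-normalize (..., T, T) scores over t_j <= t_i."""
    T = scores.shape[-1]
    mask = np.triu(np.full((T, T), _NEG), k=1)  # forbid t_j > t_i
    masked = scores + Tensor(mask)
    shift = Tensor(masked.data.max(axis=-1, keepdims=True))  # constant
    e = (masked - shift).exp()
    return e / e.sum(axis=-1, keepdims=True)


def temporal_relevance(node_seq: np.ndarray, W: np.ndarray, b: np.ndarray,
                       return_raw: bool = False) -> np.ndarray:
    """Normalized causal relevance matrix for one node sequence.

    node_seq: (T, M); W: (D, M); b: (D,).  Returns (T, T) with row t_i a
    probability distribution over t_j <= t_i.  With ``return_raw`` the
    unnormalized scores delta = g(x_i) . g(x_j) / D are returned instead
    (note the division by the projection width D).
    """
    node_seq = np.asarray(node_seq, dtype=float)
    g = np.maximum(node_seq @ np.asarray(W, float).T + np.asarray(b, float), 0.0)
    D = g.shape[1]
    scores = (g @ g.T) / D
    if return_raw:
        return scores
    out = _causal_softmax(Tensor(scores[None]))
    return out.data[0]


class TemporalAttentionLayer(Module):
    """Multi-head causal attention block with residual + batch norm.

    Heads act on disjoint D = M / heads slices: each head projects the
    input with its own ReLU map g_in (used for queries, keys and values
    alike), forms the causal relevance-weighted sum, and re-projects it
    with g_out; head outputs are concatenated, added to the input, and
    batch-normalized.
    """

    def __init__(self, features: int, heads: int, rng: np.random.Generator):
        super().__init__()
        if features % heads != 0:
            raise ValueError(f"feature width {features} not divisible by "
                             f"{heads} heads")
        self.heads = heads
        self.D = features // heads
        self.g_in = [Linear(features, self.D, rng) for _ in range(heads)]
        self.g_out = [Linear(self.D, self.D, rng) for _ in range(heads)]
        self.norm = BatchNorm(features)

    def __call__(self, x: Tensor) -> Tensor:
        # x: (B, N, T, M)
        outs = []
        for g_in, g_out in zip(self.g_in, self.g_out):
            g = g_in(x).relu()                        # (B, N, T, D)
            scores = (g @ g.transpose((0, 1, 3, 2))) * (1.0 / self.D)
            rel = _causal_softmax(scores)             # (B, N, T, T)
            ctx = rel @ g
            outs.append(g_out(ctx).relu())
        att = concat(outs, axis=-1)                   # (B, N, T, M)
        return self.norm(x + att)


class TAtt(ForecastModel):
    """Temporal-attention forecaster.

    The single-feature input is projected to M features, passed through L
    attention layers, collapsed back to one feature, and mapped from the
    T_p input positions to the T_f output positions by one learned affine
    map over the time axis (shared across regions).  Defaults follow the
    reference configuration: M=32 features, 4 heads, 4 layers.
    """

    def __init__(self, n_nodes: int, T_p: int, T_f: int, features: int = 32,
                 heads: int = 4, layers: int = 4, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.n_nodes, self.T_p, self.T_f = n_nodes, T_p, T_f
        self.in_proj = Linear(1, features, rng)
        self.layers = [TemporalAttentionLayer(features, heads, rng)
                       for _ in range(layers)]
        self.out_proj = Linear(features, 1, rng)
        self.time_map = Linear(T_p, T_f, rng)

    def forward(self, past: Tensor) -> Tensor:
        B, N, T_p = past.shape
        if T_p != self.T_p:
            raise ValueError(f"expected T_p={self.T_p}, got {T_p}")
        h = self.in_proj(past.reshape(B, N, T_p, 1))
        for layer in self.layers:
            h = layer(h)
        series = self.out_proj(h).reshape(B, N, T_p)
        return self.time_map(series)  # affine over the time axis
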