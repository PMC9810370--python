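"""Graph WaveNet: gated dilated causal temporal convolutions interleaved
with graph convolutions, residual and skip connections, dense output head.

The temporal stack is strictly causal: layer outputs at time t depend only
on inputs at t, t-d, ..., t-d(R-1), with the dilation d following the
WaveNet doubling schedule (1, 2, ... within each block, repeated across
blocks).  After each gated temporal convolution a graph convolution mixes
information between regions at every retained time index; skip branches
(taken after the graph convolution) are summed and passed through two
fully connected layers that emit all T_f horizons in one shot.

Internal layout is (B, T, N, C): batch, time, region, channel.
"""

from __future__ import annotations

import numpy as np

from .._tensor import Tensor
from ..graph import GraphConvLayer
from ..nn import Linear, Module, glorot
from .base import ForecastModel

__all__ = ["DilatedCausalConv", "GatedTCN", "GWN"]


class DilatedCausalConv(Module):
    """Causal convolution along the time axis with dilation d.

    y[t] = sum_{r=0}^{R-1} x[t - d*r] @ W[r] + b, with left zero padding so
    the output has the input's length.  R=1 reduces to pointwise channel
    mixing.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 dilation: int, rng: np.random.Generator):
        super().__init__()
        if kernel < 1 or dilation < 1:
            raise ValueError("kernel width and dilation must be >= 1")
        self.R, self.d = kernel, dilation
        self.weight = Tensor(
            glorot(rng, in_channels * kernel, out_channels,
                   shape=(kernel, in_channels, out_channels)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        # x: (B, T, N, C)
        T = x.shape[1]
        pad = self.d * (self.R - 1)
        padded = x.pad_axis(1, before=pad) if pad else x
        out = None
        for r in range(self.R):
            lo = pad - self.d * r
            tap = padded[:, lo:lo + T] @ self.weight[r]
            out = tap if out is None else out + tap
        return out + self.bias


class GatedTCN(Module):
    """h = tanh(DCC_1(x) + b_1) * logistic(DCC_2(x) + b_2)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 dilation: int, rng: np.random.Generator):
        super().__init__()
        self.filter = DilatedCausalConv(in_channels, out_channels, kernel,
                                        dilation, rng)
        self.gate = DilatedCausalConv(in_channels, out_channels, kernel,
                                      dilation, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.filter(x).tanh() * self.gate(x).sigmoid()


class GWN(ForecastModel):
    """Graph WaveNet forecaster.

    Default configuration: 12 blocks of 2 gated temporal layers (dilations
    1, 2 per block), 32 channels, kernel width R=2 — receptive field
    1 + (R-1) * sum(dilations) = 37 steps, within the T_p = 60 window.
    """

    def __init__(self, n_nodes: int, T_p: int, T_f: int,
                 supports=(), K: int = 1, channels: int = 32,
                 blocks: int = 12, layers_per_block: int = 2,
                 kernel: int = 2, end_channels: int = 128,
                 adaptive: bool = False, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.n_nodes, self.T_p, self.T_f = n_nodes, T_p, T_f
        self.K = K
        self.adaptive_V = (
            Tensor(np.zeros((n_nodes, n_nodes)), requires_grad=True)
            if adaptive else None
        )
        supports = list(supports)
        self.in_proj = Linear(1, channels, rng)
        self.dilations = [2 ** i for _ in range(blocks)
                          for i in range(layers_per_block)]
        self.tcn_layers = []
        self.graph_layers = []
        self.skip_layers = []
        for d in self.dilations:
            self.tcn_layers.append(GatedTCN(channels, channels, kernel, d, rng))
            self.graph_layers.append(GraphConvLayer(channels, channels, K,
                                                    supports, self.adaptive_V,
                                                    rng))
            self.skip_layers.append(Linear(channels, channels, rng))
        self.head1 = Linear(channels * T_p, end_channels, rng)
        self.head2 = Linear(end_channels, T_f, rng)

    @property
    def receptive_field(self) -> int:
        R = self.tcn_layers[0].filter.R
        return 1 + (R - 1) * sum(self.dilations)

    def temporal_stack(self, past: Tensor) -> Tensor:
        """Run the causal stack and return the summed skip output
        (B, T_p, N, C) — everything before the dense head, hence still
        causal along the time axis."""
        B, N, T_p = past.shape
        z = self.in_proj(past.transpose((0, 2, 1)).reshape(B, T_p, N, 1))
        skip = None
        for tcn, gc, sk in zip(self.tcn_layers, self.graph_layers,
                               self.skip_layers):
            g = tcn(z)
            g = gc(g).relu()
            s = sk(g)
            skip = s if skip is None else skip + s
            z = z + g  # residual (channel counts match)
        return skip

    def forward(self, past: Tensor) -> Tensor:
        B, N, T_p = past.shape
        if T_p != self.T_p:
            raise ValueError(f"expected T_p={self.T_p}, got {T_p}")
        skip = self.temporal_stack(past).relu()
        # (B, T, N, C) -> (B, N, T*C): the head may mix the whole window
        flat = skip.transpose((0, 2, 1, 3)).reshape(B, N, T_p * skip.shape[-1])
        return self.head2(self.head1(flat).relu())  # (B, N, T_f)
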