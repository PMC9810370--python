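"""Diffusion-convolution GRU sequence-to-sequence forecaster (DCRNN).

The encoder folds the T_p past graph signals into stacked DCGRU hidden
states; the decoder, initialized from those states, recursively emits T_f
predictions starting from a zero <GO> input.  Each DCGRU cell replaces the
dense matrix products of a GRU with diffusion graph convolutions over the
concatenation of input and hidden state:

    r = logistic(GC_r([x || h]) + b_r)
    u = logistic(GC_u([x || h]) + b_u)
    c = tanh(GC_c([x || r*h]) + b_c)
    h' = u * h + (1 - u) * c

During training the decoder consumes the true value with probability
eps_i = tau / (tau + exp(i / tau)) (scheduled sampling, decaying over
iterations i); during validation and testing it always consumes its own
previous prediction.
"""

from __future__ import annotations

import numpy as np

from .._tensor import Tensor, concat
from ..graph import GraphConvLayer
from ..nn import Linear, Module
from .base import ForecastModel

__all__ = ["DCGRUCell", "DCRNN", "scheduled_sampling_prob"]


def scheduled_sampling_prob(i: int, tau: float) -> float:
    """Probability eps_i = tau / (tau + exp(i / tau)) of feeding the truth."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if i < 0:
        raise ValueError("iteration must be >= 0")
    return tau / (tau + np.exp(i / tau))


class DCGRUCell(Module):
    """One graph-convolutional GRU cell (single layer)."""

    def __init__(self, in_channels: int, hidden: int, K: int, supports,
                 adaptive, rng: np.random.Generator):
        super().__init__()
        self.hidden = hidden
        self.conv_r = GraphConvLayer(in_channels + hidden, hidden, K,
                                     supports, adaptive, rng)
        self.conv_u = GraphConvLayer(in_channels + hidden, hidden, K,
                                     supports, adaptive, rng)
        self.conv_c = GraphConvLayer(in_channels + hidden, hidden, K,
                                     supports, adaptive, rng)

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        xh = concat([x, h], axis=-1)
        r = self.conv_r(xh).sigmoid()
        u = self.conv_u(xh).sigmoid()
        c = self.conv_c(concat([x, r * h], axis=-1)).tanh()
        return u * h + (1.0 - u) * c


class DCRNN(ForecastModel):
    """Encoder-decoder DCRNN forecaster.

    Parameters mirror the reference configuration: two stacked DCGRU layers
    of hidden size 64 in both encoder and decoder, an affine output head
    from the top decoder state to one feature per node and step, and
    scheduled sampling with decay parameter tau.
    """

    def __init__(self, n_nodes: int, T_p: int, T_f: int,
                 supports=(), K: int = 1, hidden: int = 64,
                 num_layers: int = 2, adaptive: bool = False,
                 tau: float = 2000.0, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.n_nodes, self.T_p, self.T_f = n_nodes, T_p, T_f
        self.K, self.hidden, self.num_layers = K, hidden, num_layers
        self.tau = tau
        self.adaptive_V = (
            Tensor(np.zeros((n_nodes, n_nodes)), requires_grad=True)
            if adaptive else None
        )
        supports = list(supports)

        def make_stack():
            cells = []
            for layer in range(num_layers):
                cin = 1 if layer == 0 else hidden
                cells.append(DCGRUCell(cin, hidden, K, supports,
                                       self.adaptive_V, rng))
            return cells

        self.encoder = make_stack()
        self.decoder = make_stack()
        self.out = Linear(hidden, 1, rng)

    def _run_stack(self, cells, x: Tensor, hs: list[Tensor]) -> list[Tensor]:
        new_hs = []
        inp = x
        for cell, h in zip(cells, hs):
            h_new = cell(inp, h)
            new_hs.append(h_new)
            inp = h_new
        return new_hs

    def forward(self, past: Tensor, teacher: Tensor | None = None,
                eps: float = 0.0,
                rng: np.random.Generator | None = None) -> Tensor:
        """Forecast (B, N, T_f) from past (B, N, T_p).

        In training mode a teacher sequence (B, N, T_f) may be supplied;
        each decoder step then consumes the true previous value with
        probability eps (one Bernoulli draw per step per sample).  In eval
        mode supplying a teacher is a contract violation.
        """
        if not self.training and teacher is not None:
            raise ValueError("teacher forcing is a training-mode-only input")
        if teacher is not None and rng is None and 0.0 < eps < 1.0:
            raise ValueError("scheduled sampling needs an explicit rng")
        B, N, T_p = past.shape
        hs = [Tensor(np.zeros((B, N, self.hidden))) for _ in self.encoder]
        for t in range(T_p):
            x_t = past[:, :, t].reshape(B, N, 1)
            hs = self._run_stack(self.encoder, x_t, hs)
        preds = []
        inp = Tensor(np.zeros((B, N, 1)))  # <GO> symbol
        for j in range(self.T_f):
            hs = self._run_stack(self.decoder, inp, hs)
            pred = self.out(hs[-1])  # (B, N, 1)
            preds.append(pred)
            if j + 1 < self.T_f:
                if teacher is not None and eps > 0.0:
                    truth = teacher[:, :, j].reshape(B, N, 1)
                    if eps >= 1.0:
                        inp = truth
                    else:
                        use_truth = (rng.random(B) < eps).astype(float)
                        mask = Tensor(use_truth[:, None, None])
                        inp = mask * truth + (1.0 - mask) * pred
                else:
                    inp = pred
        return concat(preds, axis=-1)
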