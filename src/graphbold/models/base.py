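"""Shared forecaster contract and helpers.

Every forecaster maps a batch of past sequences (B, N, T_p) to predicted
future sequences (B, N, T_f).  Spatial coupling enters through a list of
sparse transition operators ("supports") and/or a trainable adaptive
adjacency; a model built with no supports and no adaptive matrix treats
regions as independent (the K=0 null model).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .._tensor import Tensor, no_grad
from ..graph import TransitionOperator, WeightedAdjacency, transition_matrix
from ..nn import Module

__all__ = ["ForecastModel", "LinearGraphModel", "spatial_supports"]


def spatial_supports(adjacency, mode: str = "sc"):
    """Resolve a spatial mode into (supports, use_adaptive).

    mode "sc"/"ce": one fixed transition operator from the adjacency;
    "adaptive": no fixed operator, trainable adjacency only; "none": purely
    temporal model (no spatial mixing beyond k=0).
    """
    mode = mode.lower()
    if mode in ("sc", "ce"):
        if adjacency is None:
            raise ValueError(f"mode {mode!r} requires an adjacency")
        if isinstance(adjacency, WeightedAdjacency):
            op = transition_matrix(adjacency)
        elif isinstance(adjacency, TransitionOperator):
            op = adjacency
        else:
            op = transition_matrix(WeightedAdjacency(np.asarray(adjacency),
                                                     kind="synthetic"))
        return [op.matrix], False
    if mode == "adaptive":
        return [], True
    if mode == "none":
        return [], False
    raise ValueError(f"unknown spatial mode {mode!r}")


class ForecastModel(Module):
    """Base class: N x T_p past -> N x T_f prediction."""

    n_nodes: int
    T_p: int
    T_f: int

    def forward(self, past: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def predict(self, past: np.ndarray) -> np.ndarray:
        """Deterministic eval-mode prediction on a numpy batch (B, N, T_p)."""
        past = np.asarray(past, dtype=float)
        squeeze = past.ndim == 2
        if squeeze:
            past = past[None]
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                out = self.forward(Tensor(past)).data
        finally:
            if was_training:
                self.train()
        return out[0] if squeeze else out


class LinearGraphModel(ForecastModel):
    """Analytic linear forecaster x^(t+1) = M x^(t), iterated from the last
    observed state.  Used as a closed-form reference for the influence
    measure and in sanity tests; it has no trainable parameters.
    """

    def __init__(self, M: np.ndarray, horizon: int):
        super().__init__()
        self.M = np.asarray(M, dtype=float)
        if self.M.ndim != 2 or self.M.shape[0] != self.M.shape[1]:
            raise ValueError("coupling matrix must be square")
        self.n_nodes = self.M.shape[0]
        self.T_f = int(horizon)

    def forward(self, past: Tensor) -> Tensor:
        x = past.data[:, :, -1]  # (B, N)
        preds = np.empty((x.shape[0], self.n_nodes, self.T_f))
        cur = x
        for t in range(self.T_f):
            cur = cur @ self.M.T
            preds[:, :, t] = cur
        return Tensor(preds)
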