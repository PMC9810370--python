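"""Forecast evaluation: MAE, per-horizon MAE, R-squared, FC-state similarity.

The mean absolute error is the training objective and headline accuracy
measure; R-squared and the similarity between functional-connectivity
(pairwise Pearson correlation) states of predicted and true signals are
scale-free complements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["mae", "horizon_mae", "r_squared", "FCState", "fc_state",
           "fc_similarity"]


def _check(x_true, x_pred):
    x_true = np.asarray(x_true, dtype=float)
    x_pred = np.asarray(x_pred, dtype=float)
    if x_true.shape != x_pred.shape:
        raise ValueError(f"shape mismatch {x_true.shape} vs {x_pred.shape}")
    return x_true, x_pred


def mae(x_true: np.ndarray, x_pred: np.ndarray) -> float:
    """Mean absolute difference over regions, horizon steps and samples."""
    x_true, x_pred = _check(x_true, x_pred)
    return float(np.mean(np.abs(x_true - x_pred)))


def horizon_mae(x_true: np.ndarray, x_pred: np.ndarray) -> np.ndarray:
    """Per-forecast-step MAE (mean over everything but the last axis).

    Its mean equals :func:`mae` exactly.
    """
    x_true, x_pred = _check(x_true, x_pred)
    err = np.abs(x_true - x_pred)
    return err.mean(axis=tuple(range(err.ndim - 1)))


def r_squared(x_true: np.ndarray, x_pred: np.ndarray) -> float:
    """1 - SS_res / SS_tot pooled over regions, steps and samples."""
    x_true, x_pred = _check(x_true, x_pred)
    ss_tot = float(np.sum((x_true - x_true.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("constant truth: R^2 undefined")
    ss_res = float(np.sum((x_true - x_pred) ** 2))
    return 1.0 - ss_res / ss_tot


def per_region_r_squared(x_true: np.ndarray, x_pred: np.ndarray) -> np.ndarray:
    """R^2 computed separately per region (region = axis -2)."""
    x_true, x_pred = _check(x_true, x_pred)
    axes = tuple(i for i in range(x_true.ndim) if i != x_true.ndim - 2)
    mu = x_true.mean(axis=axes, keepdims=True)
    ss_tot = np.sum((x_true - mu) ** 2, axis=axes)
    if np.any(ss_tot == 0):
        raise ValueError("constant region truth: R^2 undefined")
    ss_res = np.sum((x_true - x_pred) ** 2, axis=axes)
    return 1.0 - ss_res / ss_tot


@dataclass
class FCState:
    """Functional-connectivity state: pairwise Pearson correlation matrix."""

    A_FC: np.ndarray

    def __post_init__(self):
        self.A_FC = np.asarray(self.A_FC, dtype=float)


def fc_state(signals: np.ndarray) -> FCState:
    """Pairwise Pearson correlation over time for an (N, T) signal matrix."""
    signals = np.asarray(signals, dtype=float)
    if signals.ndim != 2 or signals.shape[1] < 3:
        raise ValueError("need an (N, T) matrix with T >= 3")
    if np.any(signals.std(axis=1) < 1e-300):
        raise ValueError("constant region series: correlation undefined")
    C = np.corrcoef(signals)
    return FCState(C)


def fc_similarity(pred: np.ndarray | FCState, true: np.ndarray | FCState) -> float:
    """r_FC: Pearson correlation between the strictly-upper-triangular
    entries of predicted and true FC matrices (the diagonal is an
    uninformative 1)."""
    A = pred.A_FC if isinstance(pred, FCState) else fc_state(pred).A_FC
    B = true.A_FC if isinstance(true, FCState) else fc_state(true).A_FC
    iu = np.triu_indices(A.shape[0], k=1)
    return float(np.corrcoef(A[iu], B[iu])[0, 1])
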