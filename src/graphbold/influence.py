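"""Perturbation-based directed influence between regions.

A trained forecaster is probed by silencing one region's input window —
setting its activity to the sample mean, which is 0 for standardized data
— and measuring how much every region's forecast changes:

    I_n(n') = (1/S) sum_s (1/T_f) sum_t | xhat_n^t(s) - xhat'_n^t(s) |

where xhat' is the forecast from the perturbed input.  Entry (n, n') of
the influence matrix is the impact of region n' on region n.  Only the
input window is perturbed; targets are never modified.  For display the
off-diagonal entries are linearly rescaled to [0, 100]; the diagonal
(trivially large self-influence) is excluded from the rescaling
statistics and from edge ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .signal_io import WindowSample

__all__ = ["InfluenceMatrix", "perturb_sample", "influence_vector",
           "influence_matrix", "rescale_0_100"]


@dataclass
class InfluenceMatrix:
    I: np.ndarray           # (N, N); I[n, n'] = influence of n' on n
    n_samples: int
    horizon: int
    rescaled: bool = False

    def __post_init__(self):
        self.I = np.asarray(self.I, dtype=float)


def perturb_sample(sample: WindowSample, region: int,
                   mean_tolerance: float = 0.5) -> WindowSample:
    """Zero out one region's past sequence; everything else untouched.

    Warns when the window's overall mean is far from 0 (the zero
    perturbation then no longer equals the sample mean, so the data is
    probably not standardized).
    """
    if abs(float(sample.past.mean())) > mean_tolerance:
        warnings.warn(
            "input window mean is far from 0; perturbation assumes "
            "standardized data", stacklevel=2,
        )
    past = sample.past.copy()
    past[region, :, :] = 0.0
    return WindowSample(past, sample.future, sample.origin)


def _predict_batches(model, X: np.ndarray, batch_size: int) -> np.ndarray:
    return np.concatenate(
        [model.predict(X[lo:lo + batch_size])
         for lo in range(0, X.shape[0], batch_size)], axis=0)


def influence_vector(model, samples: list[WindowSample], region: int,
                     batch_size: int = 64) -> np.ndarray:
    """I(., n') for a single silenced region n'."""
    return _influence_columns(model, samples, [region], batch_size)[:, 0]


def _influence_columns(model, samples, regions, batch_size) -> np.ndarray:
    if not samples:
        raise ValueError("no samples to evaluate influence on")
    X = np.stack([w.past[:, :, 0] for w in samples])  # (S, N, T_p)
    base = _predict_batches(model, X, batch_size)     # (S, N, T_f)
    cols = np.empty((base.shape[1], len(regions)))
    for j, region in enumerate(regions):
        Xp = X.copy()
        Xp[:, region, :] = 0.0
        pert = _predict_batches(model, Xp, batch_size)
        cols[:, j] = np.abs(base - pert).mean(axis=(0, 2))
    return cols


def influence_matrix(model, samples: list[WindowSample],
                     targets=None, batch_size: int = 64) -> InfluenceMatrix:
    """Silence each region in turn and collect the full N x N matrix.

    Column n' is the influence vector of region n'.  `targets` restricts
    the perturbed regions (other columns are NaN).
    """
    if not samples:
        raise ValueError("no samples to evaluate influence on")
    N = samples[0].past.shape[0]
    regions = list(range(N)) if targets is None else list(targets)
    cols = _influence_columns(model, samples, regions, batch_size)
    I = np.full((N, N), np.nan)
    I[:, regions] = cols
    return InfluenceMatrix(I, n_samples=len(samples),
                           horizon=samples[0].future.shape[1])


def rescale_0_100(infl: InfluenceMatrix) -> InfluenceMatrix:
    """Map off-diagonal entries linearly onto [0, 100].

    The diagonal is excluded from the min/max statistics and set to 0 in
    the rescaled matrix.
    """
    I = infl.I.copy()
    N = I.shape[0]
    off = ~np.eye(N, dtype=bool)
    vals = I[off]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite off-diagonal entries")
    lo, hi = vals.min(), vals.max()
    if hi - lo < 1e-300:
        raise ValueError("constant off-diagonal influence: rescale undefined")
    out = (I - lo) * (100.0 / (hi - lo))
    np.fill_diagonal(out, 0.0)
    return InfluenceMatrix(out, infl.n_samples, infl.horizon, rescaled=True)
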