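"""Vector autoregression baseline fitted by ordinary least squares.

A VAR(p) models the multivariate signal as

    x(t) = b + A_1 x(t-1) + ... + A_p x(t-p) + u(t)

with one N x N coefficient matrix per lag, so its parameter count grows as
N^2 * p — the scaling that makes it fragile on large brain networks with
scarce data, in contrast to the graph models whose spatial parameters grow
only with the walk order K.  One pooled VAR is fitted across the training
segments of all sessions (lagged regressors never cross a session
boundary); multi-step forecasts iterate the one-step recursion on the
model's own predictions.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from statsmodels.tsa.stattools import adfuller

from .signal_io import SessionTimeSeries, WindowSample

__all__ = ["VARModel", "fit_var", "forecast_var", "select_order",
           "adf_fraction", "windows_to_segments"]


@dataclass
class VARModel:
    order: int
    coefs: np.ndarray      # (p, N, N); A_k = coefs[k-1]
    intercept: np.ndarray  # (N,)
    residuals: np.ndarray | None = None

    @property
    def n_series(self) -> int:
        return self.intercept.shape[0]

    @property
    def n_parameters(self) -> int:
        """N^2 * p + N — quadratic growth in the network size."""
        N = self.n_series
        return N * N * self.order + N


def windows_to_segments(windows: list[WindowSample]) -> list[np.ndarray]:
    """Reconstruct contiguous per-session segments from stride-1 windows.

    Windows from one session overlap heavily; stacking them as regression
    rows would just duplicate observations.  Instead the contiguous span
    they cover is rebuilt (first window in full, then one new column per
    subsequent window) and used as an ordinary time series.
    """
    by_session: dict[str, list[WindowSample]] = {}
    for w in windows:
        by_session.setdefault(w.origin[0], []).append(w)
    segments = []
    for sess, ws in by_session.items():
        ws = sorted(ws, key=lambda w: w.origin[1])
        starts = [w.origin[1] for w in ws]
        if starts != list(range(starts[0], starts[0] + len(ws))):
            raise ValueError(f"windows of session {sess!r} are not stride-1")
        cols = [np.concatenate([ws[0].past, ws[0].future], axis=1)[:, :, 0]]
        span = ws[0].past.shape[1] + ws[0].future.shape[1]
        for w in ws[1:]:
            cols.append(w.future[:, -1:, 0])
        segments.append(np.concatenate(cols, axis=1))
        assert segments[-1].shape[1] == span + len(ws) - 1
    return segments


def _as_segments(data) -> list[np.ndarray]:
    if isinstance(data, np.ndarray):
        return [np.asarray(data, dtype=float)]
    data = list(data)
    if not data:
        raise ValueError("no data to fit")
    if isinstance(data[0], WindowSample):
        return windows_to_segments(data)
    if isinstance(data[0], SessionTimeSeries):
        return [ts.values for ts in data]
    return [np.asarray(seg, dtype=float) for seg in data]


def fit_var(data, p: int) -> VARModel:
    """OLS fit of a VAR(p) pooled over contiguous (N, T) segments.

    `data` may be a single array, a list of arrays / sessions, or a list
    of training WindowSamples (reassembled into segments first).  p=0
    yields the intercept-only model (the pooled sample mean).
    """
    if p < 0:
        raise ValueError("order must be >= 0")
    segments = _as_segments(data)
    N = segments[0].shape[0]
    rows_y, rows_x = [], []
    for seg in segments:
        if seg.shape[0] != N:
            raise ValueError("segments disagree on the number of series")
        T = seg.shape[1]
        for t in range(p, T):
            rows_y.append(seg[:, t])
            if p > 0:
                rows_x.append(np.concatenate(
                    [seg[:, t - k] for k in range(1, p + 1)]))
    Yd = np.asarray(rows_y)  # (S, N)
    n_obs = Yd.shape[0]
    if n_obs <= N * p + 1:
        raise ValueError(
            f"insufficient samples: {n_obs} observations for {N * p + 1} "
            "parameters per equation"
        )
    if p == 0:
        b = Yd.mean(axis=0)
        resid = Yd - b
        return VARModel(0, np.zeros((0, N, N)), b, resid)
    Xd = np.asarray(rows_x)  # (S, N*p)
    design = np.concatenate([np.ones((n_obs, 1)), Xd], axis=1)
    coef, _, rank, _ = np.linalg.lstsq(design, Yd, rcond=None)
    if rank < design.shape[1]:
        raise ValueError("rank-deficient design: VAR coefficients not "
                         "identified")
    b = coef[0]
    A = coef[1:].T.reshape(N, p, N).transpose(1, 0, 2)  # (p, N, N)
    resid = Yd - design @ coef
    return VARModel(p, A, b, resid)


def forecast_var(model: VARModel, history: np.ndarray, T_f: int) -> np.ndarray:
    """Iterate the one-step recursion T_f steps from the end of `history`.

    history: (N, >= p).  Each predicted step feeds the next.
    """
    history = np.atleast_2d(np.asarray(history, dtype=float))
    N, T = history.shape
    p = model.order
    if T < p:
        raise ValueError(f"history length {T} < order {p}")
    buf = [history[:, T - k] for k in range(1, p + 1)]  # lags 1..p
    out = np.empty((N, T_f))
    for t in range(T_f):
        x = model.intercept.copy()
        for k in range(p):
            x += model.coefs[k] @ buf[k]
        out[:, t] = x
        if p > 0:
            buf = [x] + buf[:-1]
    return out


def select_order(train_data, test_windows: list[WindowSample], T_f: int,
                 candidates=None) -> tuple[int, dict[int, float]]:
    """Sweep the model order and return (best p, per-candidate test MAE).

    Candidates default to 5, 10, ..., T_p in steps of five; candidates that
    cannot be fitted (too few samples, or longer than the available past)
    are skipped with a warning.  Selection minimizes T_f-step forecast MAE
    on the test windows — a purely predictive criterion.
    """
    if not test_windows:
        raise ValueError("no test windows")
    T_p = test_windows[0].past.shape[1]
    if candidates is None:
        candidates = list(range(5, T_p + 1, 5))
    table: dict[int, float] = {}
    for p in candidates:
        if p > T_p:
            warnings.warn(f"order {p} exceeds past length {T_p}; skipped")
            continue
        try:
            model = fit_var(train_data, p)
        except ValueError as exc:
            warnings.warn(f"order {p} infeasible: {exc}")
            continue
        errs = []
        for w in test_windows:
            pred = forecast_var(model, w.past[:, :, 0], T_f)
            errs.append(np.mean(np.abs(w.future[:, :T_f, 0] - pred)))
        table[p] = float(np.mean(errs))
    if not table:
        raise ValueError("no feasible VAR order candidate")
    best = min(table, key=table.get)
    return best, table


def adf_fraction(sessions, alpha: float = 0.01) -> float:
    """Fraction of region series failing the augmented Dickey-Fuller
    stationarity screen (unit root not rejected at `alpha`).

    Reported, never blocking: the forecasting comparison proceeds on the
    predictive criterion regardless.
    """
    if isinstance(sessions, SessionTimeSeries):
        sessions = [sessions]
    n_fail = 0
    n_total = 0
    for ts in sessions:
        series_iter = ts.values if isinstance(ts, SessionTimeSeries) else np.atleast_2d(ts)
        for row in series_iter:
            if row.size < 20:
                raise ValueError("series too short for the ADF regression")
            pval = adfuller(row, autolag="AIC")[1]
            n_total += 1
            if pval > alpha:
                n_fail += 1
    return n_fail / n_total
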