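"""Session time-series I/O, filtering, scaling, windowing and splitting.

A resting-state session is a region-by-time matrix ``X in R^{N x T}``
(rows = regions in a stable, shared ordering; columns = TRs).  The
preparation pipeline band-pass filters each region's series (0.04-0.07 Hz
by default, zero phase), scales it, slides paired past/future windows of
lengths (T_p, T_f) over the session, and splits the windows chronologically
into train/validation/test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
from scipy import signal as _signal

__all__ = [
    "SessionTimeSeries",
    "WindowSample",
    "ScalingParams",
    "bandpass_filter",
    "scale",
    "inverse_scale",
    "make_windows",
    "split_windows",
    "read_session_tsv",
    "write_session_tsv",
    "read_adjacency",
    "write_adjacency",
    "read_region_order",
    "save_prepared",
    "load_prepared",
]


@dataclass
class SessionTimeSeries:
    """One session's region x time signal matrix with its sampling interval."""

    values: np.ndarray  # (N, T)
    sampling_interval: float = 0.72  # seconds per TR
    session_id: str = "session"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D region x time matrix")
        N, T = self.values.shape
        if N < 1 or T < 2:
            raise ValueError("need N >= 1 regions and T >= 2 time points")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("missing/non-finite values in session matrix")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class WindowSample:
    """A paired past/future sample: future immediately follows past."""

    past: np.ndarray    # (N, T_p, M)
    future: np.ndarray  # (N, T_f, M)
    origin: tuple[str, int] = ("session", 0)

    def __post_init__(self):
        if self.past.ndim == 2:
            self.past = self.past[:, :, None]
        if self.future.ndim == 2:
            self.future = self.future[:, :, None]


@dataclass
class ScalingParams:
    """Statistics needed to invert a scaling transform.

    minmax01: per-session minimum/range; zscore: per-region mean/std pooled
    over the whole dataset.
    """

    mode: str
    offset: np.ndarray
    scale_: np.ndarray


def bandpass_filter(ts: SessionTimeSeries, low_hz: float, high_hz: float,
                    order: int = 5) -> SessionTimeSeries:
    """Zero-phase Butterworth band-pass applied identically to each region.

    The filter is applied forward and backward (sosfiltfilt), so the pass
    band is phase-neutral — a time shift would corrupt the lag structure
    that the forecasters and the VAR rely on.
    """
    nyquist = 0.5 / ts.sampling_interval
    if not (0.0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz outside (0, Nyquist={nyquist:.4g}) Hz"
        )
    sos = _signal.butter(order, [low_hz, high_hz], btype="bandpass",
                         fs=1.0 / ts.sampling_interval, output="sos")
    filtered = _signal.sosfiltfilt(sos, ts.values, axis=1)
    return SessionTimeSeries(filtered, ts.sampling_interval, ts.session_id)


def scale(data: SessionTimeSeries | list[SessionTimeSeries], mode: str):
    """Scale session data and return (scaled, ScalingParams).

    mode="minmax01": each session is mapped linearly onto [0, 1] using its
    own min/max (full-session statistics).  mode="zscore": each region is
    standardized to zero mean, unit variance with statistics pooled over
    every session in the dataset.
    """
    single = isinstance(data, SessionTimeSeries)
    sessions = [data] if single else list(data)
    if not sessions:
        raise ValueError("no sessions to scale")
    if mode == "minmax01":
        out = []
        offs, scls = [], []
        for ts in sessions:
            lo, hi = ts.values.min(), ts.values.max()
            if hi - lo < 1e-300:
                raise ValueError(
                    f"session {ts.session_id!r} is constant; minmax01 undefined"
                )
            out.append(SessionTimeSeries((ts.values - lo) / (hi - lo),
                                         ts.sampling_interval, ts.session_id))
            offs.append(lo)
            scls.append(hi - lo)
        params = ScalingParams("minmax01", np.asarray(offs), np.asarray(scls))
    elif mode == "zscore":
        pooled = np.concatenate([ts.values for ts in sessions], axis=1)
        mu = pooled.mean(axis=1)
        sd = pooled.std(axis=1)
        if np.any(sd < 1e-300):
            raise ValueError("constant region series; zscore undefined")
        out = [
            SessionTimeSeries((ts.values - mu[:, None]) / sd[:, None],
                              ts.sampling_interval, ts.session_id)
            for ts in sessions
        ]
        params = ScalingParams("zscore", mu, sd)
    else:
        raise ValueError(f"unknown scaling mode {mode!r}")
    return (out[0] if single else out), params


def inverse_scale(data: SessionTimeSeries | list[SessionTimeSeries],
                  params: ScalingParams):
    """Invert :func:`scale`; round-trips to < 1e-10 relative error."""
    single = isinstance(data, SessionTimeSeries)
    sessions = [data] if single else list(data)
    out = []
    for i, ts in enumerate(sessions):
        if params.mode == "minmax01":
            vals = ts.values * params.scale_[i] + params.offset[i]
        elif params.mode == "zscore":
            vals = ts.values * params.scale_[:, None] + params.offset[:, None]
        else:
            raise ValueError(f"unknown scaling mode {params.mode!r}")
        out.append(SessionTimeSeries(vals, ts.sampling_interval, ts.session_id))
    return out[0] if single else out


def make_windows(ts: SessionTimeSeries, T_p: int, T_f: int) -> list[WindowSample]:
    """Slide stride-1 past/future pairs over the session.

    Produces exactly T - T_p - T_f + 1 samples, in chronological order.
    """
    if T_p < 1 or T_f < 1:
        raise ValueError("T_p and T_f must be >= 1")
    T = ts.n_timepoints
    if T < T_p + T_f:
        raise ValueError(f"session length {T} < T_p + T_f = {T_p + T_f}")
    X = ts.values
    out = []
    for s in range(T - T_p - T_f + 1):
        out.append(WindowSample(
            past=X[:, s:s + T_p, None],
            future=X[:, s + T_p:s + T_p + T_f, None],
            origin=(ts.session_id, s),
        ))
    return out


def split_windows(pairs_per_session: list[list[WindowSample]],
                  fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)):
    """Chronological per-session split, aggregated across sessions.

    Per session: the final floor(f_test * count) pairs are test, the
    preceding floor(f_val * count) pairs are validation, and the remainder
    (the earliest pairs) are training — no shuffling, so validation and
    test always lie in the session's future relative to training.
    """
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("need three positive fractions")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    if pairs_per_session and isinstance(pairs_per_session[0], WindowSample):
        pairs_per_session = [pairs_per_session]  # single session convenience
    train, val, test = [], [], []
    for pairs in pairs_per_session:
        n = len(pairs)
        n_test = int(np.floor(fractions[2] * n))
        n_val = int(np.floor(fractions[1] * n))
        n_train = n - n_val - n_test
        train.extend(pairs[:n_train])
        val.extend(pairs[n_train:n_train + n_val])
        test.extend(pairs[n_train + n_val:])
    return train, val, test


# ---------------------------------------------------------------------------
# file formats


def read_session_tsv(path, sampling_interval: float = 0.72,
                     delimiter: str = "\t") -> SessionTimeSeries:
    """Read a delimited region x time matrix (no header)."""
    path = Path(path)
    values = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    return SessionTimeSeries(values, sampling_interval, session_id=path.stem)


def write_session_tsv(ts: SessionTimeSeries, path, delimiter: str = "\t"):
    np.savetxt(path, ts.values, delimiter=delimiter, fmt="%.10g")


def read_region_order(path) -> list[str]:
    """One region label per line; order shared by sessions and adjacency."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_adjacency(path, kind: str = "SC", labels: list[str] | None = None,
                   delimiter: str = "\t"):
    """Read a square delimited matrix, or a 3-column weighted edge list.

    Edge lists require `labels` (the region order) to resolve node names;
    edges are symmetrized.
    """
    from .graph import WeightedAdjacency

    path = Path(path)
    raw = np.genfromtxt(path, delimiter=delimiter, dtype=str, ndmin=2)
    square = raw.shape[0] == raw.shape[1] and (labels is None or
                                               raw.shape[0] == len(labels))
    if raw.shape[1] == 3 and not square:
        if labels is None:
            raise ValueError("edge-list adjacency requires a region order file")
        index = {lab: i for i, lab in enumerate(labels)}
        N = len(labels)
        w = np.zeros((N, N))
        for src, dst, weight in raw:
            if src not in index or dst not in index:
                raise ValueError(f"edge endpoint {src!r}/{dst!r} not in region order")
            i, j = index[src], index[dst]
            w[i, j] = w[j, i] = float(weight)
        return WeightedAdjacency(w, kind=kind)
    return WeightedAdjacency(raw.astype(float), kind=kind)


def write_adjacency(A, path, delimiter: str = "\t"):
    np.savetxt(path, np.asarray(A.weights if hasattr(A, "weights") else A),
               delimiter=delimiter, fmt="%.10g")


def save_prepared(path, splits: dict, meta: dict | None = None):
    """Write prepared train/val/test windows to an HDF5 container."""
    with h5py.File(path, "w") as fh:
        for name, windows in splits.items():
            grp = fh.create_group(name)
            if windows:
                grp.create_dataset("past", data=np.stack([w.past for w in windows]))
                grp.create_dataset("future", data=np.stack([w.future for w in windows]))
                grp.create_dataset(
                    "origin_session",
                    data=np.array([w.origin[0] for w in windows], dtype="S64"),
                )
                grp.create_dataset(
                    "origin_start", data=np.array([w.origin[1] for w in windows])
                )
        for k, v in (meta or {}).items():
            fh.attrs[k] = v


def load_prepared(path) -> dict[str, list[WindowSample]]:
    splits = {}
    with h5py.File(path, "r") as fh:
        for name in fh:
            grp = fh[name]
            windows = []
            if "past" in grp:
                past = grp["past"][...]
                future = grp["future"][...]
                sess = [s.decode() for s in grp["origin_session"][...]]
                start = grp["origin_start"][...]
                for i in range(past.shape[0]):
                    windows.append(WindowSample(past[i], future[i],
                                                (sess[i], int(start[i]))))
            splits[name] = windows
    return splits
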