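"""Shared training loop: MAE objective, Adam, annealing schedules.

Each model family has a named preset matching its reference training
recipe (epochs, batch size, initial learning rate, decay epochs); the
learning rate is additionally decayed early if validation MAE fails to
improve for `patience` epochs, and the best-validation weights are
restored before every decay and at the end of training.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._tensor import Tensor
from .metrics import mae
from .models.dcrnn import DCRNN, scheduled_sampling_prob
from .nn import Adam, clip_grad_norm
from .signal_io import WindowSample

__all__ = ["TrainSchedule", "schedule_preset", "learning_rate_at",
           "stack_windows", "train_model"]


@dataclass
class TrainSchedule:
    family: str = "dcrnn"
    epochs: int = 70
    batch_size: int = 16
    learning_rate: float = 0.1
    decay_epochs: tuple[int, ...] = (20, 40, 60)
    decay_factor: float = 0.1
    patience: int = 10
    restore_best: bool = True
    clip_norm: float | None = 5.0
    tau: float = 2000.0  # scheduled-sampling decay (DCRNN only)
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")
        if not (0.0 < self.decay_factor < 1.0):
            raise ValueError("decay factor must lie in (0, 1)")


_PRESETS = {
    "dcrnn": TrainSchedule("dcrnn", epochs=70, batch_size=16,
                           learning_rate=0.1, decay_epochs=(20, 40, 60)),
    "dcrnn-small-cohort": TrainSchedule("dcrnn", epochs=140, batch_size=16,
                                        learning_rate=0.1,
                                        decay_epochs=(40, 80, 120)),
    "gwn": TrainSchedule("gwn", epochs=30, batch_size=8,
                         learning_rate=1e-4, decay_epochs=(10, 20),
                         clip_norm=None),
    "gwn-small-cohort": TrainSchedule("gwn", epochs=60, batch_size=8,
                                      learning_rate=1e-4,
                                      decay_epochs=(20, 40), clip_norm=None),
    "tatt": TrainSchedule("tatt", epochs=40, batch_size=16,
                          learning_rate=0.1, decay_epochs=(10, 20, 30),
                          clip_norm=None),
}


def schedule_preset(name: str, **overrides) -> TrainSchedule:
    """Named training preset; keyword overrides replace fields."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; have {sorted(_PRESETS)}")
    return replace(_PRESETS[name], **overrides)


def learning_rate_at(schedule: TrainSchedule, epoch: int) -> float:
    """Nominal learning rate during a given (1-indexed) epoch, ignoring
    plateau-triggered early decays."""
    n = sum(1 for d in schedule.decay_epochs if d < epoch)
    return schedule.learning_rate * schedule.decay_factor ** n


def stack_windows(windows: list[WindowSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack single-feature windows into (B, N, T_p) / (B, N, T_f) arrays."""
    if not windows:
        raise ValueError("empty window list")
    X = np.stack([w.past[:, :, 0] for w in windows])
    Y = np.stack([w.future[:, :, 0] for w in windows])
    return X, Y


def _evaluate(model, X: np.ndarray, Y: np.ndarray, batch_size: int) -> float:
    preds = []
    for lo in range(0, X.shape[0], batch_size):
        preds.append(model.predict(X[lo:lo + batch_size]))
    return mae(Y, np.concatenate(preds, axis=0))


def train_model(model, train_windows, val_windows, schedule: TrainSchedule):
    """Minimize MAE on minibatches; returns (model, history).

    history holds per-epoch train/val MAE and the applied learning rates;
    the returned model carries the best-validation weights.  A non-finite
    loss aborts with a diagnostic.
    """
    X, Y = stack_windows(train_windows)
    Xv, Yv = stack_windows(val_windows) if val_windows else (None, None)
    rng = np.random.default_rng(schedule.seed)
    params = model.parameters()
    opt = Adam(params, lr=schedule.learning_rate)
    history = {"train_mae": [], "val_mae": [], "lr": []}
    best_val = np.inf
    best_state = model.state_dict()
    decays = list(schedule.decay_epochs)
    since_improve = 0
    iteration = 0
    lr = schedule.learning_rate

    n = X.shape[0]
    for epoch in range(1, schedule.epochs + 1):
        model.train()
        order = rng.permutation(n)
        epoch_losses = []
        for lo in range(0, n, schedule.batch_size):
            idx = order[lo:lo + schedule.batch_size]
            xb, yb = Tensor(X[idx]), Y[idx]
            if isinstance(model, DCRNN):
                eps = scheduled_sampling_prob(iteration, schedule.tau)
                pred = model.forward(xb, teacher=Tensor(yb), eps=eps, rng=rng)
            else:
                pred = model.forward(xb)
            loss = (pred - Tensor(yb)).abs().mean()
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}"
                )
            model.zero_grad()
            loss.backward()
            if schedule.clip_norm is not None:
                clip_grad_norm(params, schedule.clip_norm)
            opt.lr = lr
            opt.step()
            epoch_losses.append(float(loss.data))
            iteration += 1

        train_mae = float(np.mean(epoch_losses))
        if Xv is not None:
            val_mae = _evaluate(model, Xv, Yv, max(schedule.batch_size, 32))
        else:
            val_mae = train_mae
        history["train_mae"].append(train_mae)
        history["val_mae"].append(val_mae)
        history["lr"].append(lr)

        if val_mae < best_val - 1e-12:
            best_val = val_mae
            best_state = model.state_dict()
            since_improve = 0
        else:
            since_improve += 1

        # scheduled decay, or early decay after a validation plateau
        due = decays and (epoch >= decays[0] or since_improve > schedule.patience)
        if due:
            if schedule.restore_best:
                model.load_state_dict(best_state)
            lr *= schedule.decay_factor
            decays.pop(0)
            since_improve = 0

    if schedule.restore_best:
        model.load_state_dict(best_state)
    history["best_val_mae"] = best_val if Xv is not None else min(
        history["val_mae"])
    return model, history
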