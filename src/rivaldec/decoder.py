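"""One-hidden-layer feed-forward classifier with log-sigmoid units.

The network maps an N-ROI input row to two outputs in (0,1) — a face score
and a house score — through a 65-unit hidden layer; both layers use the
logistic (log-sigmoid) activation.  Training is full-batch gradient descent
on the mean squared error against one-hot targets, with a random 75/25
train/validation split; the weights kept are those at the minimum of the
validation MSE.  Training that fails to reach MSE < 0.02 is restarted from
fresh random weights.  At decode time a rivalry time point is assigned to
the stimulus whose output exceeds the other by more than 0.9; otherwise it
is unassigned, and the whole train+classify procedure is reiterated until
fewer than 16.7% of time points are unassigned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from numba import njit

__all__ = [
    "AnnModel",
    "TrainConfig",
    "TrainingRecord",
    "ClassificationOutput",
    "ConvergenceError",
    "init_network",
    "forward",
    "mse_and_gradients",
    "train",
    "classify",
    "decode_with_reiteration",
]

HIDDEN_DEFAULT = 65


class ConvergenceError(RuntimeError):
    """Training or reiteration budget exhausted; carries the best attempt."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


@dataclass
class TrainConfig:
    """Training and decoding thresholds.

    The defaults are the method's fixed operating points: train/validation
    split 75/25, acceptance at validation MSE < 0.02, assignment margin 0.9,
    and at most 1/6 of time points left unassigned.
    """

    hidden: int = HIDDEN_DEFAULT
    mse_threshold: float = 0.02
    train_fraction: float = 0.75
    margin: float = 0.9
    max_unassigned: float = 1.0 / 6.0
    learning_rate: float = 0.05
    adaptive_lr: bool = False
    max_epochs: int = 8000
    max_restarts: int = 20
    max_reiterations: int = 50
    seed: int = 0

    def __post_init__(self):
        for name in ("mse_threshold", "train_fraction", "margin", "max_unassigned", "learning_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0,1)")


@dataclass
class TrainingRecord:
    final_val_mse: float
    restarts_used: int
    epochs_at_best: int
    seed: int


@dataclass
class AnnModel:
    w1: np.ndarray  # (hidden, n_inputs)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (2, hidden)
    b2: np.ndarray  # (2,)
    record: TrainingRecord | None = None

    @property
    def n_inputs(self) -> int:
        return self.w1.shape[1]

    def copy(self) -> "AnnModel":
        return AnnModel(self.w1.copy(), self.b1.copy(), self.w2.copy(), self.b2.copy(), self.record)

    def to_json(self) -> str:
        d = {
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2.tolist(),
            "record": asdict(self.record) if self.record else None,
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "AnnModel":
        d = json.loads(text)
        rec = TrainingRecord(**d["record"]) if d.get("record") else None
        return cls(
            np.asarray(d["w1"]), np.asarray(d["b1"]), np.asarray(d["w2"]), np.asarray(d["b2"]), rec
        )


@dataclass
class ClassificationOutput:
    """Per-time-point network scores and thresholded assignments."""

    X: np.ndarray            # (N, 2): face score, house score
    assignments: np.ndarray  # object array of 'face' / 'house' / 'unassigned'
    margin: float

    @property
    def unassigned_fraction(self) -> float:
        return float(np.mean(self.assignments == "unassigned"))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"t": np.arange(len(self.assignments)), "x1": self.X[:, 0], "x2": self.X[:, 1],
             "assignment": self.assignments}
        )


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def init_network(n_inputs: int, hidden: int = HIDDEN_DEFAULT, seed: int = 0) -> AnnModel:
    """Seeded initialization: weights uniform in (-w, w) with w = 1/sqrt(fan_in),
    biases zero."""
    if n_inputs < 1:
        raise ValueError("need at least one input")
    rng = np.random.default_rng(seed)
    w_in = 1.0 / np.sqrt(n_inputs)
    w_hid = 1.0 / np.sqrt(hidden)
    return AnnModel(
        w1=rng.uniform(-w_in, w_in, size=(hidden, n_inputs)),
        b1=np.zeros(hidden),
        w2=rng.uniform(-w_hid, w_hid, size=(2, hidden)),
        b2=np.zeros(2),
    )


def forward(model: AnnModel, inputs: np.ndarray) -> np.ndarray:
    """Network outputs for one row or a batch; each output lies in (0,1)."""
    u = np.atleast_2d(np.asarray(inputs, dtype=float))
    if u.shape[1] != model.n_inputs:
        raise ValueError(f"expected {model.n_inputs} inputs, got {u.shape[1]}")
    h = _sigmoid(u @ model.w1.T + model.b1)
    x = _sigmoid(h @ model.w2.T + model.b2)
    return x[0] if np.asarray(inputs).ndim == 1 else x


def mse_and_gradients(model: AnnModel, U: np.ndarray, T: np.ndarray):
    """Full-batch MSE and its analytic gradients (backpropagation).

    MSE is the mean of squared output errors over all samples and both
    output units.
    """
    H = _sigmoid(U @ model.w1.T + model.b1)
    Y = _sigmoid(H @ model.w2.T + model.b2)
    E = Y - T
    mse = float(np.mean(E * E))
    dY = (2.0 / E.size) * E * Y * (1.0 - Y)
    gw2 = dY.T @ H
    gb2 = dY.sum(axis=0)
    dH = (dY @ model.w2) * H * (1.0 - H)
    gw1 = dH.T @ U
    gb1 = dH.sum(axis=0)
    return mse, {"w1": gw1, "b1": gb1, "w2": gw2, "b2": gb2}


def _val_mse(model: AnnModel, U, T) -> float:
    H = _sigmoid(U @ model.w1.T + model.b1)
    Y = _sigmoid(H @ model.w2.T + model.b2)
    return float(np.mean((Y - T) ** 2))


@njit(cache=True)
def _gd_loop(Utr, Ttr, Uva, Tva, w1, b1, w2, b2, lr, epochs, adaptive):  # pragma: no cover
    """Full-batch gradient-descent epochs, keeping the weights at the
    minimum of the validation MSE.  Compiled for speed; the analytic
    gradients here mirror :func:`mse_and_gradients`."""
    best_val = np.inf
    bw1, bb1, bw2, bb2 = w1.copy(), b1.copy(), w2.copy(), b2.copy()
    best_epoch = 0
    prev_train = np.inf
    for ep in range(1, epochs + 1):
        H = 1.0 / (1.0 + np.exp(-(Utr @ w1.T + b1)))
        Y = 1.0 / (1.0 + np.exp(-(H @ w2.T + b2)))
        E = Y - Ttr
        scale = 2.0 / E.size
        train_mse = (E * E).mean()
        dY = scale * E * Y * (1.0 - Y)
        gw2 = dY.T @ H
        gb2 = dY.sum(axis=0)
        dH = (dY @ w2) * H * (1.0 - H)
        gw1 = dH.T @ Utr
        gb1 = dH.sum(axis=0)
        w1 -= lr * gw1
        b1 -= lr * gb1
        w2 -= lr * gw2
        b2 -= lr * gb2
        Hv = 1.0 / (1.0 + np.exp(-(Uva @ w1.T + b1)))
        Yv = 1.0 / (1.0 + np.exp(-(Hv @ w2.T + b2)))
        Ev = Yv - Tva
        val = (Ev * Ev).mean()
        if val < best_val:
            best_val = val
            best_epoch = ep
            bw1[:] = w1
            bb1[:] = b1
            bw2[:] = w2
            bb2[:] = b2
        if adaptive:
            lr = lr * 1.05 if train_mse < prev_train else lr * 0.7
            prev_train = train_mse
    return bw1, bb1, bw2, bb2, best_val, best_epoch


def _train_once(U, T, cfg: TrainConfig, seed: int):
    rng = np.random.default_rng(seed)
    n = U.shape[0]
    idx = rng.permutation(n)
    ntr = int(round(cfg.train_fraction * n))
    tr_idx, va_idx = idx[:ntr], idx[ntr:]
    model = init_network(U.shape[1], cfg.hidden, seed=seed)
    init_val = _val_mse(model, U[va_idx], T[va_idx])
    w1, b1, w2, b2, best_val, best_epoch = _gd_loop(
        np.ascontiguousarray(U[tr_idx]), np.ascontiguousarray(T[tr_idx]),
        np.ascontiguousarray(U[va_idx]), np.ascontiguousarray(T[va_idx]),
        model.w1, model.b1, model.w2, model.b2,
        cfg.learning_rate, cfg.max_epochs, cfg.adaptive_lr,
    )
    if init_val < best_val:  # the untrained net was already (vacuously) best
        return model, init_val, 0
    return AnnModel(w1, b1, w2, b2), best_val, best_epoch


def train(task_matrix: np.ndarray, targets: np.ndarray, cfg: TrainConfig, seed: int | None = None) -> AnnModel:
    """Train with restarts until validation MSE < ``cfg.mse_threshold``.

    Each attempt reinitializes weights and re-randomizes the 75/25 split
    from a fresh derived seed.  Raises :class:`ConvergenceError` (carrying
    the best model) if the threshold is never reached.
    """
    U = np.asarray(task_matrix, dtype=float)
    T = np.asarray(targets, dtype=float)
    if U.shape[0] < 8:
        raise ValueError("need at least 8 rows to split 75/25 meaningfully")
    if T.shape != (U.shape[0], 2) or not np.all(np.isin(T, (0.0, 1.0))):
        raise ValueError("targets must be one-hot rows of shape (n, 2)")
    base = cfg.seed if seed is None else seed
    best_overall, best_val_overall = None, np.inf
    for attempt in range(cfg.max_restarts):
        model, val, epoch = _train_once(U, T, cfg, seed=base + attempt)
        if val < best_val_overall:
            best_overall, best_val_overall = model, val
            best_overall.record = TrainingRecord(
                final_val_mse=val, restarts_used=attempt, epochs_at_best=epoch, seed=base + attempt
            )
        if val < cfg.mse_threshold:
            return best_overall
    raise ConvergenceError(
        f"validation MSE {best_val_overall:.4f} never dropped below "
        f"{cfg.mse_threshold} in {cfg.max_restarts} restarts",
        best=best_overall,
    )


def classify(model: AnnModel, br_matrix: np.ndarray, margin: float = 0.9) -> ClassificationOutput:
    """Thresholded assignment: face if x1-x2 > margin, house if x2-x1 > margin,
    else unassigned (discarded)."""
    X = forward(model, np.atleast_2d(br_matrix))
    diff = X[:, 0] - X[:, 1]
    assignments = np.where(diff > margin, "face", np.where(-diff > margin, "house", "unassigned"))
    return ClassificationOutput(X=X, assignments=assignments.astype(object), margin=margin)


def decode_with_reiteration(
    bnr_inputs, br_inputs, cfg: TrainConfig, seed: int | None = None
):
    """Train on localizer inputs and decode the rivalry run, reiterating the
    whole train+classify procedure with fresh seeds until the unassigned
    fraction drops below ``cfg.max_unassigned``.

    ``bnr_inputs`` / ``br_inputs`` are :class:`~rivaldec.sigprep.PreparedInputs`
    (or anything with ``task_matrix`` / ``target_matrix``).  Returns
    ``(model, output, n_iterations)``.
    """
    if bnr_inputs.task_matrix.shape[1] != br_inputs.task_matrix.shape[1]:
        raise ValueError("localizer and rivalry inputs have different ROI counts")
    base = cfg.seed if seed is None else seed
    best = None
    for it in range(cfg.max_reiterations):
        model = train(bnr_inputs.task_matrix, bnr_inputs.target_matrix, cfg, seed=base + 1000 * it)
        out = classify(model, br_inputs.task_matrix, cfg.margin)
        if best is None or out.unassigned_fraction < best[1].unassigned_fraction:
            best = (model, out, it + 1)
        # strict bound, except that a bound of 1 accepts anything (including
        # the fully-unassigned degenerate output)
        if out.unassigned_fraction < cfg.max_unassigned or cfg.max_unassigned >= 1.0:
            return model, out, it + 1
    raise ConvergenceError(
        f"unassigned fraction {best[1].unassigned_fraction:.3f} never fell below "
        f"{cfg.max_unassigned:.3f} in {cfg.max_reiterations} reiterations",
        best=best,
    )
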