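"""Neural-network yield surrogate: a 4-input, one-hidden-layer, one-output MLP.

The network maps the four reaction conditions (temperature, geniposide dose,
glycine dose, time) to gardenia-blue yield.  Inputs and target are linearly
rescaled to [−1, +1]; the hidden layer uses hyperbolic-tangent units and the
output is linear, so the model is

    yhat = W2 · tanh(W1 x + b1) + b2          (all on the normalized scale).

Training is full-batch gradient descent on the mean-squared error with a
momentum term and an adaptive learning rate: after each epoch the tentative
step is kept only if the MSE did not grow by more than ``max_perf_inc``
relative to the previous epoch; on rejection the step is discarded, the
velocity reset and the rate shrunk by ``rate_down``, while every strict
improvement grows the rate by ``rate_up``.  Training stops at ``goal_mse``
(normalized scale) or ``max_epochs``, whichever comes first.

Hidden-layer width is chosen by k-fold cross-validation over a candidate
list, with a small tolerance that prefers the narrower network when CV error
is effectively tied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np


class TrainingError(RuntimeError):
    """Raised when training diverges (non-finite loss)."""


# ---------------------------------------------------------------------------
# min-max normalization to [-1, 1]


@dataclass(frozen=True)
class NormalizationParams:
    """Per-column min/max used to map data linearly onto [−1, +1]."""

    lo: np.ndarray
    hi: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return 2.0 * (X - self.lo) / (self.hi - self.lo) - 1.0

    def invert(self, Xn: np.ndarray) -> np.ndarray:
        Xn = np.asarray(Xn, dtype=float)
        return (Xn + 1.0) / 2.0 * (self.hi - self.lo) + self.lo


def minmax_fit(X: np.ndarray) -> NormalizationParams:
    """Fit column-wise [−1, 1] scaling; rejects constant columns."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    lo, hi = X.min(axis=0), X.max(axis=0)
    if np.any(hi <= lo):
        bad = int(np.argmax(hi <= lo))
        raise ValueError(f"column {bad} is constant; min-max scale degenerate")
    return NormalizationParams(lo=lo, hi=hi)


# ---------------------------------------------------------------------------
# model and configuration


@dataclass
class TrainConfig:
    """Hyper-parameters of the momentum + adaptive-rate batch trainer.

    Defaults follow the widely used toolbox implementation of this schedule:
    momentum 0.9, initial rate 0.01, rate growth 1.05 on improvement, rate
    shrink 0.7 on rejection, rejection threshold 1.04.  ``goal_mse`` is
    measured on the normalized target scale.
    """

    max_epochs: int = 2000
    goal_mse: float = 1e-4
    initial_rate: float = 0.01
    momentum: float = 0.9
    rate_up: float = 1.05
    rate_down: float = 0.7
    max_perf_inc: float = 1.04
    init: str = "nguyen-widrow"  # or "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.init not in ("nguyen-widrow", "uniform"):
            raise ValueError("init must be 'nguyen-widrow' or 'uniform'")
        if not (0.0 < self.rate_down < 1.0 < self.rate_up):
            raise ValueError("need 0 < rate_down < 1 < rate_up")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")
        if self.max_perf_inc <= 1.0:
            raise ValueError("max_perf_inc must exceed 1")
        if self.max_epochs < 1 or self.goal_mse <= 0 or self.initial_rate <= 0:
            raise ValueError("max_epochs, goal_mse and initial_rate must be positive")


@dataclass
class MLPModel:
    """Weights of the H-hidden-unit network plus the fitted normalization."""

    W1: np.ndarray  # (H, n_in)
    b1: np.ndarray  # (H,)
    W2: np.ndarray  # (H,)
    b2: float
    norm_x: NormalizationParams
    norm_y: NormalizationParams

    @property
    def hidden_size(self) -> int:
        return self.W1.shape[0]

    def forward_normalized(self, Xn: np.ndarray) -> np.ndarray:
        """Forward pass on already-normalized inputs; normalized output."""
        return mlp_forward(self.W1, self.b1, self.W2, self.b2, Xn)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict yields on the original scale from raw condition vectors."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        yn = self.forward_normalized(self.norm_x.apply(X))
        return self.norm_y.invert(yn[:, None])[:, 0]

    def save(self, path: str | Path) -> None:
        blob = {
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "W2": self.W2.tolist(),
            "b2": self.b2,
            "norm_x": {"lo": self.norm_x.lo.tolist(), "hi": self.norm_x.hi.tolist()},
            "norm_y": {"lo": self.norm_y.lo.tolist(), "hi": self.norm_y.hi.tolist()},
        }
        Path(path).write_text(json.dumps(blob, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "MLPModel":
        blob = json.loads(Path(path).read_text())
        return cls(
            W1=np.array(blob["W1"], dtype=float),
            b1=np.array(blob["b1"], dtype=float),
            W2=np.array(blob["W2"], dtype=float),
            b2=float(blob["b2"]),
            norm_x=NormalizationParams(
                lo=np.array(blob["norm_x"]["lo"]), hi=np.array(blob["norm_x"]["hi"])
            ),
            norm_y=NormalizationParams(
                lo=np.array(blob["norm_y"]["lo"]), hi=np.array(blob["norm_y"]["hi"])
            ),
        )


@dataclass
class FitReport:
    """Training outcome: normalized-scale MSEs, original-scale R², history."""

    train_mse: float
    epochs_run: int
    mse_history: list[float] = field(default_factory=list)
    test_mse: float | None = None
    r2: float | None = None
    r2_pearson: float | None = None


def mlp_forward(
    W1: np.ndarray, b1: np.ndarray, W2: np.ndarray, b2: float, Xn: np.ndarray
) -> np.ndarray:
    """yhat = W2 · tanh(W1 x + b1) + b2, vectorized over rows of ``Xn``."""
    Xn = np.atleast_2d(np.asarray(Xn, dtype=float))
    if Xn.shape[1] != W1.shape[1]:
        raise ValueError(
            f"input width {Xn.shape[1]} does not match W1 width {W1.shape[1]}"
        )
    return np.tanh(Xn @ W1.T + b1) @ W2 + b2


def _mse_and_grads(W1, b1, W2, b2, Xn, yn):
    """Batch MSE and its analytic gradients for every parameter block."""
    n = Xn.shape[0]
    A = np.tanh(Xn @ W1.T + b1)  # (n, H)
    err = A @ W2 + b2 - yn  # (n,)
    mse = float(err @ err) / n
    d = 2.0 * err / n  # dMSE/dyhat
    gW2 = A.T @ d
    gb2 = float(d.sum())
    dA = np.outer(d, W2) * (1.0 - A * A)  # (n, H)
    gW1 = dA.T @ Xn
    gb1 = dA.sum(axis=0)
    return mse, (gW1, gb1, gW2, gb2)


def init_weights(hidden: int, n_in: int, rng: np.random.Generator, scheme: str = "nguyen-widrow"):
    """Seeded weight initialization.

    ``"nguyen-widrow"`` (default) spreads the hidden-unit active regions
    evenly over the [−1, 1] input cube — the standard initializer for
    tanh-hidden networks trained on min-max-scaled data, and noticeably
    faster to converge here.  ``"uniform"`` draws every parameter from
    U(−0.5, 0.5).
    """
    if scheme == "uniform":
        W1 = rng.uniform(-0.5, 0.5, size=(hidden, n_in))
        b1 = rng.uniform(-0.5, 0.5, size=hidden)
    else:
        magnitude = 0.7 * hidden ** (1.0 / n_in)
        W1 = rng.uniform(-1.0, 1.0, size=(hidden, n_in))
        W1 = magnitude * W1 / np.linalg.norm(W1, axis=1, keepdims=True)
        if hidden == 1:
            b1 = np.zeros(1)
        else:
            b1 = magnitude * np.linspace(-1.0, 1.0, hidden) * np.sign(W1[:, 0])
    W2 = rng.uniform(-0.5, 0.5, size=hidden)
    b2 = float(rng.uniform(-0.5, 0.5))
    return W1, b1, W2, b2


def train_gdx(
    X: np.ndarray,
    y: np.ndarray,
    hidden: int,
    config: TrainConfig | None = None,
    norm_x: NormalizationParams | None = None,
    norm_y: NormalizationParams | None = None,
) -> tuple[MLPModel, FitReport]:
    """Train the surrogate on raw (conditions, yield) pairs.

    Normalization is fitted on the training data unless explicit parameters
    are supplied (as when evaluating on a held-out split scaled like the
    training set).  Identical configuration and seed give bit-identical
    weight trajectories.
    """
    config = config or TrainConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y row counts differ")
    if X.shape[0] < 2:
        raise ValueError("need at least two training rows")
    if hidden < 1:
        raise ValueError("hidden-layer size must be >= 1")

    norm_x = norm_x or minmax_fit(X)
    norm_y = norm_y or minmax_fit(y[:, None])
    Xn = norm_x.apply(X)
    yn = norm_y.apply(y[:, None])[:, 0]

    rng = np.random.default_rng(config.seed)
    W1, b1, W2, b2 = init_weights(hidden, X.shape[1], rng, config.init)
    vel = [np.zeros_like(W1), np.zeros_like(b1), np.zeros_like(W2), 0.0]

    lr = config.initial_rate
    mc = config.momentum
    mse, grads = _mse_and_grads(W1, b1, W2, b2, Xn, yn)
    history = [mse]
    epochs = 0
    for epoch in range(config.max_epochs):
        if mse <= config.goal_mse:
            break
        vel = [mc * v - lr * g for v, g in zip(vel, grads)]
        cand = (W1 + vel[0], b1 + vel[1], W2 + vel[2], b2 + vel[3])
        new_mse, new_grads = _mse_and_grads(*cand, Xn, yn)
        if not np.isfinite(new_mse):
            raise TrainingError(f"training diverged at epoch {epoch + 1}")
        epochs = epoch + 1
        if new_mse > config.max_perf_inc * mse:
            # reject: keep old weights, damp the rate, kill the momentum
            lr *= config.rate_down
            vel = [np.zeros_like(W1), np.zeros_like(b1), np.zeros_like(W2), 0.0]
        else:
            if new_mse < mse:
                lr *= config.rate_up
            W1, b1, W2, b2 = cand
            mse, grads = new_mse, new_grads
        history.append(mse)

    model = MLPModel(W1=W1, b1=b1, W2=W2, b2=b2, norm_x=norm_x, norm_y=norm_y)
    report = FitReport(train_mse=mse, epochs_run=epochs, mse_history=history)
    return model, report


def evaluate(model: MLPModel, X: np.ndarray, y: np.ndarray) -> FitReport:
    """Held-out metrics: normalized-scale MSE, original-scale R².

    R² = 1 − SS_res/SS_tot on the original yield scale; the squared Pearson
    correlation between predictions and truth is reported alongside.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if y.shape[0] < 2:
        raise ValueError("need at least two evaluation rows")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("zero-variance truth: R² undefined")
    pred = model.predict(X)
    ss_res = float(np.sum((y - pred) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    denom = np.std(pred) * np.std(y)
    r2p = float(np.corrcoef(pred, y)[0, 1] ** 2) if denom > 0 else 0.0
    yn = model.norm_y.apply(y[:, None])[:, 0]
    pn = model.norm_y.apply(pred[:, None])[:, 0]
    test_mse = float(np.mean((yn - pn) ** 2))
    return FitReport(
        train_mse=float("nan"),
        epochs_run=0,
        test_mse=test_mse,
        r2=r2,
        r2_pearson=r2p,
    )


def train_test_split(
    n: int, n_test: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded uniform random partition of ``range(n)`` into train/test indices."""
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


def select_hidden_size(
    X: np.ndarray,
    y: np.ndarray,
    candidates=tuple(range(2, 15)),
    k_folds: int = 5,
    seed: int = 0,
    config: TrainConfig | None = None,
    tie_tolerance: float = 0.05,
) -> tuple[int, dict[int, float]]:
    """Choose the hidden-layer width by k-fold cross-validation.

    Validation MSE is measured on the original yield scale so folds are
    comparable.  Among candidates whose mean CV error is within
    ``tie_tolerance`` (relative) of the minimum, the smallest network wins.
    Returns the selected width and the full CV curve.
    """
    candidates = tuple(int(h) for h in candidates)
    if not candidates:
        raise ValueError("candidate list is empty")
    if any(h < 1 for h in candidates):
        raise ValueError("hidden-layer candidates must be >= 1")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if not 2 <= k_folds <= n:
        raise ValueError("k_folds must be in [2, n]")
    config = config or TrainConfig()

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k_folds)
    fold_seeds = rng.integers(0, 2**31 - 1, size=(len(candidates), k_folds))

    curve: dict[int, float] = {}
    for ci, h in enumerate(candidates):
        errs = []
        for fi, val_idx in enumerate(folds):
            train_idx = np.setdiff1d(perm, val_idx)
            cfg = TrainConfig(**{**asdict(config), "seed": int(fold_seeds[ci, fi])})
            model, _ = train_gdx(X[train_idx], y[train_idx], h, cfg)
            pred = model.predict(X[val_idx])
            errs.append(float(np.mean((pred - y[val_idx]) ** 2)))
        curve[h] = float(np.mean(errs))

    best_err = min(curve.values())
    # CV errors below the training goal (rescaled to the original yield
    # units) are indistinguishable from converged fits: treat them as tied.
    half_span = (y.max() - y.min()) / 2.0
    floor = config.goal_mse * half_span * half_span
    cutoff = max((1.0 + tie_tolerance) * best_err, floor)
    eligible = [h for h in candidates if curve[h] <= cutoff]
    return min(eligible), curve
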