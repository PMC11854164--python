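"""Feed-forward 3-h-1 neural surrogate trained by error backpropagation.

The network maps the three extraction conditions (pH, enzyme addition %,
ultrasonic time min) to yield %.  Inputs and output are min-max scaled to
[-1, 1]; the hidden layer is tanh, the output linear.  Training is
full-batch gradient descent with momentum on the mean squared error of the
scaled output, with early stopping on a validation split (best-epoch
weights restored).  All randomness flows from a single seeded generator, so
a (data, config) pair is bit-reproducible.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np

from .design import Dataset

__all__ = [
    "MLPParams",
    "TrainConfig",
    "TrainHistory",
    "StopReason",
    "hidden_size",
    "split_dataset",
    "forward",
    "train",
    "backprop_gradient",
    "regression_report",
    "error_histogram",
    "save_params",
    "load_params",
]


class StopReason(str, Enum):
    PATIENCE = "patience"
    MAX_EPOCHS = "max_epochs"
    GOAL = "goal"


def hidden_size(n_inputs: int, n_outputs: int, a: int) -> int:
    """Empirical hidden-layer sizing rule round(sqrt(n_in + n_out)) + a.

    With 3 inputs, 1 output and a = 8 this gives the 10 hidden neurons used
    by the reference 3-10-1 topology.
    """
    if n_inputs < 1 or n_outputs < 1:
        raise ValueError("layer sizes must be >= 1")
    if not 1 <= a <= 10:
        raise ValueError(f"constant a must lie in [1, 10], got {a}")
    return int(round(math.sqrt(n_inputs + n_outputs))) + a


@dataclass
class MLPParams:
    """Weights, biases and scalers of the single-hidden-layer network."""

    hidden_weights: np.ndarray  # h x 3
    hidden_biases: np.ndarray  # h
    output_weights: np.ndarray  # 1 x h
    output_bias: float
    input_scaler: np.ndarray  # 3 x 2 columns (min, max)
    output_scaler: tuple[float, float]

    @property
    def layer_sizes(self) -> tuple[int, int, int]:
        h, n_in = self.hidden_weights.shape
        return (n_in, h, 1)

    @property
    def n_parameters(self) -> int:
        n_in, h, n_out = self.layer_sizes
        return (n_in + 1) * h + (h + 1) * n_out


@dataclass
class TrainConfig:
    learning_rate: float = 0.1
    momentum: float = 0.9
    max_epochs: int = 8000
    patience: int = 300
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    goal_mse: float = 0.0  # scaled-output MSE at which training stops early
    hidden: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must lie in [0, 1)")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class TrainHistory:
    train_mse: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)
    test_mse: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stop_reason: StopReason = StopReason.MAX_EPOCHS


def split_dataset(
    n: int | Dataset,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random disjoint (train, validation, test) index sets.

    Validation and test sizes are the fractions rounded to the nearest
    integer; train receives the remainder.  The permutation is driven solely
    by ``seed``.
    """
    if isinstance(n, Dataset):
        n = len(n.observed())
    if n < 3:
        raise ValueError("need at least 3 points to split")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n_val = round(fractions[1] * n)
    n_test = round(fractions[2] * n)
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(
            f"split of {n} points into {fractions} leaves an empty subset "
            f"({n_train}, {n_val}, {n_test})"
        )
    perm = np.random.default_rng(seed).permutation(n)
    return perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]


# ----------------------------------------------------------------- scaling


def _fit_scaler(values: np.ndarray) -> np.ndarray:
    """Per-column (min, max) pairs; degenerate columns rejected."""
    vmin, vmax = values.min(axis=0), values.max(axis=0)
    if np.any(vmax <= vmin):
        raise ValueError("cannot scale a constant variable (max <= min)")
    return np.column_stack([vmin, vmax])


def _scale(values: np.ndarray, scaler: np.ndarray) -> np.ndarray:
    lo, hi = scaler[..., 0], scaler[..., 1]
    return 2.0 * (values - lo) / (hi - lo) - 1.0


def _unscale(scaled: np.ndarray, scaler: np.ndarray) -> np.ndarray:
    lo, hi = scaler[..., 0], scaler[..., 1]
    return lo + (scaled + 1.0) * (hi - lo) / 2.0


def forward(params: MLPParams, raw_input: Sequence[float]) -> float | np.ndarray:
    """Predicted yield % for raw (pH, enzyme %, time min) inputs.

    Extrapolation is permitted but flagged with a warning once any scaled
    coordinate leaves [-1.5, 1.5].
    """
    x = np.atleast_2d(np.asarray(raw_input, dtype=float))
    xs = _scale(x, params.input_scaler)
    if np.any(np.abs(xs) > 1.5):
        warnings.warn("input far outside the training range; extrapolating", stacklevel=2)
    hidden = np.tanh(xs @ params.hidden_weights.T + params.hidden_biases)
    ys = hidden @ params.output_weights.T + params.output_bias
    out = _unscale(ys[:, 0], np.array(params.output_scaler))
    return float(out[0]) if np.asarray(raw_input).ndim == 1 else out


# ---------------------------------------------------------------- training


def _net_forward_scaled(w1, b1, w2, b2, xs):
    hidden = np.tanh(xs @ w1.T + b1)
    return hidden @ w2.T + b2, hidden


def backprop_gradient(w1, b1, w2, b2, xs, ys):
    """Analytic gradient of MSE = mean((pred - ys)^2) w.r.t. all parameters."""
    n = len(xs)
    pred, hidden = _net_forward_scaled(w1, b1, w2, b2, xs)
    err = (pred - ys) * (2.0 / n)  # n x 1
    g_w2 = err.T @ hidden
    g_b2 = float(err.sum())
    back = (err @ w2) * (1.0 - hidden**2)  # n x h
    g_w1 = back.T @ xs
    g_b1 = back.sum(axis=0)
    return g_w1, g_b1, g_w2, g_b2


def _mse(w1, b1, w2, b2, xs, ys) -> float:
    pred, _ = _net_forward_scaled(w1, b1, w2, b2, xs)
    with np.errstate(over="ignore"):  # divergence is detected and reported upstream
        return float(np.mean((pred - ys) ** 2))


def train(
    data: Dataset, config: TrainConfig | None = None
) -> tuple[MLPParams, TrainHistory]:
    """Train the surrogate on a dataset's observed runs.

    Weights start from a seeded uniform(-0.5, 0.5); each epoch is one
    full-batch gradient step with momentum.  Validation MSE is checked every
    epoch; after ``patience`` checks without improvement training stops and
    the best-epoch weights are restored.
    """
    config = config or TrainConfig()
    obs = data.observed()
    X = obs.actual_matrix
    y = obs.yields.reshape(-1, 1)
    idx_train, idx_val, idx_test = split_dataset(
        len(obs), config.split_fractions, config.seed
    )
    in_scaler = _fit_scaler(X)
    out_scaler = _fit_scaler(y)[0]
    Xs, ys = _scale(X, in_scaler), _scale(y, np.array(out_scaler))
    xs_tr, ys_tr = Xs[idx_train], ys[idx_train]
    xs_va, ys_va = Xs[idx_val], ys[idx_val]
    xs_te, ys_te = Xs[idx_test], ys[idx_test]

    h = config.hidden
    rng = np.random.default_rng(config.seed)
    w1 = rng.uniform(-0.5, 0.5, size=(h, 3))
    b1 = rng.uniform(-0.5, 0.5, size=h)
    w2 = rng.uniform(-0.5, 0.5, size=(1, h))
    b2 = float(rng.uniform(-0.5, 0.5))
    vel = [np.zeros_like(w1), np.zeros_like(b1), np.zeros_like(w2), 0.0]

    hist = TrainHistory()
    best = (math.inf, -1, None)
    stale = 0
    stop = StopReason.MAX_EPOCHS
    for epoch in range(config.max_epochs + 1):
        tr = _mse(w1, b1, w2, b2, xs_tr, ys_tr)
        va = _mse(w1, b1, w2, b2, xs_va, ys_va)
        te = _mse(w1, b1, w2, b2, xs_te, ys_te)
        if not (math.isfinite(tr) and math.isfinite(va)):
            raise FloatingPointError(
                f"training diverged at epoch {epoch} "
                f"(learning_rate={config.learning_rate})"
            )
        hist.train_mse.append(tr)
        hist.val_mse.append(va)
        hist.test_mse.append(te)
        if va < best[0]:
            best = (va, epoch, (w1.copy(), b1.copy(), w2.copy(), b2))
            stale = 0
        else:
            stale += 1
        if tr <= config.goal_mse:
            stop = StopReason.GOAL
            break
        if stale >= config.patience:
            stop = StopReason.PATIENCE
            break
        if epoch == config.max_epochs:
            break
        grads = backprop_gradient(w1, b1, w2, b2, xs_tr, ys_tr)
        for k, g in enumerate(grads):
            vel[k] = config.momentum * vel[k] - config.learning_rate * g
        w1, b1 = w1 + vel[0], b1 + vel[1]
        w2, b2 = w2 + vel[2], b2 + vel[3]

    hist.best_epoch = best[1]
    hist.stop_reason = stop
    w1, b1, w2, b2 = best[2]
    params = MLPParams(
        hidden_weights=w1,
        hidden_biases=b1,
        output_weights=w2,
        output_bias=float(b2),
        input_scaler=in_scaler,
        output_scaler=(float(out_scaler[0]), float(out_scaler[1])),
    )
    return params, hist


# --------------------------------------------------------------- reporting


def regression_report(
    params: MLPParams,
    data: Dataset,
    splits: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> dict[str, dict[str, float | None]]:
    """Pearson R plus prediction-vs-target regression line per subset.

    Returns a mapping subset -> {r, slope, intercept, n}; subsets are
    'train'/'validation'/'test' (when splits are given) and 'overall'.
    Subsets with fewer than 2 points, or with constant predictions, report
    r as None.
    """
    obs = data.observed()
    preds = np.asarray(forward(params, obs.actual_matrix))
    targets = obs.yields
    report: dict[str, dict[str, float | None]] = {}

    def entry(p: np.ndarray, t: np.ndarray) -> dict[str, float | None]:
        n = len(p)
        if n < 2 or np.std(p) == 0 or np.std(t) == 0:
            return {"r": None, "slope": None, "intercept": None, "n": n}
        r = float(np.corrcoef(t, p)[0, 1])
        slope, intercept = np.polyfit(t, p, 1)
        return {"r": r, "slope": float(slope), "intercept": float(intercept), "n": n}

    if splits is not None:
        for name, idx in zip(("train", "validation", "test"), splits):
            report[name] = entry(preds[idx], targets[idx])
    report["overall"] = entry(preds, targets)
    return report


def error_histogram(
    params: MLPParams, data: Dataset, n_bins: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width histogram of prediction errors (target - prediction)."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    obs = data.observed()
    errors = obs.yields - np.asarray(forward(params, obs.actual_matrix))
    lo, hi = errors.min(), errors.max()
    if lo == hi:  # all errors identical: one degenerate-width bin
        hi = lo + 1e-12
    counts, edges = np.histogram(errors, bins=n_bins, range=(lo, hi))
    return edges, counts


# ------------------------------------------------------------ serialization


def save_params(
    params: MLPParams,
    path: str | Path,
    config: TrainConfig | None = None,
) -> None:
    doc = {
        "layer_sizes": list(params.layer_sizes),
        "hidden_weights": params.hidden_weights.ravel().tolist(),
        "hidden_biases": params.hidden_biases.tolist(),
        "output_weights": params.output_weights.ravel().tolist(),
        "output_bias": params.output_bias,
        "input_scaler": params.input_scaler.tolist(),
        "output_scaler": list(params.output_scaler),
    }
    if config is not None:
        doc["config"] = {
            "learning_rate": config.learning_rate,
            "momentum": config.momentum,
            "max_epochs": config.max_epochs,
            "patience": config.patience,
            "split_fractions": list(config.split_fractions),
            "hidden": config.hidden,
            "seed": config.seed,
        }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def load_params(path: str | Path) -> MLPParams:
    doc = json.loads(Path(path).read_text())
    n_in, h, _ = doc["layer_sizes"]
    return MLPParams(
        hidden_weights=np.array(doc["hidden_weights"]).reshape(h, n_in),
        hidden_biases=np.array(doc["hidden_biases"]),
        output_weights=np.array(doc["output_weights"]).reshape(1, h),
        output_bias=float(doc["output_bias"]),
        input_scaler=np.array(doc["input_scaler"]),
        output_scaler=tuple(doc["output_scaler"]),
    )
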