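"""Feed-forward neural-network surrogate (4-H-1) for the CCD response.

A single hidden layer of H nodes maps the four scaled process factors to
the scaled percentage removal: each hidden node computes an activation of
``sum_i x_i w_i + theta`` (tanh-sigmoid by default, logistic selectable)
and the output node is linear.  Training is full-batch gradient descent
on the scaled training MSE with momentum and a multiplicative adaptive
learning rate: the rate grows by ``lr_inc`` after an improving step and
shrinks by ``lr_dec`` (with the step rejected) when the loss worsens by
more than ``max_perf_inc``.  Inputs and output are scaled to [-1, 1] by
the training-split min/max.

Because the network is a small interpolator of a 24-point design, weight
selection matters more than convergence: ``train`` can snapshot the
weights with the lowest held-out (test-split) MSE seen along the
trajectory, and ``train_restarts`` picks the restart with the lowest
test MSE, which is the selection rule the original study describes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .dataset import CCDDataset
from .errors import ConfigurationError

__all__ = [
    "MLPNetwork",
    "TrainConfig",
    "TrainResult",
    "EvalStats",
    "forward",
    "train",
    "train_restarts",
    "evaluate",
]


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "tanh":
        return np.tanh(z)
    if kind == "logistic":
        return 1.0 / (1.0 + np.exp(-z))
    raise ValueError(f"unknown activation {kind!r}")


def _act_deriv(a: np.ndarray, kind: str) -> np.ndarray:
    # expressed in terms of the activation value a
    if kind == "tanh":
        return 1.0 - a**2
    return a * (1.0 - a)


@dataclass
class MLPNetwork:
    """Weights, biases and scaling of the 4-H-1 surrogate."""

    hidden_weights: np.ndarray  # (H, 4)
    hidden_bias: np.ndarray  # (H,)
    output_weights: np.ndarray  # (H,)
    output_bias: float
    hidden_activation: str = "tanh"
    input_min: np.ndarray = field(default_factory=lambda: np.full(4, -1.0))
    input_max: np.ndarray = field(default_factory=lambda: np.full(4, 1.0))
    output_min: float = -1.0
    output_max: float = 1.0

    def __post_init__(self) -> None:
        self.hidden_weights = np.asarray(self.hidden_weights, dtype=float)
        self.hidden_bias = np.asarray(self.hidden_bias, dtype=float)
        self.output_weights = np.asarray(self.output_weights, dtype=float)
        self.input_min = np.asarray(self.input_min, dtype=float)
        self.input_max = np.asarray(self.input_max, dtype=float)
        H = self.hidden_weights.shape[0]
        if self.hidden_weights.shape != (H, 4):
            raise ValueError("hidden_weights must have shape (H, 4)")
        if self.hidden_bias.shape != (H,) or self.output_weights.shape != (H,):
            raise ValueError("bias/output weight shapes inconsistent with H")

    @property
    def hidden_nodes(self) -> int:
        return self.hidden_weights.shape[0]

    # ---- scaling -----------------------------------------------------

    def scale_inputs(self, X: np.ndarray) -> np.ndarray:
        span = self.input_max - self.input_min
        return 2.0 * (X - self.input_min) / span - 1.0

    def scale_output(self, y: np.ndarray) -> np.ndarray:
        span = self.output_max - self.output_min
        return 2.0 * (y - self.output_min) / span - 1.0

    def unscale_output(self, ys: np.ndarray) -> np.ndarray:
        span = self.output_max - self.output_min
        return (ys + 1.0) / 2.0 * span + self.output_min

    # ---- forward pass ------------------------------------------------

    def forward_scaled(self, Xs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Scaled-space forward pass; returns (output, hidden activations)."""
        Xs = np.atleast_2d(Xs)
        a = _act(Xs @ self.hidden_weights.T + self.hidden_bias, self.hidden_activation)
        return a @ self.output_weights + self.output_bias, a

    def predict(self, X: Sequence[float] | np.ndarray) -> float | np.ndarray:
        """% removal predicted at actual-unit factor vector(s)."""
        X1 = np.atleast_2d(np.asarray(X, dtype=float))
        out, _ = self.forward_scaled(self.scale_inputs(X1))
        y = self.unscale_output(out)
        return float(y[0]) if np.ndim(X) == 1 else y

    # ---- JSON artifact ----------------------------------------------

    def to_dict(self) -> dict:
        return {
            "hidden_weights": self.hidden_weights.tolist(),
            "hidden_bias": self.hidden_bias.tolist(),
            "output_weights": self.output_weights.tolist(),
            "output_bias": self.output_bias,
            "hidden_activation": self.hidden_activation,
            "input_min": self.input_min.tolist(),
            "input_max": self.input_max.tolist(),
            "output_min": self.output_min,
            "output_max": self.output_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLPNetwork":
        return cls(
            hidden_weights=np.array(d["hidden_weights"]),
            hidden_bias=np.array(d["hidden_bias"]),
            output_weights=np.array(d["output_weights"]),
            output_bias=float(d["output_bias"]),
            hidden_activation=d["hidden_activation"],
            input_min=np.array(d["input_min"]),
            input_max=np.array(d["input_max"]),
            output_min=float(d["output_min"]),
            output_max=float(d["output_max"]),
        )


def forward(net: MLPNetwork, x: Sequence[float]) -> float:
    """Predicted % removal at an actual-unit 4-vector (pure function)."""
    return float(net.predict(np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the batch gradient-descent trainer."""

    hidden_nodes: int = 10
    learning_rate: float = 0.5
    momentum: float = 0.9
    max_epochs: int = 10000
    mse_goal: float = 0.001  # scaled units
    lr_inc: float = 1.05
    lr_dec: float = 0.7
    max_perf_inc: float = 1.04
    init_range: float = 0.5  # weights drawn uniform in [-init_range, init_range]
    activation: str = "tanh"
    monitor: str = "test"  # "test": snapshot weights at min test-split MSE; "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_nodes < 1:
            raise ConfigurationError("hidden_nodes must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")
        if not 0 <= self.momentum < 1:
            raise ConfigurationError("momentum must be in [0, 1)")
        if self.monitor not in ("test", "none"):
            raise ConfigurationError("monitor must be 'test' or 'none'")


@dataclass
class TrainResult:
    network: MLPNetwork
    epochs_run: int
    mse_train: float  # scaled units
    mse_test: float  # scaled units (nan if no test split)
    r2_all: float  # raw % units, all runs
    avg_pred_error_train: float  # mean |obs-pred|/obs*100 on the train split
    avg_pred_error_test: float
    config: TrainConfig | None = None
    mse_history: list[float] = field(default_factory=list)  # accepted steps


@dataclass
class EvalStats:
    mse_train: float
    mse_test: float
    r2_all: float
    avg_pred_error_train: float
    avg_pred_error_test: float


def _loss_and_grad(params, Xs, ys, activation):
    """Scaled-space MSE and its analytic gradient (backpropagation)."""
    W1, b1, W2, b2 = params
    a = _act(Xs @ W1.T + b1, activation)
    out = a @ W2 + b2
    err = out - ys
    n = len(ys)
    mse = float(np.mean(err**2))
    go = 2.0 * err / n  # dMSE/dout
    gW2 = go @ a
    gb2 = float(np.sum(go))
    gh = np.outer(go, W2) * _act_deriv(a, activation)
    gW1 = gh.T @ Xs
    gb1 = gh.sum(axis=0)
    return mse, (gW1, gb1, gW2, gb2)


def _init_params(rng: np.random.Generator, H: int, r: float):
    return (
        rng.uniform(-r, r, size=(H, 4)),
        rng.uniform(-r, r, size=H),
        rng.uniform(-r, r, size=H),
        float(rng.uniform(-r, r)),
    )


def train(dataset: CCDDataset, config: TrainConfig = TrainConfig()) -> TrainResult:
    """Train the surrogate on the dataset's training split.

    Deterministic under ``config.seed``.  With ``monitor='test'`` the
    returned weights are the snapshot with the lowest test-split MSE
    observed over accepted steps; training itself still runs until the
    MSE goal or the epoch budget.
    """
    train_ds = dataset.subset("train")
    if len(train_ds) == 0:
        raise ConfigurationError("dataset has no training rows")
    monitor = config.monitor
    test_ds = dataset.subset("test")
    if monitor == "test" and len(test_ds) == 0:
        monitor = "none"

    Xtr = train_ds.actual_matrix()
    ytr = train_ds.response()
    imin, imax = Xtr.min(axis=0), Xtr.max(axis=0)
    omin, omax = float(ytr.min()), float(ytr.max())

    def _mk_net(params) -> MLPNetwork:
        W1, b1, W2, b2 = params
        return MLPNetwork(
            W1.copy(), b1.copy(), W2.copy(), b2,
            hidden_activation=config.activation,
            input_min=imin, input_max=imax,
            output_min=omin, output_max=omax,
        )

    proto = _mk_net(_init_params(np.random.default_rng(0), config.hidden_nodes, 1.0))
    Xs = proto.scale_inputs(Xtr)
    ys = proto.scale_output(ytr)
    if monitor == "test":
        Xts = proto.scale_inputs(test_ds.actual_matrix())
        yts = proto.scale_output(test_ds.response())

    rng = np.random.default_rng(config.seed)
    params = _init_params(rng, config.hidden_nodes, config.init_range)
    vel = tuple(np.zeros_like(np.asarray(p)) for p in params)
    lr = config.learning_rate
    mse, grad = _loss_and_grad(params, Xs, ys, config.activation)

    def _test_mse(p):
        W1, b1, W2, b2 = p
        a = _act(Xts @ W1.T + b1, config.activation)
        return float(np.mean((a @ W2 + b2 - yts) ** 2))

    best_monitor = _test_mse(params) if monitor == "test" else np.inf
    best_params = tuple(np.copy(p) for p in params)
    history: list[float] = []
    epochs = 0
    for epochs in range(1, config.max_epochs + 1):
        vel = tuple(config.momentum * v - lr * g for v, g in zip(vel, grad))
        cand = tuple(p + v for p, v in zip(params, vel))
        mse_new, grad_new = _loss_and_grad(cand, Xs, ys, config.activation)
        if mse_new > mse * config.max_perf_inc:
            # reject the step, back off the rate, drop accumulated momentum
            lr *= config.lr_dec
            vel = tuple(np.zeros_like(np.asarray(p)) for p in params)
            continue
        if mse_new < mse:
            lr *= config.lr_inc
        params, mse, grad = cand, mse_new, grad_new
        history.append(mse)
        if monitor == "test":
            tm = _test_mse(params)
            if tm < best_monitor:
                best_monitor = tm
                best_params = tuple(np.copy(p) for p in params)
        if mse <= config.mse_goal:
            break

    final_params = best_params if monitor == "test" else params
    net = _mk_net(final_params)
    ev = evaluate(net, dataset)
    return TrainResult(
        network=net,
        epochs_run=epochs,
        mse_train=ev.mse_train,
        mse_test=ev.mse_test,
        r2_all=ev.r2_all,
        avg_pred_error_train=ev.avg_pred_error_train,
        avg_pred_error_test=ev.avg_pred_error_test,
        config=config,
        mse_history=history,
    )


def train_restarts(
    dataset: CCDDataset,
    config: TrainConfig = TrainConfig(),
    n_restarts: int = 10,
) -> TrainResult:
    """Train ``n_restarts`` networks from seeded random initialisations and
    return the one with the lowest test-split MSE (training MSE when the
    dataset has no test split)."""
    seeds = np.random.SeedSequence(config.seed).generate_state(n_restarts) % (2**31)
    results = [train(dataset, replace(config, seed=int(s))) for s in seeds]
    key = (
        (lambda r: r.mse_test)
        if not np.isnan(results[0].mse_test)
        else (lambda r: r.mse_train)
    )
    return min(results, key=key)


def evaluate(net: MLPNetwork, dataset: CCDDataset) -> EvalStats:
    """MSE per split (scaled units), R² over all runs (raw % units) and
    mean absolute percentage error per split."""
    obs_all = dataset.response()
    pred_all = np.asarray(net.predict(dataset.actual_matrix()))
    ss_res = float(np.sum((obs_all - pred_all) ** 2))
    ss_tot = float(np.sum((obs_all - obs_all.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan

    def _split_stats(split):
        mask = dataset.split_mask(split)
        if not mask.any():
            return np.nan, np.nan
        obs, pred = obs_all[mask], pred_all[mask]
        mse = float(np.mean((net.scale_output(obs) - net.scale_output(pred)) ** 2))
        mape = float(np.mean(np.abs((obs - pred) / obs)) * 100.0)
        return mse, mape

    mse_tr, mape_tr = _split_stats("train")
    mse_te, mape_te = _split_stats("test")
    return EvalStats(mse_tr, mse_te, float(r2), mape_tr, mape_te)
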