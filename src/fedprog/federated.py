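"""Logistic model, local SGD, and the FedAvg server loop.

The model is a single linear layer with a sigmoid: p = sigmoid(X w + b),
trained by minibatch gradient descent on mean binary cross-entropy.  In the
federated loop, the server broadcasts the global parameters to every client
each round; each client runs E local epochs of minibatch SGD on its private
shard and returns its updated parameters; the server aggregates them as the
sample-size-weighted average sum_k (n_k / n) * params_k.  The centralized
("NonFed") baseline is the identical optimizer run on the pooled training
set, i.e. FedAvg with a single client.

All randomness (initialization and per-epoch minibatch shuffles) is derived
deterministically from explicit integer seeds; a seed tuple
(seed, round, client, epoch) identifies every shuffle, so runs reproduce
bit-for-bit and a multi-epoch local update decomposes into single-epoch
updates with the corresponding epoch seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
from scipy.special import expit

__all__ = [
    "LinearModelParams",
    "FedConfig",
    "TrainingTrace",
    "init_params",
    "predict_proba",
    "bce_loss",
    "local_update",
    "aggregate",
    "run_fedavg",
    "train_centralized",
    "train_local_only",
]

_CLIP = 1e-12  # probability clipping inside the loss only, never in predictions


@dataclass
class LinearModelParams:
    """Weights and bias of the logistic model."""

    w: np.ndarray
    b: float

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.b = float(self.b)
        if self.w.ndim != 1:
            raise ValueError("w must be a vector")
        if not (np.isfinite(self.w).all() and np.isfinite(self.b)):
            raise ValueError("parameters must be finite")

    @property
    def p(self) -> int:
        return self.w.size

    def copy(self) -> "LinearModelParams":
        return LinearModelParams(self.w.copy(), self.b)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"w": self.w.tolist(), "b": self.b}, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "LinearModelParams":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(np.array(payload["w"]), payload["b"])


@dataclass
class FedConfig:
    """FedAvg hyperparameters: K clients, minibatch size B, E local epochs
    per round, learning rate eta, T communication rounds.

    Defaults are standard FedAvg practice for small tabular problems;
    ``convergence_tol`` stops early when the max-norm parameter change of a
    round falls below it.  ``pos_weight`` optionally up-weights positive
    samples in the loss (defaults to 1: unweighted, matching a plain mean
    cross-entropy despite the ~4.4% prevalence).
    """

    K: int = 5
    B: int = 32
    E: int = 1
    eta: float = 0.05
    rounds: int = 200
    seed: int = 0
    convergence_tol: float | None = 1e-6
    pos_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.K < 1 or self.B < 1 or self.E < 1:
            raise ValueError("K, B and E must all be >= 1")
        if self.eta < 0:
            raise ValueError("eta must be nonnegative")
        if self.rounds < 0:
            raise ValueError("rounds must be >= 0")
        if self.pos_weight <= 0:
            raise ValueError("pos_weight must be positive")


@dataclass
class TrainingTrace:
    """Per-round history: global params (incl. initialization), the max-norm
    parameter change of each round, and validation AUC when available."""

    params_history: list[LinearModelParams] = field(default_factory=list)
    param_deltas: list[float] = field(default_factory=list)
    validation_auc: list[float] = field(default_factory=list)

    @property
    def executed_rounds(self) -> int:
        return len(self.params_history) - 1

    def to_csv(self, path) -> None:
        import pandas as pd

        n = len(self.params_history)
        df = pd.DataFrame(
            {
                "round": np.arange(n),
                "param_delta": [np.nan] + self.param_deltas,
                "validation_auc": self.validation_auc
                if self.validation_auc
                else [np.nan] * n,
            }
        )
        df.to_csv(path, index=False)


def init_params(p: int, seed: int = 0) -> LinearModelParams:
    """Small seeded random start: weights uniform in [-0.01, 0.01], bias 0."""
    if p < 1:
        raise ValueError("need at least one feature")
    rng = np.random.default_rng(seed)
    return LinearModelParams(rng.uniform(-0.01, 0.01, size=p), 0.0)


def predict_proba(params: LinearModelParams, X: np.ndarray) -> np.ndarray:
    """sigmoid(X w + b), elementwise in (0, 1); unclipped."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != params.p:
        raise ValueError(
            f"X must be 2-D with {params.p} columns, got shape {X.shape}"
        )
    return expit(X @ params.w + params.b)


def _sample_weights(y: np.ndarray, pos_weight: float) -> np.ndarray:
    if pos_weight == 1.0:
        return np.ones_like(y, dtype=float)
    return np.where(y == 1, pos_weight, 1.0)


def bce_loss(
    params: LinearModelParams, X: np.ndarray, y: np.ndarray, pos_weight: float = 1.0
) -> float:
    """Mean binary cross-entropy, probabilities clipped to [1e-12, 1-1e-12]."""
    p = np.clip(predict_proba(params, X), _CLIP, 1.0 - _CLIP)
    y = np.asarray(y, dtype=float)
    w = _sample_weights(y, pos_weight)
    ll = y * np.log(p) + (1.0 - y) * np.log1p(-p)
    return float(-(w * ll).sum() / w.sum())


def _as_seed_tuple(seed) -> tuple[int, ...]:
    if isinstance(seed, (int, np.integer)):
        return (int(seed),)
    return tuple(int(s) for s in seed)


def local_update(
    params: LinearModelParams,
    X: np.ndarray,
    y: np.ndarray,
    B: int,
    E: int,
    eta: float,
    seed,
    epoch_offset: int = 0,
    pos_weight: float = 1.0,
) -> LinearModelParams:
    """E epochs of minibatch gradient descent on mean binary cross-entropy.

    Each epoch reshuffles the rows with a generator seeded by
    (*seed, epoch_offset + epoch); batches have size B (last one possibly
    smaller).  The gradient of the mean loss over a batch of size m is
    grad_w = (1/m) X^T (sigmoid(Xw+b) - y), grad_b = mean(sigmoid(Xw+b) - y)
    (weighted-mean form when ``pos_weight`` != 1).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("client data must be non-empty")
    if B < 1 or E < 1:
        raise ValueError("B and E must be >= 1")
    base = _as_seed_tuple(seed)
    w = params.w.copy()
    b = params.b
    n = X.shape[0]
    for e in range(E):
        rng = np.random.default_rng(base + (epoch_offset + e,))
        order = rng.permutation(n)
        for start in range(0, n, B):
            batch = order[start : start + B]
            Xb, yb = X[batch], y[batch]
            resid = expit(Xb @ w + b) - yb
            sw = _sample_weights(yb, pos_weight)
            denom = sw.sum()
            w = w - eta * (Xb.T @ (sw * resid)) / denom
            b = b - eta * float((sw * resid).sum() / denom)
    return LinearModelParams(w, b)


def aggregate(
    params_list: list[LinearModelParams], n_k_list: list[int]
) -> LinearModelParams:
    """Sample-size-weighted average: sum_k (n_k / n) params_k, n = sum n_k."""
    if not params_list:
        raise ValueError("nothing to aggregate")
    if len(params_list) != len(n_k_list):
        raise ValueError("params and sizes differ in length")
    n_k = np.asarray(n_k_list, dtype=float)
    if (n_k < 1).any():
        raise ValueError("every client size must be >= 1")
    weights = n_k / n_k.sum()
    w = sum(wt * p.w for wt, p in zip(weights, params_list))
    b = float(sum(wt * p.b for wt, p in zip(weights, params_list)))
    return LinearModelParams(w, b)


def run_fedavg(
    client_data: list[tuple[np.ndarray, np.ndarray]],
    config: FedConfig,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[LinearModelParams, TrainingTrace]:
    """The FedAvg server loop with full client participation.

    Round t: broadcast the global parameters to every client, run
    ``local_update`` on each client's shard (epoch seeds derived from
    (config.seed, t, k)), and aggregate the returned parameters weighted by
    client sample counts.  Stops after ``config.rounds`` rounds or when the
    max-norm parameter change falls below ``config.convergence_tol``.
    """
    if not client_data:
        raise ValueError("need at least one client")
    for k, (Xk, yk) in enumerate(client_data):
        if np.asarray(Xk).shape[0] == 0:
            raise ValueError(f"client {k} has no data")
    p = np.asarray(client_data[0][0]).shape[1]
    sizes = [int(np.asarray(Xk).shape[0]) for Xk, _ in client_data]

    params = init_params(p, config.seed)
    trace = TrainingTrace(params_history=[params.copy()])

    def _val_auc(pr: LinearModelParams) -> float:
        from .metrics import roc_auc

        Xv, yv = validation
        return roc_auc(predict_proba(pr, Xv), yv)

    if validation is not None:
        trace.validation_auc.append(_val_auc(params))

    for t in range(config.rounds):
        locals_ = [
            local_update(
                params,
                Xk,
                yk,
                config.B,
                config.E,
                config.eta,
                seed=(config.seed, t, k),
                pos_weight=config.pos_weight,
            )
            for k, (Xk, yk) in enumerate(client_data)
        ]
        new = aggregate(locals_, sizes)
        delta = max(
            float(np.abs(new.w - params.w).max(initial=0.0)),
            abs(new.b - params.b),
        )
        params = new
        trace.params_history.append(params.copy())
        trace.param_deltas.append(delta)
        if validation is not None:
            trace.validation_auc.append(_val_auc(params))
        if config.convergence_tol is not None and delta < config.convergence_tol:
            break
    return params, trace


def train_centralized(
    X: np.ndarray,
    y: np.ndarray,
    config: FedConfig,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[LinearModelParams, TrainingTrace]:
    """The 'NonFed' baseline: the same optimizer on the pooled training set
    (identically FedAvg with a single client holding everything)."""
    return run_fedavg([(X, y)], config, validation=validation)


def train_local_only(
    X: np.ndarray, y: np.ndarray, config: FedConfig
) -> LinearModelParams:
    """A model trained on one client's shard alone (no communication)."""
    params, _ = run_fedavg([(X, y)], config)
    return params
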