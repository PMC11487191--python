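"""Multitask bioactivity classifier: an ensemble of small MLPs.

One model maps a morphological profile to per-assay activity
probabilities for all tasks at once, trained with a *masked* binary
cross-entropy so that unobserved (compound, task) cells contribute
nothing to the loss or its gradient — essential when the label matrix
is ~5% filled. Training minimises the masked BCE with Adam; the
ensemble members differ only in their seed-derived initialisation and
minibatch order, and predictions are the arithmetic mean of member
probabilities.

The networks are implemented directly in numpy (dense layers, ReLU,
inverted dropout, per-task sigmoid heads, hand-written gradients):
this keeps the masked multitask loss explicit, the training
deterministic on one CPU, and the models small enough to train in
seconds at the problem sizes used here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one ensemble training run.

    ``n_iterations`` counts minibatch gradient steps; 2000 is a desk
    default that converges on the synthetic screens here (production
    configuration used 34000). All sizes are configurable.
    """

    n_members: int = 8
    hidden_sizes: tuple[int, ...] = (256, 128)
    dropout: float = 0.25
    learning_rate: float = 1e-3
    n_iterations: int = 2000
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")


def _as_label_arrays(labels) -> tuple[np.ndarray, np.ndarray]:
    """Accept a BinaryLabels, a DataFrame or an ndarray (NaN = masked)."""
    wide = getattr(labels, "wide", labels)
    y = np.asarray(wide, dtype=float)
    mask = ~np.isnan(y)
    return np.where(mask, y, 0.0), mask


def masked_bce(outputs, labels) -> float:
    """Mean binary cross-entropy over unmasked label cells only.

    ``outputs`` are probabilities in (0, 1); ``labels`` may be a
    BinaryLabels, a DataFrame or an array with NaN marking missing
    cells. Masked cells contribute nothing. With no unmasked cell the
    loss is defined as 0 (with a warning).
    """
    y, mask = _as_label_arrays(labels)
    p = np.asarray(outputs, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: outputs {p.shape} vs labels {y.shape}")
    n = int(mask.sum())
    if n == 0:
        warnings.warn("masked_bce over zero unmasked cells; returning 0", stacklevel=2)
        return 0.0
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    ll = y * np.log(p) + (1.0 - y) * np.log(1.0 - p)
    return float(-np.sum(ll[mask]) / n)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _MLP:
    """One feed-forward member: ReLU hidden layers, sigmoid task heads."""

    def __init__(self, n_features: int, n_tasks: int,
                 hidden_sizes: tuple[int, ...], dropout: float,
                 rng: np.random.Generator):
        sizes = [n_features, *hidden_sizes, n_tasks]
        self.dropout = dropout
        self.weights = []
        self.biases = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / fan_in)  # He init for ReLU layers
            self.weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    def forward(self, x: np.ndarray, rng: np.random.Generator | None = None):
        """Return (probabilities, cache). Dropout active iff rng given."""
        a = x
        cache = [a]
        drop_masks = []
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ w + b
            if i < last:
                a = np.maximum(z, 0.0)
                if rng is not None and self.dropout > 0.0:
                    m = (rng.random(a.shape) >= self.dropout) / (1.0 - self.dropout)
                    a = a * m
                    drop_masks.append(m)
                else:
                    drop_masks.append(None)
                cache.append(a)
            else:
                p = _sigmoid(z)
        return p, (cache, drop_masks)

    def backward(self, p, y, mask, cache_pack):
        """Gradients of masked BCE w.r.t. all parameters.

        d(loss)/d(logit) = (p - y) * mask / n_unmasked: masked cells
        have exactly zero gradient.
        """
        cache, drop_masks = cache_pack
        n = max(int(mask.sum()), 1)
        delta = (p - y) * mask / n
        grads_w, grads_b = [], []
        for i in range(len(self.weights) - 1, -1, -1):
            a_prev = cache[i]
            grads_w.append(a_prev.T @ delta)
            grads_b.append(delta.sum(axis=0))
            if i > 0:
                delta = delta @ self.weights[i].T
                if drop_masks[i - 1] is not None:
                    delta = delta * drop_masks[i - 1]
                delta = delta * (cache[i] > 0.0)
        return grads_w[::-1], grads_b[::-1]

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        p, _ = self.forward(x, rng=None)
        return p


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class EnsembleModel:
    """A trained ensemble: members plus the task list and feature size."""

    members: list
    n_features: int
    tasks: list
    config: TrainConfig

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Mean member probability per (row, task); values in (0, 1)."""
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.n_features:
            raise ValueError(
                f"expected features of width {self.n_features}, got {x.shape}"
            )
        p = np.mean([m.predict_proba(x) for m in self.members], axis=0)
        # keep outputs in the open interval even when a sigmoid underflows
        return np.clip(p, 1e-12, 1.0 - 1e-12)

    def predict_proba_frame(self, x: np.ndarray, index) -> pd.DataFrame:
        return pd.DataFrame(self.predict_proba(x), index=index, columns=self.tasks)

    # --- persistence ------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "n_features": self.n_features,
            "tasks": list(map(str, self.tasks)),
            "config": {**asdict(self.config),
                       "hidden_sizes": list(self.config.hidden_sizes)},
            "n_members": len(self.members),
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
        arrays = {}
        for i, m in enumerate(self.members):
            for j, (w, b) in enumerate(zip(m.weights, m.biases)):
                arrays[f"m{i}_w{j}"] = w
                arrays[f"m{i}_b{j}"] = b
        np.savez(directory / "weights.npz", **arrays)

    @classmethod
    def load(cls, directory: str | Path) -> "EnsembleModel":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        cfg_d = dict(manifest["config"])
        cfg_d["hidden_sizes"] = tuple(cfg_d["hidden_sizes"])
        config = TrainConfig(**cfg_d)
        data = np.load(directory / "weights.npz")
        members = []
        for i in range(manifest["n_members"]):
            m = _MLP.__new__(_MLP)
            m.dropout = config.dropout
            m.weights, m.biases = [], []
            j = 0
            while f"m{i}_w{j}" in data:
                m.weights.append(data[f"m{i}_w{j}"])
                m.biases.append(data[f"m{i}_b{j}"])
                j += 1
            members.append(m)
        return cls(members=members, n_features=manifest["n_features"],
                   tasks=manifest["tasks"], config=config)


def _train_member(x, y, mask, config: TrainConfig, seed_seq) -> _MLP:
    rng = np.random.default_rng(seed_seq)
    n_rows = x.shape[0]
    net = _MLP(x.shape[1], y.shape[1], tuple(config.hidden_sizes),
               config.dropout, rng)
    params = net.weights + net.biases
    opt = _Adam(params, config.learning_rate)
    for _ in range(config.n_iterations):
        idx = rng.integers(0, n_rows, size=min(config.batch_size, n_rows))
        mb = mask[idx]
        if not mb.any():
            continue
        p, cache = net.forward(x[idx], rng=rng)
        gw, gb = net.backward(p, y[idx], mb, cache)
        opt.step(params, gw + gb)
    return net


def train_ensemble(features, labels, config: TrainConfig = TrainConfig()) -> EnsembleModel:
    """Train the ensemble on the full (masked) label matrix.

    ``features``: (n_compounds, n_features) array, row-aligned with
    ``labels`` (a BinaryLabels, DataFrame or NaN-masked array). Members
    get independent seed streams spawned from ``config.seed``; the
    result is deterministic given (features, labels, config).
    """
    x = np.asarray(features, dtype=float)
    y, mask = _as_label_arrays(labels)
    if x.shape[0] != y.shape[0]:
        raise ValueError(
            f"feature rows ({x.shape[0]}) != label rows ({y.shape[0]})"
        )
    if not mask.any():
        raise ValueError("no unmasked labels to train on")
    tasks = list(getattr(getattr(labels, "wide", labels), "columns",
                         range(y.shape[1])))
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_members)
    members = [_train_member(x, y, mask, config, s) for s in seeds]
    return EnsembleModel(members=members, n_features=x.shape[1],
                         tasks=tasks, config=config)


def predict_proba(model: EnsembleModel, features) -> np.ndarray:
    """Ensemble probability table: mean of member outputs, in (0, 1)."""
    return model.predict_proba(features)
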