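"""Per-read modification classifier (Model 1).

A compact residual 1-D CNN takes the paired length-100 observed-signal
and distance vectors of one read window (two input channels) and outputs
the probability that the centre base of that window is modified in that
molecule.  Training minimises binary cross-entropy (reported in bits)
with the AMSGrad optimizer; validation metrics are recorded every
``eval_every`` training examples and the parameters with the best
validation loss are kept.

Read-level calls use a double cutoff: probability above ``hi`` is called
modified, below ``lo`` unmodified, and the closed band [lo, hi] is
discarded as unreliable.  The defaults 0.7/0.3 trade accuracy against the
fraction of retained reads.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Dict, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .nn import AMSGrad, ConvNet

MODIFIED = "modified"
UNMODIFIED = "unmodified"
DISCARDED = "discarded"

DEFAULT_HI = 0.7
DEFAULT_LO = 0.3

_EPS = 1e-7
_LN2 = np.log(2.0)


def _npz_path(path) -> str:
    p = str(path)
    return p if p.endswith(".npz") else p + ".npz"


@dataclass
class Model1Config:
    channels: Tuple[int, ...] = (16, 16)
    kernel: int = 5
    lr: float = 1e-4
    batch_size: int = 64
    epochs: int = 10
    eval_every: int = 200_000  # examples between validation evaluations
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if min(self.channels) < 1 or self.kernel < 1 or self.batch_size < 1:
            raise ValueError("sizes must be positive")


def bce_loss(p: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy in bits, probabilities clamped at 1e-7."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.shape != y.shape:
        raise ValueError("probability and label arrays differ in length")
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log2(p) + (1 - y) * np.log2(1 - p)))


def rank_auc(p: np.ndarray, y: np.ndarray) -> float:
    """ROC AUC via the rank statistic (midranks for ties)."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined for single-class labels")
    ranks = rankdata(p)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def evaluate_reads(p: np.ndarray, y: np.ndarray) -> Dict[str, float]:
    """Accuracy, precision, recall (threshold 0.5) and rank AUC."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y).astype(int)
    pred = (p > 0.5).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    return {
        "accuracy": (tp + tn) / len(y),
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
        "recall": tp / (tp + fn) if tp + fn else float("nan"),
        "auc": rank_auc(p, y),
    }


def double_cutoff(
    p: Union[float, np.ndarray], hi: float = DEFAULT_HI, lo: float = DEFAULT_LO
):
    """Read-level call: > hi modified, < lo unmodified, [lo, hi] discarded."""
    if lo > hi:
        raise ValueError(f"double cutoff misconfigured: lo={lo} > hi={hi}")
    scalar = np.isscalar(p)
    p = np.atleast_1d(np.asarray(p, dtype=float))
    out = np.full(p.shape, DISCARDED, dtype=object)
    out[p > hi] = MODIFIED
    out[p < lo] = UNMODIFIED
    return out[0] if scalar else out


class Model1:
    """Trained per-read classifier with its mode tag and config."""

    def __init__(self, net: ConvNet, mode: str, config: Model1Config):
        self.net = net
        self.mode = mode
        self.config = config

    def predict(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=float)
        if features.ndim != 3 or features.shape[1] != 2 or features.shape[2] != 100:
            raise ValueError(
                f"expected features of shape (n, 2, 100), got {features.shape}"
            )
        return self.net.predict_proba(features)

    def save(self, path: str) -> None:
        np.savez(_npz_path(path), **self.net.state_dict())
        sidecar = {"mode": self.mode, "config": asdict(self.config),
                   "model": "read-level"}
        with open(_npz_path(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "Model1":
        with open(_npz_path(path) + ".json") as fh:
            sidecar = json.load(fh)
        cfg = Model1Config(**{**sidecar["config"],
                              "channels": tuple(sidecar["config"]["channels"])})
        net = ConvNet(c_in=2, channels=cfg.channels, kernel=cfg.kernel,
                      seed=cfg.seed)
        with np.load(_npz_path(path)) as data:
            net.load_state_dict({k: data[k] for k in data.files})
        return cls(net, sidecar["mode"], cfg)


def train_network(
    net: ConvNet,
    train_x: np.ndarray,
    train_y: np.ndarray,
    valid_x: np.ndarray,
    valid_y: np.ndarray,
    lr: float,
    batch_size: int,
    epochs: int,
    eval_every: int,
    seed: int,
) -> pd.DataFrame:
    """Generic minibatch training loop shared by the read and site models.

    Returns the metric trace and leaves ``net`` holding the parameters with
    the best validation loss.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    opt = AMSGrad(net.params(), lr=lr)
    n = len(train_x)
    trace = []
    best_loss, best_state = np.inf, None
    seen_since_eval, seen_total = 0, 0
    running_loss, running_count = 0.0, 0

    def _evaluate():
        nonlocal best_loss, best_state
        pv = net.predict_proba(valid_x)
        vloss = bce_loss(pv, valid_y)
        try:
            metrics = evaluate_reads(pv, valid_y)
        except ValueError:  # single-class validation set: AUC undefined
            pred = (pv > 0.5).astype(int)
            metrics = {"accuracy": float(np.mean(pred == valid_y)),
                       "precision": float("nan"), "recall": float("nan"),
                       "auc": float("nan")}
        trace.append(
            {
                "examples_seen": seen_total,
                "train_loss": running_loss / max(running_count, 1),
                "valid_loss": vloss,
                **{f"valid_{k}": v for k, v in metrics.items()},
            }
        )
        if vloss < best_loss:
            best_loss = vloss
            best_state = net.state_dict()

    for _ in range(epochs):
        order = rng.permutation(n)
        for i in range(0, n, batch_size):
            idx = order[i : i + batch_size]
            xb = train_x[idx]
            yb = train_y[idx].astype(np.float64)
            z = net.forward_logits(xb, train=True)
            p = 1.0 / (1.0 + np.exp(-z.astype(np.float64)))
            loss = bce_loss(p, yb)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss after {seen_total} examples"
                )
            # d(mean bits)/dz = (p - y) / (N ln 2)
            dz = (p - yb) / (len(yb) * _LN2)
            net.backward(dz)
            opt.step(net.params(), net.grads())
            running_loss += loss * len(yb)
            running_count += len(yb)
            seen_total += len(yb)
            seen_since_eval += len(yb)
            if seen_since_eval >= eval_every:
                _evaluate()
                seen_since_eval = 0
                running_loss, running_count = 0.0, 0
    _evaluate()
    if best_state is not None:
        net.load_state_dict(best_state)
    return pd.DataFrame(trace)


def train_model1(
    train_x: np.ndarray,
    train_y: np.ndarray,
    valid_x: np.ndarray,
    valid_y: np.ndarray,
    config: Model1Config = Model1Config(),
    mode: str = "m6A",
) -> Tuple[Model1, pd.DataFrame]:
    """Train the per-read classifier on (n, 2, 100) feature arrays."""
    net = ConvNet(c_in=2, channels=config.channels, kernel=config.kernel,
                  seed=config.seed)
    trace = train_network(
        net, np.asarray(train_x), np.asarray(train_y),
        np.asarray(valid_x), np.asarray(valid_y),
        lr=config.lr, batch_size=config.batch_size, epochs=config.epochs,
        eval_every=config.eval_every, seed=config.seed,
    )
    return Model1(net, mode, config), trace
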