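"""Site-level classifier (Model 2) and stoichiometry estimation.

At a transcript site the per-read classifier yields one probability per
covering read.  Model 2 classifies the *distribution* of those
probabilities as coming from a modified site (some or all reads with high
probability) or an unmodified one.  The distribution is encoded as a
length-100 sorted-quantile vector — invariant to read order and to
duplication of the whole read set — and fed to the same compact residual
CNN family as the read model, with a single input channel.

Training sites are controlled mixtures drawn from pools of per-read
probabilities of known state: a site is modified with probability 0.5;
coverage (1–100) and, for modified sites, stoichiometry are drawn with
linearly decaying weights ``(10 − c) × 0.01 + 0.9`` (clamped at zero), so
that low-coverage, low-stoichiometry sites dominate, as they do in real
transcriptomes.

Stoichiometry is *not* regressed by the network: it is the fraction of
covering reads called modified under the read-level double cutoff, with
discarded reads excluded from the denominator.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model1 import (DEFAULT_HI, DEFAULT_LO, Model1Config, _npz_path,
                     double_cutoff, train_network)
from .nn import ConvNet

SITE_FEATURE_LEN = 100

#: linear-decay weight for coverage/stoichiometry value v in 1..100
def _decay_weight(v: np.ndarray) -> np.ndarray:
    return np.clip((10.0 - v) * 0.01 + 0.9, 0.0, None)


@dataclass
class SiteRecord:
    contig: str
    center_pos: int
    read_probs: np.ndarray
    label: Optional[int] = None  # known state for training mixtures

    def __post_init__(self):
        self.read_probs = np.asarray(self.read_probs, dtype=float)
        if self.read_probs.size < 1:
            raise ValueError("site record needs at least one read")
        if ((self.read_probs < 0) | (self.read_probs > 1)).any():
            raise ValueError("read probabilities outside [0, 1]")

    @property
    def coverage(self) -> int:
        return int(self.read_probs.size)


@dataclass
class SiteCall:
    contig: str
    center_pos: int
    coverage: int
    site_probability: float
    stoichiometry: float  # NaN when every read was discarded
    n_mod: int
    n_unmod: int
    n_discarded: int


def build_mixtures(
    pool_mod_probs: Sequence[float],
    pool_unmod_probs: Sequence[float],
    n_sites: int,
    seed: int,
) -> List[SiteRecord]:
    """Labelled training mixtures from modified/unmodified probability pools.

    The pools must come from reads never used to train the read-level
    model.  Per site: modified with probability 0.5; coverage in 1..100
    and (if modified) stoichiometry in 1..100% drawn under the linear
    decay; read probabilities sampled with replacement from the pools.
    """
    pool_mod = np.asarray(pool_mod_probs, dtype=float)
    pool_unmod = np.asarray(pool_unmod_probs, dtype=float)
    if pool_mod.size == 0 or pool_unmod.size == 0:
        raise ValueError("empty probability pool")
    rng = np.random.default_rng(seed)
    grid = np.arange(1, 101)
    w = _decay_weight(grid)
    w = w / w.sum()
    records = []
    for i in range(n_sites):
        modified = int(rng.random() < 0.5)
        coverage = int(rng.choice(grid, p=w))
        if modified:
            stoich = int(rng.choice(grid, p=w)) / 100.0
            n_mod = round(stoich * coverage)
            probs = np.concatenate([
                rng.choice(pool_mod, size=n_mod, replace=True),
                rng.choice(pool_unmod, size=coverage - n_mod, replace=True),
            ])
            rng.shuffle(probs)
        else:
            probs = rng.choice(pool_unmod, size=coverage, replace=True)
        records.append(
            SiteRecord(contig="mix", center_pos=i, read_probs=probs,
                       label=modified)
        )
    return records


def site_feature(read_probs: Sequence[float],
                 length: int = SITE_FEATURE_LEN) -> np.ndarray:
    """Sorted-quantile encoding of a probability multiset.

    Entry i is the empirical quantile (inverted CDF) at level (i+0.5)/L,
    which is invariant to read order and to duplicating the whole multiset.
    """
    probs = np.asarray(read_probs, dtype=float)
    if probs.size < 1:
        raise ValueError("site feature needs at least one read probability")
    levels = (np.arange(length) + 0.5) / length
    return np.quantile(probs, levels, method="inverted_cdf")


def site_feature_matrix(records: Sequence[SiteRecord]) -> np.ndarray:
    out = np.empty((len(records), 1, SITE_FEATURE_LEN))
    for i, rec in enumerate(records):
        out[i, 0] = site_feature(rec.read_probs)
    return out


class Model2:
    """Trained site-level classifier."""

    def __init__(self, net: ConvNet, mode: str, config: Model1Config):
        self.net = net
        self.mode = mode
        self.config = config

    def predict_sites(self, records: Sequence[SiteRecord]) -> np.ndarray:
        if len(records) == 0:
            return np.empty(0)
        return self.net.predict_proba(site_feature_matrix(records))

    def save(self, path: str) -> None:
        np.savez(_npz_path(path), **self.net.state_dict())
        sidecar = {"mode": self.mode, "config": asdict(self.config),
                   "model": "site-level"}
        with open(_npz_path(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "Model2":
        with open(_npz_path(path) + ".json") as fh:
            sidecar = json.load(fh)
        cfg = Model1Config(**{**sidecar["config"],
                              "channels": tuple(sidecar["config"]["channels"])})
        net = ConvNet(c_in=1, channels=cfg.channels, kernel=cfg.kernel,
                      seed=cfg.seed)
        with np.load(_npz_path(path)) as data:
            net.load_state_dict({k: data[k] for k in data.files})
        return cls(net, sidecar["mode"], cfg)


def train_model2(
    records: Sequence[SiteRecord],
    config: Model1Config = Model1Config(),
    mode: str = "m6A",
    test_fraction: float = 0.1,
) -> Tuple[Model2, pd.DataFrame, Dict[str, float]]:
    """Train on labelled mixtures with a 9:1 train/test split.

    Returns the model, the training trace, and held-out test metrics.
    """
    labels = np.array([r.label for r in records])
    if any(l is None for l in labels):
        raise ValueError("all training site records need labels")
    x = site_feature_matrix(records)
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(records))
    n_test = max(1, int(round(test_fraction * len(records))))
    test_idx, train_idx = order[:n_test], order[n_test:]
    net = ConvNet(c_in=1, channels=config.channels, kernel=config.kernel,
                  seed=config.seed)
    trace = train_network(
        net, x[train_idx], labels[train_idx], x[test_idx], labels[test_idx],
        lr=config.lr, batch_size=config.batch_size, epochs=config.epochs,
        eval_every=config.eval_every, seed=config.seed,
    )
    model = Model2(net, mode, config)
    from .model1 import bce_loss, evaluate_reads

    p_test = net.predict_proba(x[test_idx])
    metrics = evaluate_reads(p_test, labels[test_idx])
    metrics["bce"] = bce_loss(p_test, labels[test_idx])
    return model, trace, metrics


def estimate_stoichiometry(
    read_probs: Sequence[float],
    hi: float = DEFAULT_HI,
    lo: float = DEFAULT_LO,
) -> Tuple[float, int, int, int]:
    """Double-cutoff stoichiometry: n_mod / (n_mod + n_unmod).

    Returns (stoichiometry, n_mod, n_unmod, n_discarded); the estimate is
    NaN when every read falls in the discard band.
    """
    labels = double_cutoff(np.asarray(read_probs, dtype=float), hi=hi, lo=lo)
    n_mod = int(np.sum(labels == "modified"))
    n_unmod = int(np.sum(labels == "unmodified"))
    n_disc = int(np.sum(labels == "discarded"))
    denom = n_mod + n_unmod
    stoich = n_mod / denom if denom else float("nan")
    return stoich, n_mod, n_unmod, n_disc


def call_site(
    record: SiteRecord,
    site_probability: float,
    hi: float = DEFAULT_HI,
    lo: float = DEFAULT_LO,
) -> SiteCall:
    stoich, n_mod, n_unmod, n_disc = estimate_stoichiometry(
        record.read_probs, hi=hi, lo=lo
    )
    return SiteCall(
        contig=record.contig,
        center_pos=record.center_pos,
        coverage=record.coverage,
        site_probability=float(site_probability),
        stoichiometry=stoich,
        n_mod=n_mod,
        n_unmod=n_unmod,
        n_discarded=n_disc,
    )
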