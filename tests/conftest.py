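"""Shared fixtures: a simulated pore model, labelled signal samples and
session-scoped trained read/site classifiers (small networks, short
schedules) reused across the suite."""

import numpy as np
import pandas as pd
import pytest

from poremeth.featurizer import extract_windows, feature_matrix
from poremeth.model1 import Model1Config, train_model1
from poremeth.model2 import build_mixtures, train_model2
from poremeth.signal_io import assemble_read_tracks
from poremeth.simulator import SimConfig, simulate_pore_model, simulate_sample

#: desk-scale training configuration used throughout the suite
SMALL_M1 = dict(channels=(12, 12), epochs=4, lr=1e-3, batch_size=64,
                eval_every=2000, seed=0)
SMALL_M2 = dict(channels=(12, 12), epochs=8, lr=1e-3, batch_size=64,
                eval_every=5000, seed=0)


@pytest.fixture(scope="session")
def pore_model():
    return simulate_pore_model(7)


def make_labelled_sample(pore_model, seed, n_transcripts, stoich_fn,
                         reads=60, mode="m6A", **cfg_kwargs):
    """Simulate transcripts with one designated centre site each and return
    (features, labels, sample) for those sites."""
    sites = {(f"tx{t:04d}", 10): stoich_fn(t) for t in range(n_transcripts)}
    cfg = SimConfig(seed=seed, mode=mode, n_transcripts=n_transcripts,
                    transcript_length=21, n_reads_per_transcript=reads,
                    site_stoichiometries=sites, **cfg_kwargs)
    sample = simulate_sample(cfg, pore_model)
    windows = []
    for track in assemble_read_tracks(iter(sample.events)):
        for w in extract_windows(track, mode):
            if (w.contig, w.center_pos) in sites:
                windows.append(w)
    feats, keys = feature_matrix(windows, pore_model)
    wdf = pd.DataFrame(keys, columns=["read_id", "contig", "center_pos"])
    labels = wdf.merge(
        sample.truth, on=["read_id", "contig", "center_pos"]
    )["modified"].to_numpy()
    return feats, labels, sample


@pytest.fixture(scope="session")
def trained_model1(pore_model):
    """Read-level classifier trained on a separable simulated sample, plus
    its held-out validation data and training trace."""
    feats, labels, _ = make_labelled_sample(
        pore_model, seed=1, n_transcripts=40,
        stoich_fn=lambda t: 1.0 if t < 20 else 0.0,
    )
    rng = np.random.default_rng(0)
    order = rng.permutation(len(feats))
    val, train = order[:500], order[500:]
    model, trace = train_model1(
        feats[train], labels[train], feats[val], labels[val],
        Model1Config(**SMALL_M1),
    )
    return {
        "model": model,
        "trace": trace,
        "valid_x": feats[val],
        "valid_y": labels[val],
    }


@pytest.fixture(scope="session")
def prob_pools(trained_model1, pore_model):
    """Per-read probabilities from an independent sample of known state."""
    feats, labels, _ = make_labelled_sample(
        pore_model, seed=2, n_transcripts=20,
        stoich_fn=lambda t: 1.0 if t < 10 else 0.0, reads=80,
    )
    probs = trained_model1["model"].predict(feats)
    return probs[labels == 1], probs[labels == 0]


@pytest.fixture(scope="session")
def trained_model2(prob_pools):
    pool_mod, pool_unmod = prob_pools
    records = build_mixtures(pool_mod, pool_unmod, n_sites=3000, seed=3)
    model, trace, metrics = train_model2(records, Model1Config(**SMALL_M2))
    return {"model": model, "trace": trace, "metrics": metrics}
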