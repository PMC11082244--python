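"""Single-sample transcriptome-wide calling (read + site models combined).

Orchestrates the full path from an eventalign table to site calls: track
assembly, window featurization, per-read prediction, grouping into site
records, a coverage filter (>20 reads by default), site classification,
and the significance cutoff (site probability > 0.9999 by default).

The significance cutoff is calibrated with a read-shuffling permutation:
all per-read probabilities are shuffled across sites while keeping the
number of sites and each site's coverage fixed, the site model is re-run,
and the fraction of shuffled sites passing a cutoff estimates the false
discovery rate at that cutoff.  A companion permutation test measures
whether an externally defined candidate list is enriched in
high-probability sites among all tested sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .featurizer import extract_windows, feature_matrix
from .model1 import Model1
from .model2 import Model2, SiteRecord, call_site
from .signal_io import PoreModel, SignalEvent, assemble_read_tracks, read_eventalign

DEFAULT_MIN_COVERAGE = 21  # ">20 reads"
DEFAULT_SITE_CUTOFF = 0.9999


@dataclass
class SoloConfig:
    mode: str = "m6A"
    min_coverage: int = DEFAULT_MIN_COVERAGE
    site_prob_cutoff: float = DEFAULT_SITE_CUTOFF
    hi: float = 0.7
    lo: float = 0.3
    fdr_permutations: int = 10
    seed: int = 0
    #: optional restriction of candidate centres, e.g. designated sites
    positions: Optional[Set[Tuple[str, int]]] = None

    def __post_init__(self):
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if not 0.0 < self.site_prob_cutoff < 1.0:
            raise ValueError("site_prob_cutoff must lie in (0, 1)")


@dataclass
class SoloResult:
    read_predictions: pd.DataFrame  # read_id, contig, center_pos, probability
    tested_sites: pd.DataFrame      # per-site calls with `significant` flag
    site_records: List[SiteRecord] = field(default_factory=list)

    @property
    def significant_sites(self) -> pd.DataFrame:
        return self.tested_sites[self.tested_sites["significant"]]


def predict_read_probabilities(
    events: Iterable[SignalEvent],
    pore_model: PoreModel,
    model1: Model1,
    mode: str,
    positions: Optional[Set[Tuple[str, int]]] = None,
) -> pd.DataFrame:
    """Per-read probabilities for every fully covered candidate window."""
    windows = []
    for track in assemble_read_tracks(events):
        for w in extract_windows(track, mode):
            if positions is None or (w.contig, w.center_pos) in positions:
                windows.append(w)
    if not windows:
        return pd.DataFrame(
            columns=["read_id", "contig", "center_pos", "probability"]
        )
    feats, keys = feature_matrix(windows, pore_model)
    probs = model1.predict(feats)
    df = pd.DataFrame(keys, columns=["read_id", "contig", "center_pos"])
    df["probability"] = probs
    return df


def group_site_records(
    read_predictions: pd.DataFrame, min_coverage: int
) -> List[SiteRecord]:
    records = []
    for (contig, pos), grp in read_predictions.groupby(
        ["contig", "center_pos"], sort=True
    ):
        if len(grp) >= min_coverage:
            records.append(
                SiteRecord(contig=contig, center_pos=int(pos),
                           read_probs=grp["probability"].to_numpy())
            )
    return records


def run_solo(
    events,
    pore_model: PoreModel,
    model1: Model1,
    model2: Model2,
    config: SoloConfig = SoloConfig(),
) -> SoloResult:
    """Full single-sample run.

    ``events`` may be an eventalign path, a list of paths (replicates are
    pooled by concatenation), or an in-memory event iterable.
    """
    if model1.mode != config.mode or model2.mode != config.mode:
        raise ValueError(
            f"mode mismatch: config={config.mode}, "
            f"model1={model1.mode}, model2={model2.mode}"
        )
    events = _as_event_stream(events)
    reads = predict_read_probabilities(
        events, pore_model, model1, config.mode, config.positions
    )
    records = group_site_records(reads, config.min_coverage)
    probs = model2.predict_sites(records)
    calls = [
        call_site(rec, p, hi=config.hi, lo=config.lo)
        for rec, p in zip(records, probs)
    ]
    tested = pd.DataFrame([vars(c) for c in calls]) if calls else pd.DataFrame(
        columns=["contig", "center_pos", "coverage", "site_probability",
                 "stoichiometry", "n_mod", "n_unmod", "n_discarded"]
    )
    tested["significant"] = tested.get(
        "site_probability", pd.Series(dtype=float)
    ) > config.site_prob_cutoff
    return SoloResult(read_predictions=reads, tested_sites=tested,
                      site_records=records)


def _as_event_stream(events):
    if isinstance(events, (str,)) or hasattr(events, "__fspath__"):
        return read_eventalign(events)
    if isinstance(events, (list, tuple)) and events and (
        isinstance(events[0], str) or hasattr(events[0], "__fspath__")
    ):
        def _chain():
            for path in events:
                yield from read_eventalign(path)
        return _chain()
    return events


def shuffle_site_records(
    records: Sequence[SiteRecord], rng: np.random.Generator
) -> List[SiteRecord]:
    """One read-shuffling round: same sites, same coverages, pooled reads."""
    pooled = np.concatenate([r.read_probs for r in records])
    bounds = np.cumsum([r.coverage for r in records])[:-1]
    chunks = np.split(rng.permutation(pooled), bounds)
    return [
        SiteRecord(contig=r.contig, center_pos=r.center_pos, read_probs=c)
        for r, c in zip(records, chunks)
    ]


def permutation_fdr(
    records: Sequence[SiteRecord],
    model2: Model2,
    cutoffs: Sequence[float],
    n_rounds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """FDR estimate per cutoff from read-shuffled site configurations.

    Shuffling permutes the pooled per-read probabilities across sites,
    preserving the site count and each site's coverage; the unit shuffled
    is the read-level probability, which fully determines the site model's
    input.  Returns the mean fraction (and mean count) of shuffled sites
    exceeding each cutoff over ``n_rounds`` independent shuffles.
    """
    if n_rounds < 1:
        raise ValueError("need at least one permutation round")
    rng = np.random.default_rng(seed)
    frac = np.zeros((n_rounds, len(cutoffs)))
    counts = np.zeros((n_rounds, len(cutoffs)))
    for it in range(n_rounds):
        fake = shuffle_site_records(records, rng)
        probs = model2.predict_sites(fake)
        for j, cut in enumerate(cutoffs):
            counts[it, j] = np.sum(probs > cut)
            frac[it, j] = counts[it, j] / len(records)
    return pd.DataFrame(
        {
            "cutoff": list(cutoffs),
            "fdr_estimate": frac.mean(axis=0),
            "mean_significant_count": counts.mean(axis=0),
            "n_sites": len(records),
            "n_rounds": n_rounds,
        }
    )


def enrichment_permutation(
    candidate_sites: Iterable[Tuple[str, int]],
    tested_sites: pd.DataFrame,
    high_prob_cutoff: float = 0.99,
    n_rounds: int = 1000,
    seed: int = 0,
) -> Dict[str, float]:
    """Empirical p for enrichment of high-probability sites in a candidate list.

    Counts how many candidates are high-probability (> cutoff) among the
    tested sites, then repeatedly samples candidate-sized site sets at
    random from the tested table; p = (1 + #{rounds ≥ observed}) / (rounds + 1).
    """
    keys = list(dict.fromkeys(candidate_sites))
    if not keys:
        raise ValueError("empty candidate site list")
    indexed = tested_sites.set_index(["contig", "center_pos"])
    missing = [k for k in keys if k not in indexed.index]
    if missing:
        raise ValueError(f"candidates not among tested sites: {missing[:3]}")
    high = (tested_sites["site_probability"] > high_prob_cutoff).to_numpy()
    cand_high = indexed.loc[keys, "site_probability"].to_numpy() > high_prob_cutoff
    observed = int(cand_high.sum())
    rng = np.random.default_rng(seed)
    n = len(keys)
    hits = 0
    for _ in range(n_rounds):
        draw = rng.choice(len(tested_sites), size=n, replace=False)
        if int(high[draw].sum()) >= observed:
            hits += 1
    return {
        "observed_high": observed,
        "n_candidates": n,
        "p_value": (1 + hits) / (n_rounds + 1),
        "n_rounds": n_rounds,
    }
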