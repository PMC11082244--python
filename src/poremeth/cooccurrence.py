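"""Single-molecule co-occurrence of modification sites.

For two modified sites on one transcript, co-occurrence is the fraction
of reads covering both whose read-level states (modified / unmodified
under the double cutoff; discarded reads at either site are excluded)
agree at the two sites — both-modified and both-unmodified reads count as
co-occurring.  The null is built two ways: (a) independently permuting
each site's state vector across reads, which preserves the marginal
modified fractions while destroying molecular linkage, and (b) pairing
modified sites from different transcripts by random index alignment.

For independent sites with modified fractions p and q the expected
co-occurrence is pq + (1−p)(1−q); the permutation null converges to it.
A distance-stratified one-sided Mann–Whitney test compares observed and
permutation-expected co-occurrence per orientation and distance, and a
transcript-level two-tailed Fisher's exact test asks whether transcripts
carrying one modification type are more likely to carry the other (only
counting site pairs at least 5 nt apart).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .model1 import DEFAULT_HI, DEFAULT_LO, MODIFIED, double_cutoff

MIN_FISHER_DISTANCE = 5  # nt; closer A/C pairs are excluded from the 2x2 table


@dataclass
class SitePairStates:
    """Per-read 0/1 states of two sites, restricted to shared retained reads."""

    contig: str
    pos_upstream: int
    pos_downstream: int
    orientation: str  # e.g. "A-upstream" / "C-upstream"
    states_upstream: np.ndarray
    states_downstream: np.ndarray

    def __post_init__(self):
        self.states_upstream = np.asarray(self.states_upstream, dtype=np.int8)
        self.states_downstream = np.asarray(self.states_downstream, dtype=np.int8)
        if self.states_upstream.size != self.states_downstream.size:
            raise ValueError("state vectors differ in length")
        if self.states_upstream.size < 1:
            raise ValueError("a site pair needs at least one retained read")
        if self.distance < 1:
            raise ValueError("site pair distance must be >= 1 nt")

    @property
    def distance(self) -> int:
        return self.pos_downstream - self.pos_upstream

    @property
    def n_reads(self) -> int:
        return int(self.states_upstream.size)


def pair_states_from_reads(
    reads: pd.DataFrame,
    contig: str,
    pos_a: int,
    pos_b: int,
    orientation: str = "A-upstream",
    hi: float = DEFAULT_HI,
    lo: float = DEFAULT_LO,
) -> Optional[SitePairStates]:
    """Build a pair-state record from a per-read probability table.

    Reads must cover both sites; reads discarded by the double cutoff at
    either site are dropped entirely.  Returns None when no read remains.
    """
    sub = reads[reads["contig"] == contig]
    a = sub[sub["center_pos"] == pos_a].set_index("read_id")["probability"]
    b = sub[sub["center_pos"] == pos_b].set_index("read_id")["probability"]
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        return None
    la = double_cutoff(a.loc[shared].to_numpy(), hi=hi, lo=lo)
    lb = double_cutoff(b.loc[shared].to_numpy(), hi=hi, lo=lo)
    keep = (la != "discarded") & (lb != "discarded")
    if not keep.any():
        return None
    up, down = (pos_a, pos_b) if pos_a < pos_b else (pos_b, pos_a)
    sa = (la[keep] == MODIFIED).astype(np.int8)
    sb = (lb[keep] == MODIFIED).astype(np.int8)
    s_up, s_down = (sa, sb) if pos_a < pos_b else (sb, sa)
    return SitePairStates(
        contig=contig, pos_upstream=up, pos_downstream=down,
        orientation=orientation, states_upstream=s_up, states_downstream=s_down,
    )


def read_cooccurrence(pair: SitePairStates) -> float:
    """Fraction of retained reads with the same state at both sites."""
    return float(
        np.mean(pair.states_upstream == pair.states_downstream)
    )


def expected_cooccurrence(p: float, q: float) -> float:
    """Closed-form co-occurrence of two independent sites."""
    return p * q + (1 - p) * (1 - q)


def permutation_null(
    pair: SitePairStates, n_perm: int = 1000, seed: int = 0
) -> Dict[str, object]:
    """Null co-occurrence by permuting each site's states independently.

    Every round preserves each site's marginal modified count exactly.
    Returns the null distribution, its mean, and the one-sided
    (greater, +1-corrected) empirical p-value for the observed value.
    """
    if n_perm < 100:
        raise ValueError("use at least 100 permutation rounds")
    rng = np.random.default_rng(seed)
    observed = read_cooccurrence(pair)
    null = np.empty(n_perm)
    su, sd = pair.states_upstream, pair.states_downstream
    for i in range(n_perm):
        null[i] = np.mean(rng.permutation(su) == rng.permutation(sd))
    p = (1 + int(np.sum(null >= observed))) / (n_perm + 1)
    return {
        "observed": observed,
        "null": null,
        "null_mean": float(null.mean()),
        "p_value": p,
    }


def random_pair_null(
    site_states: Dict[Tuple[str, int], np.ndarray],
    n_pairs: int = 1000,
    seed: int = 0,
) -> Dict[str, object]:
    """Null from random pairs of modified sites on *different* transcripts.

    Sites on different transcripts share no molecules, so their state
    vectors are paired by random index alignment after truncation to the
    smaller coverage; this preserves each site's state composition while
    destroying any molecular linkage.  Returns the empirical distribution
    with mean and central 95% band.
    """
    keys = list(site_states)
    contigs = {c for c, _ in keys}
    if len(contigs) < 2:
        raise ValueError("need modified sites on at least 2 transcripts")
    rng = np.random.default_rng(seed)
    values = np.empty(n_pairs)
    i = 0
    while i < n_pairs:
        ka, kb = keys[rng.integers(len(keys))], keys[rng.integers(len(keys))]
        if ka[0] == kb[0]:
            continue
        sa, sb = site_states[ka], site_states[kb]
        n = min(sa.size, sb.size)
        pa = rng.permutation(sa)[:n]
        pb = rng.permutation(sb)[:n]
        values[i] = np.mean(pa == pb)
        i += 1
    lo, hi = np.quantile(values, [0.025, 0.975])
    return {"null": values, "mean": float(values.mean()),
            "band95": (float(lo), float(hi))}


def distance_stratified_test(
    pairs: Sequence[SitePairStates],
    distance_range: Iterable[int] = range(1, 16),
    n_perm: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Observed vs permutation-expected co-occurrence per (orientation, distance).

    Within each bucket the observed per-pair co-occurrences are compared
    with the pooled permutation-null values by a one-sided (greater)
    Mann–Whitney U-test.  Empty buckets are reported untested (NaN p).
    """
    from scipy.stats import mannwhitneyu

    rng = np.random.default_rng(seed)
    distance_range = list(distance_range)
    rows = []
    buckets: Dict[Tuple[str, int], List[SitePairStates]] = {}
    for pair in pairs:
        if pair.distance in distance_range:
            buckets.setdefault((pair.orientation, pair.distance), []).append(pair)
    orientations = sorted({p.orientation for p in pairs})
    for orientation in orientations:
        for dist in distance_range:
            bucket = buckets.get((orientation, dist), [])
            if not bucket:
                rows.append({"orientation": orientation, "distance": dist,
                             "n_pairs": 0, "observed_mean": np.nan,
                             "expected_mean": np.nan, "p_value": np.nan})
                continue
            obs = np.array([read_cooccurrence(p) for p in bucket])
            null_pool = np.concatenate([
                permutation_null(p, n_perm=max(100, n_perm),
                                 seed=int(rng.integers(2**31)))["null"]
                for p in bucket
            ])
            res = mannwhitneyu(obs, null_pool, alternative="greater",
                               method="asymptotic")
            rows.append({
                "orientation": orientation, "distance": dist,
                "n_pairs": len(bucket), "observed_mean": float(obs.mean()),
                "expected_mean": float(null_pool.mean()),
                "p_value": float(res.pvalue),
            })
    return pd.DataFrame(rows)


def transcript_fisher(
    site_table_a: pd.DataFrame,
    site_table_c: pd.DataFrame,
    tested_transcripts: Iterable[str],
) -> Dict[str, object]:
    """Transcript-level association of the two modification types.

    ``site_table_a``/``site_table_c`` are significant-site tables (columns
    contig, center_pos) for the two modification types.  Cross-type site
    pairs closer than 5 nt are mutually discarded before flagging, since
    adjacent modifications interfere with each other's signal; a
    transcript counts as doubly modified only if both types survive.
    Returns the 2×2 counts (both, A-only, C-only, neither) over
    ``tested_transcripts`` and the two-tailed Fisher exact p-value;
    degenerate margins give p = 1.
    """
    tested = list(dict.fromkeys(tested_transcripts))
    a_sites: Dict[str, List[int]] = {}
    for _, row in site_table_a.iterrows():
        a_sites.setdefault(row["contig"], []).append(int(row["center_pos"]))
    c_sites: Dict[str, List[int]] = {}
    for _, row in site_table_c.iterrows():
        c_sites.setdefault(row["contig"], []).append(int(row["center_pos"]))
    both = a_only = c_only = neither = 0
    for tx in tested:
        pa_all = a_sites.get(tx, [])
        pc_all = c_sites.get(tx, [])
        keep_a = [p for p in pa_all
                  if not any(abs(p - q) < MIN_FISHER_DISTANCE for q in pc_all)]
        keep_c = [q for q in pc_all
                  if not any(abs(p - q) < MIN_FISHER_DISTANCE for p in pa_all)]
        has_a, has_c = bool(keep_a), bool(keep_c)
        if has_a and has_c:
            both += 1
        elif has_a:
            a_only += 1
        elif has_c:
            c_only += 1
        else:
            neither += 1
    table = np.array([[both, a_only], [c_only, neither]])
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return {"table": table, "p_value": 1.0, "odds_ratio": float("nan"),
                "degenerate": True}
    odds, p = fisher_exact(table, alternative="two-sided")
    return {"table": table, "p_value": float(p), "odds_ratio": float(odds),
            "degenerate": False}
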