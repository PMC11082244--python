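"""Synthetic direct-RNA signal generator with known per-read truth.

Emulates, at desk scale, the kind of ground-truth material that in-vitro
transcribed (IVT) RNA provides for training and benchmarking: reads whose
modification state at designated sites is known exactly.  Per reference
5-mer the generator draws a variable dwell (shifted-Poisson number of raw
samples, minimum 2) and Gaussian current noise around the pore-model
level; a modified base adds a per-offset level shift to each of the five
5-mers that overlap it.  Per-read modification states are Bernoulli with
configurable per-site stoichiometry, optionally coupled between site
pairs through a Gaussian copula to reach a target correlation.

Events are serialized in the eventalign dialect with each 5-mer's samples
in 3′→5′ order, exactly as a signal aligner would emit them, so that the
reader's flip restores the 5′→3′ orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import multivariate_normal, norm

from .signal_io import KMER_SIZE, PoreModel, SignalEvent

Site = Tuple[str, int]  # (contig, 0-based centre position)

#: default level shift (pA) added to each of the five 5-mers overlapping a
#: modified base, indexed by the offset of that base within the 5-mer.
DEFAULT_MOD_SHIFT = (4.0, 4.0, 4.0, 4.0, 4.0)


@dataclass
class SimConfig:
    seed: int = 0
    mode: str = "m6A"
    n_transcripts: int = 4
    transcript_length: int = 41
    n_reads_per_transcript: int = 30
    dwell_mean: float = 8.0  # mean raw samples per 5-mer
    dwell_min: int = 2
    noise_sd: float = 2.0  # pA
    mod_shift: Tuple[float, ...] = DEFAULT_MOD_SHIFT
    #: designated candidate sites and their modified fraction
    site_stoichiometries: Dict[Site, float] = field(default_factory=dict)
    #: optional coupling: (site_a, site_b, rho) with both sites on one contig
    coupled_pairs: List[Tuple[Site, Site, float]] = field(default_factory=list)

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.dwell_min < 1:
            raise ValueError("dwell_min must be >= 1")
        if len(self.mod_shift) != KMER_SIZE:
            raise ValueError("mod_shift must have one entry per 5-mer offset")
        for frac in self.site_stoichiometries.values():
            if not 0.0 <= frac <= 1.0:
                raise ValueError("stoichiometry outside [0, 1]")


@dataclass
class SimSample:
    transcripts: Dict[str, str]
    events: List[SignalEvent]
    truth: pd.DataFrame  # read_id, contig, center_pos, modified


def simulate_pore_model(seed: int) -> PoreModel:
    """All 1024 5-mers with distinct levels drawn uniformly in 80–130 pA."""
    rng = np.random.default_rng(seed)
    kmers = ["".join(k) for k in _all_kmers()]
    levels = rng.uniform(80.0, 130.0, size=len(kmers))
    return PoreModel(dict(zip(kmers, levels)))


def _all_kmers():
    from itertools import product

    return product("ACGT", repeat=KMER_SIZE)


def bernoulli_copula_corr(p: float, q: float, rho: float) -> float:
    """Latent Gaussian correlation producing Bernoulli correlation ``rho``.

    Solved by bisection on the bivariate-normal orthant probability.  A
    target outside the Fréchet bounds for (p, q) is an error.
    """
    if not (0 < p < 1 and 0 < q < 1):
        if rho != 0:
            raise ValueError("degenerate marginals admit only rho = 0")
        return 0.0
    denom = math.sqrt(p * (1 - p) * q * (1 - q))
    p11_lo, p11_hi = max(0.0, p + q - 1.0), min(p, q)
    rho_lo = (p11_lo - p * q) / denom
    rho_hi = (p11_hi - p * q) / denom
    if not rho_lo - 1e-9 <= rho <= rho_hi + 1e-9:
        raise ValueError(
            f"rho={rho} infeasible for stoichiometries ({p}, {q}); "
            f"Fréchet bounds are [{rho_lo:.4f}, {rho_hi:.4f}]"
        )
    target_p11 = rho * denom + p * q
    a, b = norm.ppf(p), norm.ppf(q)

    def p11(r: float) -> float:
        cov = [[1.0, r], [r, 1.0]]
        return float(multivariate_normal(mean=[0, 0], cov=cov).cdf([a, b]))

    lo, hi = -0.999999, 0.999999
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if p11(mid) < target_p11:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _draw_states(cfg: SimConfig, n_reads: int, contig: str,
                 rng: np.random.Generator) -> Dict[int, np.ndarray]:
    """Per-site 0/1 state vectors over the reads of one transcript."""
    sites = sorted(p for (c, p) in cfg.site_stoichiometries if c == contig)
    states: Dict[int, np.ndarray] = {}
    coupled = set()
    for (ca, pa), (cb, pb), rho in cfg.coupled_pairs:
        if ca != contig:
            continue
        p = cfg.site_stoichiometries[(ca, pa)]
        q = cfg.site_stoichiometries[(cb, pb)]
        r = bernoulli_copula_corr(p, q, rho)
        cov = np.array([[1.0, r], [r, 1.0]])
        z = rng.multivariate_normal([0, 0], cov, size=n_reads,
                                    method="cholesky")
        states[pa] = (z[:, 0] < norm.ppf(p)).astype(np.int8) if 0 < p < 1 \
            else np.full(n_reads, int(p >= 1), dtype=np.int8)
        states[pb] = (z[:, 1] < norm.ppf(q)).astype(np.int8) if 0 < q < 1 \
            else np.full(n_reads, int(q >= 1), dtype=np.int8)
        coupled.update((pa, pb))
    for pos in sites:
        if pos in coupled:
            continue
        frac = cfg.site_stoichiometries[(contig, pos)]
        states[pos] = (rng.random(n_reads) < frac).astype(np.int8)
    return states


def simulate_sample(cfg: SimConfig, model: PoreModel) -> SimSample:
    """Generate transcripts, per-read events and the per-read truth table.

    Every read covers its whole transcript.  The base at each designated
    site is forced to the mode's centre base (A or C) so that every site
    is a valid candidate.  Fully deterministic given (cfg, pore model).
    """
    rng = np.random.default_rng(cfg.seed)
    center_base = {"m6A": "A", "m5C": "C"}[cfg.mode]
    transcripts: Dict[str, str] = {}
    events: List[SignalEvent] = []
    truth_rows = []

    for t in range(cfg.n_transcripts):
        contig = f"tx{t:04d}"
        seq = list(rng.choice(list("ACGT"), size=cfg.transcript_length))
        for (c, pos) in cfg.site_stoichiometries:
            if c == contig:
                if not KMER_SIZE - 1 <= pos <= cfg.transcript_length - KMER_SIZE:
                    raise ValueError(f"site {pos} too close to end of {contig}")
                seq[pos] = center_base
        seq = "".join(seq)
        transcripts[contig] = seq

        states = _draw_states(cfg, cfg.n_reads_per_transcript, contig, rng)
        n_pos = cfg.transcript_length - KMER_SIZE + 1
        # per-5-mer shift from any modified base overlapping it, per read
        for r in range(cfg.n_reads_per_transcript):
            read_id = f"{contig}_read{r:05d}"
            for pos, st in sorted(states.items()):
                truth_rows.append((read_id, contig, pos, int(st[r])))
            shifts = np.zeros(n_pos)
            for pos, st in states.items():
                if st[r]:
                    for start in range(max(0, pos - KMER_SIZE + 1),
                                       min(n_pos, pos + 1)):
                        shifts[start] += cfg.mod_shift[pos - start]
            dwell = cfg.dwell_min + rng.poisson(
                max(cfg.dwell_mean - cfg.dwell_min, 0.0), size=n_pos
            )
            for start in range(n_pos):
                kmer = seq[start : start + KMER_SIZE]
                level = model.level(kmer) + shifts[start]
                samples = rng.normal(level, cfg.noise_sd, size=dwell[start])
                # serialize 3'->5' as an event aligner would
                events.append(
                    SignalEvent(
                        read_id=read_id,
                        contig=contig,
                        position=start,
                        kmer=kmer,
                        samples=tuple(samples[::-1]),
                    )
                )

    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "contig", "center_pos", "modified"]
    )
    return SimSample(transcripts=transcripts, events=events, truth=truth)


def simulate_site_mixtures(
    pool_mod: Sequence[float],
    pool_unmod: Sequence[float],
    stoichiometry: float,
    coverage: int,
    seed: int,
) -> np.ndarray:
    """Controlled mixture of per-read probabilities at one site.

    Draws ``round(stoichiometry × coverage)`` values from the modified pool
    and the rest from the unmodified pool, without replacement.  Used to
    build benchmark sites with pre-defined stoichiometry (e.g. the 20–100%
    grid) from pools of per-read classifier outputs.
    """
    if not 0.0 <= stoichiometry <= 1.0:
        raise ValueError("stoichiometry outside [0, 1]")
    rng = np.random.default_rng(seed)
    n_mod = round(stoichiometry * coverage)
    n_unmod = coverage - n_mod
    if n_mod > len(pool_mod) or n_unmod > len(pool_unmod):
        raise ValueError("pool exhausted: fewer reads than requested coverage")
    mod = rng.choice(np.asarray(pool_mod, dtype=float), size=n_mod, replace=False)
    unmod = rng.choice(np.asarray(pool_unmod, dtype=float), size=n_unmod,
                       replace=False)
    out = np.concatenate([mod, unmod])
    rng.shuffle(out)
    return out
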