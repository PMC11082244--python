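"""Differential methylation between two conditions (rank test per site).

For every transcript site with more than 20 reads in both conditions and
an absolute stoichiometry difference of at least 0.1, the per-read
modification probabilities of the two conditions are compared with a
two-tailed Mann–Whitney U-test; Benjamini–Hochberg correction is applied
over exactly the tested sites, and a site is significant when its
adjusted p-value is ≤ alpha.  The stoichiometry filter is part of the
procedure (untested sites never enter the correction), and direction is
reported through the sign of the stoichiometry difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .model2 import estimate_stoichiometry

DEFAULT_MIN_COVERAGE = 21
DEFAULT_MIN_DELTA = 0.1

#: largest min(n_A, n_B) for which the tie-free exact null is enumerated
EXACT_N = 8


def mann_whitney_two_tailed(
    probs_a: Sequence[float], probs_b: Sequence[float]
) -> Tuple[float, float]:
    """(U, two-tailed p); exact enumeration for small tie-free samples.

    The exact null distribution is used when min(n_A, n_B) ≤ 8 and there
    are no ties; otherwise the normal approximation with tie-corrected
    variance and continuity correction applies.  Identical constant
    samples give p = 1.
    """
    a = np.asarray(probs_a, dtype=float)
    b = np.asarray(probs_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(a.size * b.size / 2), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= EXACT_N and not has_ties) \
        else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    u, p = float(res.statistic), float(min(res.pvalue, 1.0))
    if u == a.size * b.size / 2:
        p = 1.0  # perfectly central statistic (e.g. identical multisets)
    return u, p


@dataclass
class DiffConfig:
    min_coverage: int = DEFAULT_MIN_COVERAGE
    min_delta: float = DEFAULT_MIN_DELTA
    alpha: float = 0.05
    hi: float = 0.7
    lo: float = 0.3


def diff_sites(
    reads_a: pd.DataFrame,
    reads_b: pd.DataFrame,
    config: DiffConfig = DiffConfig(),
) -> pd.DataFrame:
    """Differential table over sites present in both conditions.

    Inputs are per-read probability tables (columns contig, center_pos,
    probability) as produced by the single-sample pipeline.  Returns one
    row per site passing the coverage and |Δstoichiometry| filters, with
    U, raw and BH-adjusted p-values and a `significant` flag.
    """
    rows = []
    grouped_a = {k: g["probability"].to_numpy()
                 for k, g in reads_a.groupby(["contig", "center_pos"])}
    grouped_b = {k: g["probability"].to_numpy()
                 for k, g in reads_b.groupby(["contig", "center_pos"])}
    for key in sorted(set(grouped_a) & set(grouped_b)):
        pa, pb = grouped_a[key], grouped_b[key]
        if len(pa) < config.min_coverage or len(pb) < config.min_coverage:
            continue
        stoich_a, *_ = estimate_stoichiometry(pa, hi=config.hi, lo=config.lo)
        stoich_b, *_ = estimate_stoichiometry(pb, hi=config.hi, lo=config.lo)
        delta = stoich_a - stoich_b
        if np.isnan(delta) or abs(delta) < config.min_delta:
            continue
        u, p = mann_whitney_two_tailed(pa, pb)
        rows.append(
            {
                "contig": key[0],
                "center_pos": key[1],
                "coverage_a": len(pa),
                "coverage_b": len(pb),
                "stoich_a": stoich_a,
                "stoich_b": stoich_b,
                "delta": delta,
                "U": u,
                "p_value": p,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["contig", "center_pos", "coverage_a", "coverage_b",
                     "stoich_a", "stoich_b", "delta", "U", "p_value",
                     "adjusted_p", "significant"]
        )
    table = pd.DataFrame(rows)
    table["adjusted_p"] = bh_adjust(table["p_value"].to_numpy())
    table["significant"] = table["adjusted_p"] <= config.alpha
    return table


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(p_values, dtype=float),
                         method="fdr_bh")[1]
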