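"""Read-level co-occurrence, permutation nulls and the transcript test."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom, kstest

from poremeth.cooccurrence import (SitePairStates, distance_stratified_test,
                                   expected_cooccurrence, pair_states_from_reads,
                                   permutation_null, random_pair_null,
                                   read_cooccurrence, transcript_fisher)
from poremeth.simulator import SimConfig, simulate_sample


def _pair(sa, sb, pos_up=100, pos_down=110, orientation="A-upstream"):
    return SitePairStates(contig="tx", pos_upstream=pos_up,
                          pos_downstream=pos_down, orientation=orientation,
                          states_upstream=np.array(sa),
                          states_downstream=np.array(sb))


class TestReadCooccurrence:
    def test_identical_state_vectors_give_one(self):
        assert read_cooccurrence(_pair([1, 1, 0, 0], [1, 1, 0, 0])) == 1.0

    def test_complementary_vectors_give_zero(self):
        assert read_cooccurrence(_pair([1, 0], [0, 1])) == 0.0

    def test_manual_count(self):
        assert read_cooccurrence(_pair([1, 1, 1, 0], [1, 0, 1, 0])) == 0.75

    def test_symmetric_in_sites(self):
        rng = np.random.default_rng(0)
        sa, sb = rng.integers(0, 2, 30), rng.integers(0, 2, 30)
        assert read_cooccurrence(_pair(sa, sb)) == read_cooccurrence(
            _pair(sb, sa)
        )

    def test_distance_is_position_difference(self):
        pair = _pair([1], [1], pos_up=2150, pos_down=2179)
        assert pair.distance == 29

    def test_invalid_distance_rejected(self):
        with pytest.raises(ValueError):
            _pair([1], [1], pos_up=10, pos_down=10)


class TestPermutationNull:
    def test_null_mean_matches_closed_form(self):
        rng = np.random.default_rng(1)
        p_hat, q_hat = 0.5, 0.5
        sa = (rng.random(200) < p_hat).astype(int)
        sb = (rng.random(200) < q_hat).astype(int)
        out = permutation_null(_pair(sa, sb), n_perm=1000, seed=2)
        expect = expected_cooccurrence(sa.mean(), sb.mean())
        assert out["null_mean"] == pytest.approx(expect, abs=0.01)

    def test_perfect_coupling_gives_minimum_p(self):
        rng = np.random.default_rng(3)
        s = (rng.random(100) < 0.5).astype(int)
        out = permutation_null(_pair(s, s), n_perm=1000, seed=4)
        assert out["observed"] == 1.0
        assert out["p_value"] == pytest.approx(1 / 1001)

    def test_null_support_consistent_with_fixed_margins(self):
        # with margins (k1, k2) of n, any same-state fraction must equal
        # (n - k1 - k2 + 2j)/n for an overlap j
        rng = np.random.default_rng(5)
        sa = (rng.random(40) < 0.4).astype(int)
        sb = (rng.random(40) < 0.6).astype(int)
        out = permutation_null(_pair(sa, sb), n_perm=300, seed=6)
        n, k1, k2 = 40, sa.sum(), sb.sum()
        feasible = {(n - k1 - k2 + 2 * j) / n for j in range(0, min(k1, k2) + 1)}
        assert set(np.round(out["null"], 9)) <= {round(v, 9) for v in feasible}

    def test_too_few_rounds_rejected(self):
        with pytest.raises(ValueError):
            permutation_null(_pair([1, 0], [0, 1]), n_perm=10)


class TestRandomPairNull:
    def test_fully_modified_sites_always_agree(self):
        states = {("tx1", 5): np.ones(30, dtype=int),
                  ("tx2", 9): np.ones(25, dtype=int)}
        out = random_pair_null(states, n_pairs=50, seed=0)
        assert out["mean"] == 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        states = {(f"tx{i}", 5): (rng.random(30) < 0.5).astype(int)
                  for i in range(6)}
        a = random_pair_null(states, n_pairs=100, seed=7)
        b = random_pair_null(states, n_pairs=100, seed=7)
        assert np.array_equal(a["null"], b["null"])

    def test_single_transcript_rejected(self):
        with pytest.raises(ValueError):
            random_pair_null({("tx1", 5): np.ones(3, dtype=int)})

    def test_independent_sites_fall_inside_band(self):
        """With no coupling, observed pair co-occurrences should mostly lie
        inside the random-pair 95% band."""
        rng = np.random.default_rng(2)
        states = {(f"tx{i}", 5): (rng.random(60) < 0.5).astype(int)
                  for i in range(20)}
        null = random_pair_null(states, n_pairs=500, seed=3)
        lo, hi = null["band95"]
        inside = 0
        keys = list(states)
        for i in range(0, 40, 2):
            ka, kb = keys[rng.integers(20)], keys[rng.integers(20)]
            if ka == kb:
                continue
            sa, sb = states[ka], states[kb]
            val = np.mean(sa == sb)
            inside += lo <= val <= hi
        assert inside >= 0.8 * 20


class TestDistanceStratified:
    def test_coupled_distance_detected_and_bookkeeping_clean(self, pore_model):
        rng = np.random.default_rng(4)
        pairs = []
        # 8 coupled pairs at distance 10; 8 independent pairs at distance 5
        for i in range(8):
            s = (rng.random(80) < 0.5).astype(int)
            noise = s.copy()
            flip = rng.random(80) < 0.1
            noise[flip] = 1 - noise[flip]
            pairs.append(_pair(s, noise, 100, 110))
        for i in range(8):
            sa = (rng.random(80) < 0.5).astype(int)
            sb = (rng.random(80) < 0.5).astype(int)
            pairs.append(_pair(sa, sb, 100, 105))
        table = distance_stratified_test(pairs, range(1, 16), n_perm=100,
                                         seed=0)
        at10 = table[(table["distance"] == 10)
                     & (table["orientation"] == "A-upstream")]
        at5 = table[(table["distance"] == 5)
                    & (table["orientation"] == "A-upstream")]
        assert at10["p_value"].iloc[0] < 0.01
        assert at5["p_value"].iloc[0] > 0.01
        empty = table[table["distance"] == 3]
        assert empty["n_pairs"].iloc[0] == 0 and np.isnan(
            empty["p_value"].iloc[0]
        )

    def test_orientation_swap_relabels_buckets(self):
        rng = np.random.default_rng(5)
        sa = (rng.random(40) < 0.5).astype(int)
        sb = (rng.random(40) < 0.5).astype(int)
        p1 = [_pair(sa, sb, 100, 107, "A-upstream")]
        p2 = [_pair(sa, sb, 100, 107, "C-upstream")]
        t1 = distance_stratified_test(p1, range(1, 16), n_perm=100, seed=1)
        t2 = distance_stratified_test(p2, range(1, 16), n_perm=100, seed=1)
        v1 = t1.loc[(t1["orientation"] == "A-upstream")
                    & (t1["distance"] == 7), "observed_mean"]
        v2 = t2.loc[(t2["orientation"] == "C-upstream")
                    & (t2["distance"] == 7), "observed_mean"]
        assert v1.iloc[0] == v2.iloc[0]


def fisher_two_tailed_oracle(table):
    """Exact enumeration over the hypergeometric support."""
    (a, b), (c, d) = table
    n, k1, k2 = a + b + c + d, a + b, a + c
    rv = hypergeom(n, k1, k2)
    support = np.arange(max(0, k1 + k2 - n), min(k1, k2) + 1)
    p_obs = rv.pmf(a)
    return float(sum(rv.pmf(x) for x in support
                     if rv.pmf(x) <= p_obs * (1 + 1e-9)))


class TestTranscriptFisher:
    def _tables(self, a_sites, c_sites):
        adf = pd.DataFrame(a_sites, columns=["contig", "center_pos"])
        cdf = pd.DataFrame(c_sites, columns=["contig", "center_pos"])
        return adf, cdf

    def test_diagonal_table_matches_enumeration_oracle(self):
        a_sites = [(f"t{i}", 50) for i in range(10)]
        c_sites = [(f"t{i}", 80) for i in range(10)]
        others = [f"u{i}" for i in range(10)]
        adf, cdf = self._tables(a_sites, c_sites)
        tested = [f"t{i}" for i in range(10)] + others
        out = transcript_fisher(adf, cdf, tested)
        assert out["table"].tolist() == [[10, 0], [0, 10]]
        assert out["p_value"] == pytest.approx(
            fisher_two_tailed_oracle(out["table"])
        )

    def test_balanced_table_gives_p_one(self):
        a_sites = [(f"a{i}", 50) for i in range(10)]
        c_sites = [(f"c{i}", 50) for i in range(5)] + \
                  [(f"a{i}", 80) for i in range(5)]
        adf, cdf = self._tables(a_sites, c_sites)
        tested = [f"a{i}" for i in range(10)] + [f"c{i}" for i in range(5)] \
            + [f"n{i}" for i in range(5)]
        out = transcript_fisher(adf, cdf, tested)
        assert out["table"].tolist() == [[5, 5], [5, 5]]
        assert out["p_value"] == 1.0

    def test_close_pairs_do_not_count_as_both(self):
        adf, cdf = self._tables([("t1", 100)], [("t1", 103)])
        out = transcript_fisher(adf, cdf, ["t1", "t2"])
        assert out["table"][0][0] == 0  # 3 nt apart: both sites discarded

    def test_degenerate_margin_returns_p_one(self):
        adf, cdf = self._tables([], [])
        out = transcript_fisher(adf, cdf, ["t1", "t2"])
        assert out["p_value"] == 1.0 and out["degenerate"]

    def test_independent_flags_give_uniform_p(self):
        rng = np.random.default_rng(6)
        pvals = []
        for rep in range(150):
            tx = [f"t{i}" for i in range(120)]
            a_sites = [(t, 50) for t in tx if rng.random() < 0.4]
            c_sites = [(t, 80) for t in tx if rng.random() < 0.4]
            adf, cdf = self._tables(a_sites, c_sites)
            pvals.append(transcript_fisher(adf, cdf, tx)["p_value"])
        # Fisher p is discrete and conservative: bounded KS guard only
        assert kstest(pvals, "uniform").pvalue > 1e-4 or np.mean(
            np.array(pvals) <= 0.05
        ) <= 0.07


class TestPairStatesFromReads:
    def test_discarded_reads_excluded_from_both(self):
        reads = pd.DataFrame({
            "read_id": ["r1", "r2", "r3", "r1", "r2", "r3"],
            "contig": "tx",
            "center_pos": [10, 10, 10, 20, 20, 20],
            "probability": [0.9, 0.5, 0.1, 0.9, 0.9, 0.2],
        })
        pair = pair_states_from_reads(reads, "tx", 10, 20)
        assert pair.n_reads == 2  # r2 discarded at site 10
        assert read_cooccurrence(pair) == 1.0

    def test_no_shared_reads_returns_none(self):
        reads = pd.DataFrame({
            "read_id": ["r1", "r2"],
            "contig": "tx",
            "center_pos": [10, 20],
            "probability": [0.9, 0.9],
        })
        assert pair_states_from_reads(reads, "tx", 10, 20) is None


class TestRhoRecovery:
    def test_simulator_coupling_raises_cooccurrence_monotonically(
            self, pore_model):
        """End-to-end: generator coupling maps monotonically to read-level
        co-occurrence excess over the independence closed form."""
        excess = []
        for rho in (0.0, 0.4, 0.8):
            sites = {("tx0000", 10): 0.5, ("tx0000", 20): 0.5}
            cfg = SimConfig(
                seed=31, n_transcripts=1, transcript_length=31,
                n_reads_per_transcript=400, site_stoichiometries=sites,
                coupled_pairs=[(("tx0000", 10), ("tx0000", 20), rho)],
            )
            sample = simulate_sample(cfg, pore_model)
            truth = sample.truth.pivot_table(
                index="read_id", columns="center_pos", values="modified"
            )
            sa = truth[10].to_numpy().astype(int)
            sb = truth[20].to_numpy().astype(int)
            obs = np.mean(sa == sb)
            excess.append(obs - expected_cooccurrence(sa.mean(), sb.mean()))
        assert excess[0] < excess[1] < excess[2]
        assert abs(excess[0]) < 0.08
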