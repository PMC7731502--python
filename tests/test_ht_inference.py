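"""Distance tables, the HT flagging rule, and summary statistics.

The composite-likelihood (MCL) distance is cross-checked against an
independent numerical maximum-likelihood fit: on a toy whose pooled base
frequencies are exactly equal, the Tamura-Nei form reduces to the K2P
model, whose likelihood is maximised numerically with scipy.
"""

import math
import warnings

import numpy as np
import pytest
from scipy.optimize import minimize

from telandscape.dating import SaturationError
from telandscape.ht_inference import (
    DistanceTable,
    ht_compare,
    pair_count,
    pairwise_distance_table,
    summarize_distances,
    tn93_mcl_distance,
)


def k2p_numeric_mle(n_same: int, n_ts: int, n_tv: int) -> float:
    """Brute-force K2P distance: maximise the multinomial likelihood of the
    observed site-pattern counts over (t, kappa)."""

    def neg_loglik(params):
        t, kappa = params
        if t <= 0 or kappa <= 0:
            return 1e12
        beta = 1.0 / (kappa + 2.0)
        alpha = kappa * beta
        e1 = math.exp(-4.0 * beta * t)
        e2 = math.exp(-2.0 * (alpha + beta) * t)
        p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
        p_tv = 2 * (0.25 - 0.25 * e1)
        p_same = 1.0 - p_ts - p_tv
        if min(p_ts, p_tv, p_same) <= 0:
            return 1e12
        return -(n_same * math.log(p_same) + n_ts * math.log(p_ts)
                 + n_tv * math.log(p_tv))

    best = None
    for t0 in (0.1, 0.5, 1.0):
        for kap0 in (0.5, 2.0, 8.0):
            res = minimize(neg_loglik, x0=[t0, kap0], method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12})
            if best is None or res.fun < best.fun:
                best = res
    return float(best.x[0])


class TestDistanceTable:
    def test_identical_rows_zero_for_every_method(self):
        rows = [("a", "ACGTACGTAC"), ("b", "ACGTACGTAC")]
        for method in ("p", "k2p", "mcl"):
            table = pairwise_distance_table(rows, method)
            assert table.get("a", "b") == pytest.approx(0.0)

    def test_toy_p_and_k2p_values(self):
        # 1 transition (A->G) in 10 sites
        rows = [("a", "AAAAAAAAAA"), ("b", "GAAAAAAAAA")]
        assert pairwise_distance_table(rows, "p").get("a", "b") == pytest.approx(0.1)
        assert pairwise_distance_table(rows, "k2p").get("a", "b") == pytest.approx(
            -0.5 * math.log(0.8), abs=1e-9)

    def test_mcl_within_sanity_band_of_p_and_k2p(self):
        rows = [("a", "AAAACCGGTT"), ("b", "GAAACCGGTT")]
        p = pairwise_distance_table(rows, "p").get("a", "b")
        k2p = pairwise_distance_table(rows, "k2p").get("a", "b")
        mcl = pairwise_distance_table(rows, "mcl").get("a", "b")
        assert p <= mcl <= 2 * k2p

    def test_mcl_matches_numeric_likelihood_fit_on_equal_frequency_toy(self):
        """Pooled frequencies are exactly uniform, so the composite-
        likelihood distance must agree with a numeric K2P MLE."""
        a, b = "AACGTT", "AGCGTC"  # one purine and one pyrimidine transition
        freqs = np.full(4, 0.25)
        mcl = tn93_mcl_distance(a, b, freqs)
        analytic_k2p = -0.5 * math.log((1 - 2 * (2 / 6)) * math.sqrt(1.0))
        numeric = k2p_numeric_mle(n_same=4, n_ts=2, n_tv=0)
        assert mcl == pytest.approx(analytic_k2p, abs=1e-9)
        assert mcl == pytest.approx(numeric, abs=1e-4)

    def test_mcl_recovers_planted_k2p_divergence(self, rng):
        """K2P is nested in the Tamura-Nei form, so on uniform-composition
        sequences the MCL distance must recover a planted K2P divergence."""
        from telandscape._sequtils import random_sequence
        from telandscape.synthetic_data import mutate_sequence

        base = random_sequence(5000, rng, gc=0.5)
        estimates = []
        for _ in range(20):
            mut = mutate_sequence(base, 0.2, 3.0, rng=rng)
            estimates.append(
                pairwise_distance_table([("a", base), ("b", mut)], "mcl").get("a", "b"))
        assert np.mean(estimates) == pytest.approx(0.2, abs=0.02)

    def test_saturated_pair_marked_undefined(self):
        rows = [("a", "ACAC" * 5), ("b", "GTGT" * 5)]  # every site differs
        table = pairwise_distance_table(rows, "k2p")
        assert frozenset(("a", "b")) in table.undefined
        assert table.get("a", "b") is None

    def test_unaligned_input_rejected(self):
        with pytest.raises(ValueError):
            pairwise_distance_table([("a", "ACGT"), ("b", "ACG")], "p")


class TestHtCompare:
    def _table(self, method, entries):
        ids = sorted({s for pair in entries for s in pair})
        return DistanceTable(method=method, ids=ids,
                             entries={frozenset(k): v for k, v in entries.items()},
                             undefined=set())

    def test_smaller_te_distance_flagged(self):
        te = self._table("p", {("x", "y"): 0.05})
        gene = self._table("p", {("x", "y"): 0.30})
        comps, flagged, total = ht_compare(te, gene)
        assert (flagged, total) == (1, 1)
        assert comps[0].ht_flag

    def test_larger_te_distance_not_flagged(self):
        te = self._table("p", {("x", "y"): 0.30})
        gene = self._table("p", {("x", "y"): 0.05})
        _, flagged, _ = ht_compare(te, gene)
        assert flagged == 0

    def test_tie_flags_neither_direction(self):
        te = self._table("p", {("x", "y"): 0.2})
        gene = self._table("p", {("x", "y"): 0.2})
        _, f1, _ = ht_compare(te, gene)
        _, f2, _ = ht_compare(gene, te)
        assert f1 == f2 == 0

    def test_antisymmetric_under_table_swap(self):
        entries_te = {("a", "b"): 0.1, ("a", "c"): 0.4, ("b", "c"): 0.2}
        entries_gene = {("a", "b"): 0.3, ("a", "c"): 0.2, ("b", "c"): 0.2}
        te = self._table("p", entries_te)
        gene = self._table("p", entries_gene)
        comps1, f1, t1 = ht_compare(te, gene)
        comps2, f2, t2 = ht_compare(gene, te)
        for c1, c2 in zip(comps1, comps2):
            if c1.d_te != c1.d_gene:
                assert c1.ht_flag != c2.ht_flag
            else:
                assert not c1.ht_flag and not c2.ht_flag

    def test_min_split_gate(self):
        te = self._table("p", {("x", "y"): 0.05})
        gene = self._table("p", {("x", "y"): 0.30})
        splits = {frozenset(("x", "y")): 50.0}
        _, flagged, _ = ht_compare(te, gene, splits, min_split=100.0)
        assert flagged == 0
        _, flagged, _ = ht_compare(te, gene, splits, min_split=40.0)
        assert flagged == 1

    def test_missing_pair_skipped_with_warning(self):
        te = self._table("p", {("x", "y"): 0.1, ("x", "z"): 0.1, ("y", "z"): 0.1})
        gene = self._table("p", {("x", "y"): 0.3, ("x", "z"): 0.3})
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            _, flagged, total = ht_compare(te, gene)
        assert total == 2
        assert caught


class TestSummaries:
    def test_constant_distances(self):
        t = DistanceTable("p", ["a", "b", "c"],
                          {frozenset(p): 0.1 for p in (("a", "b"), ("a", "c"),
                                                       ("b", "c"))}, set())
        s = summarize_distances(t)
        assert (s.n, s.mean, s.sd) == (3, pytest.approx(0.1), pytest.approx(0.0))

    def test_population_sd_and_range(self):
        t = DistanceTable("p", ["a", "b"],
                          {frozenset(("a", "b")): 0.0,
                           frozenset(("a", "c")): 0.2}, set())
        s = summarize_distances(t)
        assert s.mean == pytest.approx(0.1)
        assert s.sd == pytest.approx(0.1)  # population SD
        assert (s.min, s.max) == (0.0, 0.2)

    @pytest.mark.parametrize("sizes,expected", [
        ([35, 5, 3, 7], 629),
        ([2], 1),
        ([0, 1], 0),
    ])
    def test_within_cluster_pair_counts(self, sizes, expected):
        assert pair_count(sizes) == expected

    def test_negative_cluster_size_rejected(self):
        with pytest.raises(ValueError):
            pair_count([-1, 5])
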