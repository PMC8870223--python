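import itertools
import math

import numpy as np
import pandas as pd
import pytest

from stromareg import enrichment as enr
from stromareg.errors import StromaregError


def running_sum_es(rnk: pd.Series, members: set, weight: float = 1.0) -> float:
    """Independent oracle: explicit position-by-position running sum."""
    order = sorted(rnk.index, key=lambda g: (-rnk[g], str(g)))
    scores = np.abs(rnk.loc[order].to_numpy()) ** weight
    is_hit = np.array([g in members for g in order])
    wsum = scores[is_hit].sum()
    n_miss = (~is_hit).sum()
    run, best = 0.0, 0.0
    for i in range(len(order)):
        if is_hit[i]:
            run += scores[i] / wsum
        else:
            run -= 1.0 / n_miss
        if abs(run) > abs(best):
            best = run
    return best


class TestGseaPreranked:
    def _rnk(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        return pd.Series(np.sort(rng.normal(size=n))[::-1],
                         index=[f"g{i}" for i in range(n)])

    def test_top_ranked_set_positive_es_full_leading_edge(self):
        rnk = self._rnk(20)
        gs = enr.GeneSet("top", ["g0", "g1", "g2"])
        res = enr.gsea_preranked(rnk, gs, n_perm=200, seed=1)
        assert res.es > 0
        assert set(res.leading_edge) == {"g0", "g1", "g2"}

    def test_es_matches_running_sum_oracle(self):
        rnk = self._rnk(10, seed=5)
        members = {"g1", "g4", "g7"}
        res = enr.gsea_preranked(rnk, enr.GeneSet("s", sorted(members)),
                                 n_perm=100, seed=0)
        assert res.es == pytest.approx(running_sum_es(rnk, members), abs=1e-12)

    def test_unweighted_reversed_ranking_negates_es(self):
        rnk = self._rnk(12, seed=2)
        members = {"g0", "g3", "g5"}
        res_fwd = enr.gsea_preranked(rnk, enr.GeneSet("s", sorted(members)),
                                     weight=0, n_perm=100, seed=0)
        reversed_rnk = pd.Series(-rnk.to_numpy()[::-1], index=rnk.index[::-1])
        res_rev = enr.gsea_preranked(reversed_rnk, enr.GeneSet("s", sorted(members)),
                                     weight=0, n_perm=100, seed=0)
        assert res_fwd.es == pytest.approx(-res_rev.es, abs=1e-12)

    def test_es_invariant_to_positive_rescaling(self):
        rnk = self._rnk(15, seed=3)
        gs = enr.GeneSet("s", ["g2", "g9", "g11"])
        a = enr.gsea_preranked(rnk, gs, n_perm=100, seed=0).es
        b = enr.gsea_preranked(rnk * 7.5, gs, n_perm=100, seed=0).es
        assert a == pytest.approx(b, abs=1e-12)

    def test_empty_intersection_errors(self):
        with pytest.raises(StromaregError):
            enr.gsea_preranked(self._rnk(), enr.GeneSet("s", ["absent"]),
                               n_perm=100, seed=0)

    def test_planted_signal_detected_in_collection(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(300)]
        scores = pd.Series(rng.normal(size=300), index=genes)
        planted = genes[:25]
        scores[planted] += 2.0
        sets = [enr.GeneSet("planted", planted),
                enr.GeneSet("random", genes[100:125])]
        out = enr.gsea_collection(scores, sets, n_perm=300, seed=4)
        assert out.loc["planted", "nes"] > out.loc["random", "nes"]
        assert out.loc["planted", "pvalue"] < 0.05


class TestHypergeom:
    def test_complete_overlap_combinatoric_value(self):
        p, ratio = enr.hypergeom_enrichment(5, 5, 5, 10)
        assert p == pytest.approx(1 / math.comb(10, 5))
        assert ratio == pytest.approx(2.0)

    def test_empty_list_degenerate(self):
        p, ratio = enr.hypergeom_enrichment(0, 0, 5, 10)
        assert p == 1.0
        assert ratio == 0.0

    def test_matches_direct_tail_summation(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            universe = int(rng.integers(20, 200))
            set_size = int(rng.integers(1, universe // 2))
            list_size = int(rng.integers(1, universe // 2))
            hits = int(rng.integers(0, min(set_size, list_size) + 1))
            p, _ = enr.hypergeom_enrichment(hits, list_size, set_size, universe)
            tail = sum(math.comb(set_size, k) * math.comb(universe - set_size,
                                                          list_size - k)
                       for k in range(hits, min(set_size, list_size) + 1)
                       ) / math.comb(universe, list_size)
            assert p == pytest.approx(tail, rel=1e-12, abs=1e-300)

    def test_inconsistent_counts_error(self):
        with pytest.raises(StromaregError):
            enr.hypergeom_enrichment(6, 5, 5, 10)


def enumerate_ks_pvalue(a, b):
    """Exact permutation p by full enumeration of label assignments."""
    pooled = list(a) + list(b)
    n = len(a)
    d_obs = _ks_d(a, b)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if _ks_d(ga, gb) >= d_obs - 1e-12:
            count += 1
    return count / total


def _ks_d(a, b):
    pts = sorted(set(a) | set(b))
    a, b = np.sort(a), np.sort(b)
    d = 0.0
    for x in pts:
        fa = np.searchsorted(a, x, side="right") / len(a)
        fb = np.searchsorted(b, x, side="right") / len(b)
        d = max(d, abs(fa - fb))
    return d


class TestKSShift:
    def test_identical_samples_d_zero(self):
        d, p = enr.ks_shift_test([1, 2, 3], [1, 2, 3])
        assert d == 0.0
        assert p == 1.0

    def test_disjoint_pairs_exact_third(self):
        d, p = enr.ks_shift_test([1, 2], [3, 4])
        assert d == 1.0
        assert p == pytest.approx(1 / 3)

    def test_exact_mode_matches_enumeration(self):
        rng = np.random.default_rng(19)
        for _ in range(10):
            a = rng.normal(size=3)
            b = rng.normal(size=4)
            _, p = enr.ks_shift_test(a, b)
            assert p == pytest.approx(enumerate_ks_pvalue(a, b), abs=1e-9)

    def test_exact_mode_used_for_n5(self):
        # n=m=5 sits inside the nm<=30 exact regime; the reported p must be
        # the exact one, not the (less accurate at this size) asymptotic
        rng = np.random.default_rng(23)
        from scipy import stats

        for _ in range(5):
            a, b = rng.normal(size=5), rng.normal(0.5, 1, size=5)
            _, p = enr.ks_shift_test(a, b)
            assert p == pytest.approx(
                stats.ks_2samp(a, b, method="exact").pvalue, abs=1e-12)

    def test_small_group_errors(self):
        with pytest.raises(StromaregError):
            enr.ks_shift_test([1], [2, 3])


class TestConcordance:
    def _calls(self, n, up_a, up_b, both):
        genes = [f"g{i}" for i in range(n)]
        a = pd.Series("unchanged", index=genes)
        b = pd.Series("unchanged", index=genes)
        a.iloc[:up_a] = "up"
        b.iloc[:both] = "up"
        b.iloc[up_a: up_a + (up_b - both)] = "up"
        return a, b

    def test_margin_expectation_and_ratio(self):
        a, b = self._calls(1000, 100, 150, 40)
        res = enr.contingency_concordance(a, b)
        assert res["observed"] == 40
        assert res["expected"] == pytest.approx(15.0)
        assert res["ratio"] == pytest.approx(40 / 15)
        # independent oracle: hypergeometric upper tail of the overlap
        import math
        tail = sum(math.comb(150, k) * math.comb(850, 100 - k)
                   for k in range(40, 101)) / math.comb(1000, 100)
        assert res["pvalue"] <= 2 * tail + 1e-12

    def test_independent_random_calls_ratio_near_one(self):
        rng = np.random.default_rng(31)
        ratios = []
        for _ in range(200):
            genes = [f"g{i}" for i in range(300)]
            a = pd.Series(rng.choice(["up", "down", "unchanged"], 300,
                                     p=[0.2, 0.2, 0.6]), index=genes)
            b = pd.Series(rng.choice(["up", "down", "unchanged"], 300,
                                     p=[0.2, 0.2, 0.6]), index=genes)
            ratios.append(enr.contingency_concordance(a, b)["ratio"])
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.05)

    def test_identical_calls_maximal_and_significant(self):
        rng = np.random.default_rng(33)
        genes = [f"g{i}" for i in range(500)]
        a = pd.Series(rng.choice(["up", "down", "unchanged"], 500), index=genes)
        res = enr.contingency_concordance(a, a.copy())
        n_changed = (a != "unchanged").sum()
        assert res["observed"] == n_changed
        assert res["pvalue"] < 1e-10

    def test_disjoint_universes_error(self):
        a = pd.Series(["up"], index=["g1"])
        b = pd.Series(["up"], index=["g2"])
        with pytest.raises(StromaregError):
            enr.contingency_concordance(a, b)
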