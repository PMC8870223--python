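import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stromareg.containers import CountMatrix
from stromareg.errors import StromaregError
from stromareg import expression as expr
from stromareg.nbdiff import bh_fdr


def _cm(array, samples, lengths=None):
    counts = pd.DataFrame(array, columns=samples,
                          index=[f"g{i}" for i in range(len(array))])
    cond = pd.Series({s: s.rsplit("_", 1)[0] for s in samples})
    lens = pd.Series(lengths, index=counts.index) if lengths is not None else None
    return CountMatrix(counts, cond, lengths=lens)


class TestCPM:
    def test_single_gene_sample_is_million(self):
        cm = _cm([[10]], ["MONO_1"])
        assert expr.compute_cpm(cm).iloc[0, 0] == 1e6

    def test_zero_count_gene_is_zero_and_split(self):
        cm = _cm([[10], [90], [0]], ["MONO_1"])
        cpm = expr.compute_cpm(cm)
        assert list(cpm["MONO_1"]) == [1e5, 9e5, 0.0]

    def test_columns_sum_to_million(self, small_counts):
        sums = expr.compute_cpm(small_counts).sum(axis=0)
        assert np.allclose(sums, 1e6)

    def test_zero_library_names_sample(self):
        cm = _cm([[0, 5]], ["MONO_1", "MONO_2"])
        with pytest.raises(StromaregError, match="MONO_1"):
            expr.compute_cpm(cm)


class TestRPKM:
    def test_unit_definition(self):
        # 1 read on a 1 kb gene in a library of 10^6 mapped reads -> RPKM 1
        counts = np.zeros((2, 1), dtype=int)
        counts[0, 0] = 1
        counts[1, 0] = 999_999
        cm = _cm(counts, ["MONO_1"], lengths=[1000, 50_000])
        assert expr.compute_rpkm(cm).iloc[0, 0] == pytest.approx(1.0)

    def test_zero_count_is_zero(self):
        cm = _cm([[0], [10]], ["MONO_1"], lengths=[1000, 1000])
        assert expr.compute_rpkm(cm).iloc[0, 0] == 0.0

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 500, size=(20, 4))
        lengths = rng.integers(200, 5000, size=20)
        cm = _cm(counts, ["MONO_1", "MONO_2", "TSW_1", "TSW_2"], lengths=lengths)
        rpkm = expr.compute_rpkm(cm).to_numpy()
        lib = counts.sum(axis=0)
        expected = np.empty_like(rpkm)
        for i in range(20):
            for j in range(4):
                expected[i, j] = counts[i, j] / (lengths[i] / 1e3) / (lib[j] / 1e6)
        assert np.allclose(rpkm, expected, rtol=1e-9)

    def test_missing_length_names_feature(self):
        cm = _cm([[1], [1]], ["MONO_1"], lengths=[1000, -5])
        with pytest.raises(StromaregError, match="g1"):
            expr.compute_rpkm(cm)


class TestBHFDR:
    def test_hand_examples(self):
        assert list(bh_fdr([1, 1, 1])) == [1, 1, 1]
        assert bh_fdr([0.02])[0] == pytest.approx(0.02)
        # step-up by hand: 0.01*3/1=0.03, 0.02*3/2=0.03, 0.03*3/3=0.03
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30),
           st.randoms(use_true_random=False))
    def test_permutation_equivariance(self, pvals, rnd):
        p = np.array(pvals)
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        perm = np.array(perm)
        direct = bh_fdr(p)[perm]
        permuted = bh_fdr(p[perm])
        assert np.allclose(direct, permuted)

    def test_rejects_out_of_range(self):
        with pytest.raises(StromaregError):
            bh_fdr([0.5, 1.5])


class TestDifferentialExpression:
    def test_identical_groups_unchanged(self):
        counts = np.tile(np.arange(10, 60, 5)[:, None], (1, 6))
        cm = _cm(counts, ["MONO_1", "MONO_2", "MONO_3", "TSW_1", "TSW_2", "TSW_3"])
        res = expr.differential_expression(cm, "MONO", "TSW")
        assert (res["call"] == "unchanged").all()
        assert np.allclose(res["log2fc"], 0.0, atol=1e-9)

    def test_strong_induction_called_up(self, small_counts):
        res = expr.differential_expression(small_counts, "MONO", "TSW")
        assert res.loc["g0", "call"] == "up"

    def test_call_respects_thresholds(self, small_counts):
        res = expr.differential_expression(small_counts, "MONO", "TSW")
        lfc_cut = np.log2(1.5)
        for _, row in res.iterrows():
            should = (row["fdr"] < 0.05 and abs(row["log2fc"]) > lfc_cut
                      and row["avg_log2cpm"] > 0)
            assert (row["call"] != "unchanged") == should

    def test_log2fc_close_to_direct_ratio(self, small_counts):
        res = expr.differential_expression(small_counts, "MONO", "TSW")
        counts = small_counts.counts
        cpm = counts / counts.sum(axis=0) * 1e6
        direct = np.log2(cpm[["TSW_1", "TSW_2", "TSW_3"]].mean(axis=1)
                         / cpm[["MONO_1", "MONO_2", "MONO_3"]].mean(axis=1))
        big = counts.mean(axis=1) >= 50
        assert (res.loc[big, "log2fc"] - direct[big]).abs().max() < 0.1

    def test_requires_two_replicates(self):
        cm = _cm(np.ones((5, 3), dtype=int),
                 ["MONO_1", "MONO_2", "TSW_1"])
        with pytest.raises(StromaregError, match="replicates"):
            expr.differential_expression(cm, "MONO", "TSW")

    def test_unknown_condition_errors(self, small_counts):
        with pytest.raises(StromaregError, match="CO"):
            expr.differential_expression(small_counts, "MONO", "CO")


class TestStromalFilter:
    def _setup(self):
        genes = [f"g{i}" for i in range(2000)]
        stromal = pd.Series(np.arange(2000, 0, -1, dtype=float), index=genes)
        mm = pd.DataFrame({"MONO_1": np.full(2000, 50.0)}, index=genes)
        return stromal, mm

    def test_top_ranked_silent_gene_excluded(self):
        stromal, mm = self._setup()
        mm.loc["g4"] = 0.3  # stromal rank 5, silenced in MM
        assert "g4" in expr.stromal_signature_filter(mm, stromal)

    def test_top_ranked_expressed_gene_retained(self):
        stromal, mm = self._setup()
        assert "g4" not in expr.stromal_signature_filter(mm, stromal)

    def test_below_rank_cutoff_retained(self):
        stromal, mm = self._setup()
        mm.loc["g1500"] = 0.0  # silenced but stromal rank 1501
        assert "g1500" not in expr.stromal_signature_filter(mm, stromal)

    def test_empty_stromal_errors(self):
        _, mm = self._setup()
        with pytest.raises(StromaregError):
            expr.stromal_signature_filter(mm, pd.Series(dtype=float))


class TestPromoterFilter:
    def _status(self):
        return pd.DataFrame({"MONO": [False, True, False],
                             "TSW": [False, True, True],
                             "CO": [False, True, False]},
                            index=["closed_all", "open_all", "open_one"])

    def test_closed_in_all_three_excluded(self):
        assert expr.promoter_open_filter(self._status()) == ["closed_all"]

    def test_open_in_one_condition_retained_by_default(self):
        assert "open_one" not in expr.promoter_open_filter(self._status())

    def test_strict_reading_excludes_partially_open(self):
        excl = expr.promoter_open_filter(self._status(), require_closed_in_all=False)
        assert set(excl) == {"closed_all", "open_one"}

    def test_missing_condition_errors(self):
        with pytest.raises(StromaregError, match="CO"):
            expr.promoter_open_filter(self._status()[["MONO", "TSW"]])


class TestMakeRnk:
    def test_sorted_descending_by_fold_change(self):
        res = pd.DataFrame({"log2fc": [2.0, 0.5, 1.0]}, index=["a", "b", "c"])
        rnk = expr.make_rnk(res)
        assert list(rnk.index) == ["a", "c", "b"]

    def test_excluded_genes_absent(self):
        res = pd.DataFrame({"log2fc": [2.0, 0.5]}, index=["a", "b"])
        assert "b" not in expr.make_rnk(res, excluded=["b"]).index

    def test_duplicate_symbols_error(self):
        res = pd.DataFrame({"log2fc": [1.0, 2.0]}, index=["a", "a"])
        with pytest.raises(StromaregError, match="duplicate"):
            expr.make_rnk(res)


class TestPCA:
    def test_duplicated_samples_coincide(self):
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
        mat["d"] = mat["a"]
        coords = expr.pca_embed(mat, 2)
        assert np.allclose(coords.loc["a"], coords.loc["d"], atol=1e-8)

    def test_rank_one_matrix_loads_pc1(self):
        v = np.arange(1, 5, dtype=float)
        mat = pd.DataFrame(np.outer(np.ones(10), v), columns=list("abcd"))
        coords = expr.pca_embed(mat, 3)
        var = coords.var(axis=0, ddof=1)
        assert var["PC1"] > 0
        assert np.allclose(var[["PC2", "PC3"]], 0, atol=1e-12)

    def test_too_many_components_errors(self):
        mat = pd.DataFrame(np.ones((5, 2)), columns=["a", "b"])
        with pytest.raises(StromaregError):
            expr.pca_embed(mat, 3)

    def test_mono_separates_from_treated_conditions(self):
        # planted between-condition effects dominate within-condition noise
        from stromareg.synthetic import SimConfig, simulate_expression

        cm, _, _, _ = simulate_expression(SimConfig(seed=21))
        logcpm = np.log2(expr.compute_cpm(cm) + 0.5)
        coords = expr.pca_embed(logcpm, 2)
        mono = coords.loc[[s for s in coords.index if s.startswith("MONO")]]
        rest = coords.loc[[s for s in coords.index if not s.startswith("MONO")]]
        spread = np.linalg.norm(mono - mono.mean(), axis=1).mean()
        gap = np.linalg.norm(mono.mean() - rest.mean())
        assert gap > spread


class TestZScore:
    def test_hand_example_sample_sd(self):
        z = expr.zscore_rows(pd.DataFrame([[1.0, 2.0, 3.0]]))
        assert np.allclose(z.to_numpy(), [[-1, 0, 1]])

    def test_constant_row_is_zero(self):
        z = expr.zscore_rows(pd.DataFrame([[5.0, 5.0, 5.0]]))
        assert np.allclose(z.to_numpy(), 0.0)

    def test_row_means_are_zero(self):
        rng = np.random.default_rng(3)
        z = expr.zscore_rows(pd.DataFrame(rng.normal(size=(20, 7))))
        assert np.abs(z.mean(axis=1)).max() < 1e-12
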