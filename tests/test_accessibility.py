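import numpy as np
import pandas as pd
import pytest

from stromareg import accessibility as acc
from stromareg.errors import StromaregError
from conftest import brute_force_support_peaks, random_peak_instances


def _peaks(intervals):
    return pd.DataFrame({
        "chrom": "chr1",
        "start": [s for s, _ in intervals],
        "end": [e for _, e in intervals],
        "summit": [(e - s) // 2 for s, e in intervals]})


class TestReferenceCompilation:
    def test_three_of_six_samples_retained(self):
        iv = [(100, 300)]
        per_sample = [_peaks(iv)] * 3 + [_peaks([(5000, 5100)])] * 3
        ref = acc.compile_reference_peaks(per_sample, min_support=3)
        got = {(r.start, r.end): r.support for r in ref.itertuples()}
        assert got[(100, 300)] == 3

    def test_two_of_six_samples_dropped(self):
        per_sample = [_peaks([(100, 300)])] * 2 + [_peaks([(5000, 5100)])] * 4
        ref = acc.compile_reference_peaks(per_sample, min_support=3)
        assert (100, 300) not in {(r.start, r.end) for r in ref.itertuples()}

    def test_matches_per_base_support_sweep(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            per_sample = random_peak_instances(rng)
            ref = acc.compile_reference_peaks(per_sample, min_support=3)
            expected = brute_force_support_peaks(per_sample, 3)
            got = [(r.start, r.end) for r in ref.itertuples()]
            assert got == expected

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(5)
        per_sample = random_peak_instances(rng, n_samples=6)
        ref = acc.compile_reference_peaks(per_sample, min_support=3)
        again = acc.compile_reference_peaks([ref], min_support=1)
        assert list(again["start"]) == list(ref["start"])
        assert list(again["end"]) == list(ref["end"])

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(9)
        per_sample = random_peak_instances(rng, n_samples=6)
        a = acc.compile_reference_peaks(per_sample, min_support=3)
        b = acc.compile_reference_peaks(per_sample[::-1], min_support=3)
        assert a[["start", "end", "support"]].equals(b[["start", "end", "support"]])

    def test_malformed_interval_errors(self):
        bad = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [90]})
        with pytest.raises(StromaregError):
            acc.compile_reference_peaks([bad, bad, bad])


class TestReadCounting:
    def _ref(self):
        ref = _peaks([(100, 200), (500, 700)])
        ref["name"] = ["p1", "p2"]
        ref["support"] = 3
        return ref

    def test_no_reads_gives_zero_column(self):
        reads = {"MONO_1": pd.DataFrame(columns=["chrom", "start", "end"])}
        cm = acc.count_reads_in_peaks(reads, self._ref())
        assert (cm.counts["MONO_1"] == 0).all()

    def test_midpoint_rule_counts_spanning_read_once(self):
        # read [150, 250): midpoint 200 -> outside [100,200) but inside nothing
        # read [90, 130): midpoint 110 -> inside p1
        reads = {"MONO_1": pd.DataFrame({
            "chrom": ["chr1", "chr1"], "start": [150, 90], "end": [250, 130]})}
        cm = acc.count_reads_in_peaks(reads, self._ref())
        assert cm.counts.loc["p1", "MONO_1"] == 1
        assert cm.counts.loc["p2", "MONO_1"] == 0

    def test_matches_quadratic_containment_scan(self):
        rng = np.random.default_rng(21)
        starts = np.sort(rng.choice(np.arange(0, 9000, 120), size=30, replace=False))
        ref = _peaks([(s, s + rng.integers(40, 110)) for s in starts])
        ref["name"] = [f"p{i}" for i in range(len(ref))]
        rstart = rng.integers(0, 9500, size=2000)
        reads = pd.DataFrame({"chrom": "chr1", "start": rstart, "end": rstart + 50})
        cm = acc.count_reads_in_peaks({"MONO_1": reads}, ref)
        mids = (reads["start"] + reads["end"]) // 2
        for p in ref.itertuples():
            brute = int(((mids >= p.start) & (mids < p.end)).sum())
            assert cm.counts.loc[p.name, "MONO_1"] == brute

    def test_total_counts_bounded_by_reads(self):
        rng = np.random.default_rng(2)
        ref = _peaks([(0, 500), (600, 900)])
        ref["name"] = ["p1", "p2"]
        rstart = rng.integers(0, 1200, size=300)
        reads = pd.DataFrame({"chrom": "chr1", "start": rstart, "end": rstart + 50})
        cm = acc.count_reads_in_peaks({"MONO_1": reads}, ref)
        assert cm.counts["MONO_1"].sum() <= 300

    def test_unknown_chromosome_skipped(self, caplog):
        reads = {"MONO_1": pd.DataFrame({
            "chrom": ["chrUn"], "start": [10], "end": [60]})}
        with caplog.at_level("WARNING"):
            cm = acc.count_reads_in_peaks(reads, self._ref())
        assert (cm.counts["MONO_1"] == 0).all()
        assert "skipped" in caplog.text


class TestGfold:
    def test_identical_groups_zero(self):
        assert acc.gfold_value([100, 100], [100, 100], [1e6] * 2, [1e6] * 2) == 0.0

    def test_cutoff_constant_is_log2_of_fc_threshold(self):
        assert acc.GFOLD_CUTOFF == 0.585
        assert abs(np.log2(1.5) - acc.GFOLD_CUTOFF) < 5e-4

    def test_matches_monte_carlo_posterior_quantiles(self):
        # independent oracle: direct Gamma posterior sampling
        rng = np.random.default_rng(7)
        for ya, yb in [(200.0, 50.0), (50.0, 200.0), (30.0, 45.0)]:
            ga = rng.gamma(ya + 0.5, 1e-6, 100_000)
            gb = rng.gamma(yb + 0.5, 1e-6, 100_000)
            ratio = np.log2(gb / ga)
            lo, hi = np.quantile(ratio, [0.005, 0.995])
            mc = lo if lo > 0 else hi if hi < 0 else 0.0
            analytic = acc.gfold_value([ya], [yb], [1e6], [1e6])
            assert analytic == pytest.approx(mc, abs=0.02)

    def test_empty_group_errors(self):
        with pytest.raises(StromaregError):
            acc.gfold_value([], [5], [1e6], [1e6])


class TestPromoterDistal:
    def _genes(self, tss_list):
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(len(tss_list))],
            "chrom": "chr1", "strand": "+", "tss": tss_list,
            "length": 1000})

    def test_peak_overlapping_tss_is_promoter(self):
        ref = _peaks([(9_900, 10_200)])
        ref["name"] = ["p1"]
        labels = acc.classify_promoter_distal(ref, self._genes([10_000]))
        assert labels["p1"] == "promoter"

    def test_far_peak_is_distal(self):
        ref = _peaks([(50_000, 50_300)])
        ref["name"] = ["p1"]
        labels = acc.classify_promoter_distal(ref, self._genes([10_000]))
        assert labels["p1"] == "distal"

    def test_half_open_boundary(self):
        # window = [tss-2500, tss+2501); peak starting exactly there is distal
        tss = 10_000
        ref = _peaks([(tss + 2501, tss + 2800), (tss + 2500, tss + 2800)])
        ref["name"] = ["outside", "touching"]
        labels = acc.classify_promoter_distal(ref, self._genes([tss]))
        assert labels["outside"] == "distal"
        assert labels["touching"] == "promoter"

    def test_matches_per_base_window_membership(self):
        rng = np.random.default_rng(3)
        genes = self._genes(sorted(rng.integers(3000, 90_000, size=5)))
        starts = rng.integers(0, 95_000, size=40)
        ref = _peaks([(s, s + 200) for s in starts])
        ref["name"] = [f"p{i}" for i in range(40)]
        labels = acc.classify_promoter_distal(ref, genes)
        member = np.zeros(100_000, dtype=bool)
        for t in genes["tss"]:
            member[max(t - 2500, 0): t + 2501] = True
        for p in ref.itertuples():
            expected = "promoter" if member[p.start:p.end].any() else "distal"
            assert labels[p.name] == expected

    def test_labels_partition_reference(self):
        rng = np.random.default_rng(4)
        genes = self._genes([20_000])
        starts = rng.integers(0, 50_000, size=25)
        ref = _peaks([(s, s + 150) for s in starts])
        ref["name"] = [f"p{i}" for i in range(25)]
        labels = acc.classify_promoter_distal(ref, genes)
        assert len(labels) == len(ref)
        assert set(labels.unique()) <= {"promoter", "distal"}


class TestSummitWindows:
    def test_window_arithmetic(self):
        ref = pd.DataFrame({"chrom": ["chr1"], "start": [900], "end": [1200],
                            "name": ["p1"], "summit": [100]})
        w = acc.summit_windows(ref)
        assert (w["start"].iloc[0], w["end"].iloc[0]) == (950, 1051)

    def test_all_windows_101bp_unless_clipped(self):
        ref = pd.DataFrame({"chrom": "chr1", "start": [0, 5000], "end": [100, 5400],
                            "name": ["clipped", "normal"], "summit": [20, 200]})
        w = acc.summit_windows(ref)
        lengths = w["end"] - w["start"]
        assert lengths[w["name"] == "normal"].iloc[0] == 101
        assert w.loc[w["name"] == "clipped", "start"].iloc[0] == 0

    def test_missing_summit_errors(self):
        ref = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100],
                            "name": ["p1"], "summit": [-1]})
        with pytest.raises(StromaregError):
            acc.summit_windows(ref)
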