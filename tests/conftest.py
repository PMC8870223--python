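import numpy as np
import pandas as pd
import pytest

from stromareg.containers import CountMatrix


@pytest.fixture
def small_counts():
    """3v3 two-condition matrix with one obviously induced gene."""
    rng = np.random.default_rng(42)
    base = rng.poisson(100, size=(400, 6))
    base[0, 3:] *= 8  # strong planted induction in TSW
    counts = pd.DataFrame(base, index=[f"g{i}" for i in range(400)],
                          columns=["MONO_1", "MONO_2", "MONO_3",
                                   "TSW_1", "TSW_2", "TSW_3"])
    conditions = pd.Series({c: c.rsplit("_", 1)[0] for c in counts.columns})
    lengths = pd.Series(1000, index=counts.index)
    return CountMatrix(counts, conditions, lengths=lengths)


def brute_force_support_peaks(per_sample, min_support, span=10_000):
    """Per-base support sweep: maximal runs covered by >= min_support samples."""
    cover = np.zeros(span, dtype=int)
    for df in per_sample:
        mask = np.zeros(span, dtype=bool)
        for _, row in df.iterrows():
            mask[row["start"]:row["end"]] = True
        cover += mask
    keep = cover >= min_support
    out = []
    i = 0
    while i < span:
        if keep[i]:
            j = i
            while j < span and keep[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def random_peak_instances(rng, n_samples=5, max_peaks=8, span=10_000):
    dfs = []
    for _ in range(n_samples):
        n = rng.integers(1, max_peaks + 1)
        starts = rng.integers(0, span - 300, size=n)
        widths = rng.integers(50, 300, size=n)
        dfs.append(pd.DataFrame({
            "chrom": "chr1", "start": starts, "end": starts + widths,
            "summit": widths // 2}))
    return dfs
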