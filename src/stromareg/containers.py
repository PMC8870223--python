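"""Shared in-memory containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from stromareg.errors import StromaregError


@dataclass
class CountMatrix:
    """Integer feature-by-sample count matrix with condition labels.

    Parameters
    ----------
    counts
        DataFrame of non-negative integer counts, index = feature ids,
        columns = sample ids.
    conditions
        Series mapping each sample id to its condition label
        (e.g. ``MONO``/``TSW``/``CO``).
    lengths
        Optional Series of feature lengths in bp (required for RPKM).
    """

    counts: pd.DataFrame
    conditions: pd.Series
    lengths: pd.Series | None = field(default=None)

    def __post_init__(self):
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise StromaregError(f"duplicate feature identifier: {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise StromaregError(f"duplicate sample identifier: {dup!r}")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise StromaregError("counts must be non-negative")
        missing = [s for s in self.counts.columns if s not in self.conditions.index]
        if missing:
            raise StromaregError(f"samples without a condition label: {missing}")
        self.conditions = self.conditions.loc[self.counts.columns]
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.counts.index)

    @property
    def features(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def samples_of(self, condition: str) -> list[str]:
        sel = [s for s in self.samples if self.conditions[s] == condition]
        if not sel:
            raise StromaregError(f"no samples with condition {condition!r}")
        return sel

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_conditions(self, conditions: list[str]) -> "CountMatrix":
        keep = [s for s in self.samples if self.conditions[s] in conditions]
        return CountMatrix(
            self.counts[keep], self.conditions.loc[keep], lengths=self.lengths
        )


def conditions_from_sample_names(samples) -> pd.Series:
    """Condition label = sample name up to the last underscore (``MONO_1`` -> ``MONO``)."""
    labels = {}
    for s in samples:
        if "_" not in s:
            raise StromaregError(
                f"cannot infer condition from sample name {s!r} (expected COND_rep)"
            )
        labels[s] = s.rsplit("_", 1)[0]
    return pd.Series(labels)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child RNG stream of a single master seed.

    A stable 32-bit key is derived from the stream name so that regenerating
    one data type does not perturb the draws of another.
    """
    key = np.frombuffer(name.encode("utf-8").ljust(4, b"\0"), dtype=np.uint8)
    h = np.uint32(2166136261)
    for b in key:
        h = np.uint32((int(h) ^ int(b)) * 16777619 & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, int(h)]))
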