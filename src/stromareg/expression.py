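"""Expression quantification, differential calling and gene-exclusion filters.

Thresholds default to the study conventions: a gene is differentially
expressed when FDR < 0.05, fold change > 1.5 (two-sided) and average log2
CPM > 0.  Two filters remove genes whose signal cannot be attributed to the
myeloma cells themselves: the stromal-signature filter (top 1000
highest-expressed stromal genes that are silent in MM cells, RPKM < 2,
guarding against the <5% stromal carry-over in the CO condition) and the
closed-promoter filter (promoter not accessible in any of the three culture
conditions).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from stromareg.containers import CountMatrix
from stromareg.errors import StromaregError
from stromareg.nbdiff import bh_fdr, differential_test

__all__ = [
    "compute_cpm",
    "compute_rpkm",
    "differential_expression",
    "bh_fdr",
    "stromal_signature_filter",
    "promoter_open_filter",
    "make_rnk",
    "pca_embed",
    "zscore_rows",
]


def compute_cpm(cm: CountMatrix) -> pd.DataFrame:
    """Counts per million; every column sums to 10^6."""
    lib = cm.library_sizes()
    zero = lib[lib <= 0]
    if len(zero):
        raise StromaregError(f"zero library size for sample {zero.index[0]!r}")
    return cm.counts / lib * 1e6


def compute_rpkm(cm: CountMatrix) -> pd.DataFrame:
    """Reads per kilobase of model per million mapped reads."""
    if cm.lengths is None:
        raise StromaregError("feature lengths required for RPKM")
    bad = cm.lengths[~(cm.lengths > 0)]
    if len(bad):
        raise StromaregError(f"missing or non-positive length for feature {bad.index[0]!r}")
    lib = cm.library_sizes()
    zero = lib[lib <= 0]
    if len(zero):
        raise StromaregError(f"zero library size for sample {zero.index[0]!r}")
    kb = cm.lengths / 1e3
    return cm.counts.div(lib / 1e6, axis=1).div(kb, axis=0)


def differential_expression(cm: CountMatrix, baseline: str, comparison: str,
                            fdr: float = 0.05, fc: float = 1.5,
                            min_avg_log2cpm: float = 0.0) -> pd.DataFrame:
    """Differential genes, ``comparison`` over ``baseline`` (NB exact-style test)."""
    return differential_test(cm, baseline, comparison, fdr_threshold=fdr,
                             fc_threshold=fc, min_avg_log2cpm=min_avg_log2cpm)


def stromal_signature_filter(mm_rpkm: pd.DataFrame, stromal_rpkm: pd.Series,
                             top_n: int = 1000, silent_rpkm: float = 2.0) -> list[str]:
    """Genes to exclude as stromal signature.

    Excluded iff the gene ranks in the ``top_n`` highest-expressed stromal
    genes (descending; ties at the boundary all included) AND its maximum
    RPKM across MM samples is below ``silent_rpkm``.
    """
    if stromal_rpkm.empty:
        raise StromaregError("empty stromal expression vector")
    ranked = stromal_rpkm.sort_values(ascending=False)
    if len(ranked) > top_n:
        cutoff = ranked.iloc[top_n - 1]
        top = ranked[ranked >= cutoff].index
    else:
        top = ranked.index
    shared = mm_rpkm.index.intersection(top)
    silent = mm_rpkm.loc[shared].max(axis=1) < silent_rpkm
    return sorted(silent[silent].index)


def promoter_open_filter(open_status: pd.DataFrame,
                         conditions=("MONO", "TSW", "CO"),
                         require_closed_in_all: bool = True) -> list[str]:
    """Genes to exclude because their promoter chromatin is not open.

    ``open_status`` is a boolean gene-by-condition frame.  With the default
    reading a gene is excluded iff the promoter is closed in ALL listed
    conditions; ``require_closed_in_all=False`` switches to the stricter
    reading (excluded unless open in all conditions).
    """
    missing = [c for c in conditions if c not in open_status.columns]
    if missing:
        raise StromaregError(f"missing promoter status for conditions: {missing}")
    sub = open_status[list(conditions)].astype(bool)
    if require_closed_in_all:
        excl = ~sub.any(axis=1)
    else:
        excl = ~sub.all(axis=1)
    return sorted(excl[excl].index)


def make_rnk(results: pd.DataFrame, excluded: list[str] | None = None) -> pd.Series:
    """Two-column rnk records: gene then log2 fold change, sorted descending.

    ``results`` is a differential table indexed by gene with a ``log2fc``
    column; genes in ``excluded`` (stromal/promoter filters) are omitted.
    """
    if results.index.duplicated().any():
        dup = results.index[results.index.duplicated()][0]
        raise StromaregError(f"duplicate gene symbol in rnk input: {dup!r}")
    scores = results["log2fc"]
    if excluded:
        scores = scores.drop(index=[g for g in excluded if g in scores.index])
    # ties broken by gene id for determinism
    order = sorted(scores.index, key=lambda g: (-scores[g], g))
    return scores.loc[order]


def pca_embed(matrix: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """Centered-SVD sample coordinates from a feature-by-sample matrix."""
    x = matrix.to_numpy(dtype=float).T  # samples x features
    n = x.shape[0]
    if n < 2:
        raise StromaregError("PCA needs >=2 samples")
    if n_components > n:
        raise StromaregError(f"cannot extract {n_components} components from {n} samples")
    xc = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    coords = u[:, :n_components] * s[:n_components]
    return pd.DataFrame(coords, index=matrix.columns,
                        columns=[f"PC{i+1}" for i in range(n_components)])


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-scores (sample SD, ddof=1); constant rows map to all zeros."""
    x = matrix.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (x - mean) / sd, 0.0)
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
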