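"""Chromatin-accessibility analysis: reference peaks, counts, differential calls.

Reference peaks follow the "present in at least three samples" rule,
realised as a per-base support sweep: a base belongs to the reference when
calls from >= ``min_support`` distinct samples cover it, and maximal such
runs become reference peaks.  Reads are assigned to peaks by the midpoint
rule so each read is counted at most once.  Differential accessibility is
available through the shared NB exact-style test (FC > 1.5, FDR < 0.01) and
through a GFOLD-style posterior fold-change bound (|value| > 0.585, i.e. a
credible fold change of 1.5).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from stromareg.containers import CountMatrix
from stromareg.errors import StromaregError
from stromareg.nbdiff import differential_test

logger = logging.getLogger(__name__)

GFOLD_CUTOFF = round(float(np.log2(1.5)), 3)  # 0.585, credible FC of 1.5

__all__ = [
    "GFOLD_CUTOFF",
    "compile_reference_peaks",
    "count_reads_in_peaks",
    "differential_peaks",
    "gfold_value",
    "gfold_table",
    "classify_promoter_distal",
    "summit_windows",
]


def _validate_peaks(df: pd.DataFrame, origin: str = "peaks"):
    bad = df.index[df["start"].to_numpy() >= df["end"].to_numpy()]
    if len(bad):
        raise StromaregError(f"{origin}: start >= end at row {bad[0]}")


def _sample_coverage_events(df: pd.DataFrame):
    """Per-chromosome +1/-1 events of a sample's union coverage."""
    out = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        iv = grp[["start", "end"]].sort_values("start").to_numpy()
        merged = []
        for s, e in iv:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = merged
    return out


def compile_reference_peaks(per_sample_peaks: list[pd.DataFrame],
                            min_support: int = 3) -> pd.DataFrame:
    """Compile the consensus reference peak set from per-sample calls.

    Returns a frame with columns ``chrom,start,end,name,support,summit``
    (summit = 0-based offset from start).  Support of a retained peak is the
    number of distinct samples with >=1 overlapping call; the consensus
    summit is the (lower) median of contributing call summits that fall
    inside the peak, or the midpoint if none do.
    """
    if len(per_sample_peaks) < min_support:
        raise StromaregError(
            f"need >= {min_support} samples to require support {min_support}")
    for i, df in enumerate(per_sample_peaks):
        _validate_peaks(df, origin=f"sample {i}")

    cov = [_sample_coverage_events(df) for df in per_sample_peaks]
    chroms = sorted({c for m in cov for c in m})
    rows = []
    for chrom in chroms:
        events = []
        for m in cov:
            for s, e in m.get(chrom, []):
                events.append((s, 1))
                events.append((e, -1))
        events.sort()
        pos = np.array([p for p, _ in events])
        delta = np.array([d for _, d in events])
        # support level on [pos[i], pos[i+1])
        uniq, idx = np.unique(pos, return_index=True)
        lev = np.add.reduceat(delta, idx).cumsum()
        open_start = None
        for i, p in enumerate(uniq):
            level = lev[i]
            if level >= min_support and open_start is None:
                open_start = p
            elif level < min_support and open_start is not None:
                rows.append((chrom, int(open_start), int(p)))
                open_start = None
        if open_start is not None:  # pragma: no cover - events always close
            rows.append((chrom, int(open_start), int(uniq[-1])))

    ref = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    supports, summits = [], []
    for chrom, start, end in ref.itertuples(index=False):
        n_sup = 0
        cand = []
        for df in per_sample_peaks:
            sub = df[(df["chrom"] == chrom) & (df["start"] < end) & (df["end"] > start)]
            if len(sub):
                n_sup += 1
                if "summit" in sub.columns:
                    sm = sub["start"].to_numpy() + sub["summit"].to_numpy()
                    sm = sm[(sub["summit"].to_numpy() >= 0) & (sm >= start) & (sm < end)]
                    cand.extend(sm.tolist())
        supports.append(n_sup)
        if cand:
            cand.sort()
            summit_abs = int(cand[(len(cand) - 1) // 2])
        else:
            summit_abs = (start + end) // 2
        summits.append(summit_abs - start)
    ref["name"] = [f"refpeak_{i:05d}" for i in range(len(ref))]
    ref["support"] = supports
    ref["summit"] = summits
    return ref[["chrom", "start", "end", "name", "support", "summit"]]


def count_reads_in_peaks(reads_per_sample: dict[str, pd.DataFrame],
                         peaks: pd.DataFrame,
                         conditions: pd.Series | None = None) -> CountMatrix:
    """Count reads whose midpoint falls inside each reference peak.

    ``reads_per_sample`` maps sample id to a BED-like frame
    (chrom/start/end).  Reads on chromosomes absent from the peak set are
    skipped with a logged warning.
    """
    from stromareg.containers import conditions_from_sample_names

    by_chrom = {}
    for chrom, grp in peaks.groupby("chrom", sort=False):
        g = grp.sort_values("start")
        by_chrom[chrom] = (g["start"].to_numpy(), g["end"].to_numpy(),
                           g.index.to_numpy())
    mat = {}
    for sample, reads in reads_per_sample.items():
        col = np.zeros(len(peaks), dtype=int)
        skipped = 0
        for chrom, grp in reads.groupby("chrom", sort=False):
            if chrom not in by_chrom:
                skipped += len(grp)
                continue
            starts, ends, rowidx = by_chrom[chrom]
            mids = (grp["start"].to_numpy() + grp["end"].to_numpy()) // 2
            j = np.searchsorted(starts, mids, side="right") - 1
            ok = (j >= 0) & (mids < ends[np.clip(j, 0, len(ends) - 1)])
            hit_rows = rowidx[j[ok]]
            np.add.at(col, peaks.index.get_indexer(hit_rows), 1)
        if skipped:
            logger.warning("sample %s: %d reads on chromosomes absent from the "
                           "peak set were skipped", sample, skipped)
        mat[sample] = col
    counts = pd.DataFrame(mat, index=peaks["name"].to_numpy())
    if conditions is None:
        conditions = conditions_from_sample_names(counts.columns)
    return CountMatrix(counts, conditions)


def differential_peaks(cm: CountMatrix, baseline: str, comparison: str,
                       fdr: float = 0.01, fc: float = 1.5) -> pd.DataFrame:
    """Differential accessibility calls (no CPM floor, stricter FDR than expression)."""
    return differential_test(cm, baseline, comparison, fdr_threshold=fdr,
                             fc_threshold=fc, min_avg_log2cpm=None)


def gfold_value(counts_a, counts_b, libsizes_a, libsizes_b,
                credibility: float = 0.99) -> float:
    """GFOLD-style posterior log2 fold-change bound for group B over group A.

    Each group's normalised rate carries a Gamma posterior under a
    Gamma-Poisson model with a Jeffreys prior (shape sum(y)+0.5, rate
    sum(L)).  The ratio of the two independent Gamma rates is a scaled
    beta-prime variable, so the equal-tailed credible interval of
    log2(rateB/rateA) is computed analytically.  The returned value is the
    interval bound nearest zero, or 0 when the interval spans zero; the
    peak is called differential when |value| > 0.585 (= log2 1.5).
    """
    ya = np.asarray(counts_a, dtype=float)
    yb = np.asarray(counts_b, dtype=float)
    if ya.size == 0 or yb.size == 0:
        raise StromaregError("empty group in gfold_value")
    la = float(np.sum(libsizes_a))
    lb = float(np.sum(libsizes_b))
    aa, ab = ya.sum() + 0.5, yb.sum() + 0.5
    # rateB/rateA = (la/lb) * BetaPrime(ab, aa)
    alpha = (1.0 - credibility) / 2.0
    scale = la / lb
    lo = np.log2(stats.betaprime.ppf(alpha, ab, aa) * scale)
    hi = np.log2(stats.betaprime.ppf(1.0 - alpha, ab, aa) * scale)
    if lo > 0:
        return float(lo)
    if hi < 0:
        return float(hi)
    return 0.0


def gfold_table(cm: CountMatrix, baseline: str, comparison: str,
                credibility: float = 0.99) -> pd.Series:
    """Per-feature GFOLD values for ``comparison`` over ``baseline``."""
    sa = cm.samples_of(baseline)
    sb = cm.samples_of(comparison)
    la = cm.counts[sa].sum(axis=0).to_numpy()
    lb = cm.counts[sb].sum(axis=0).to_numpy()
    vals = [gfold_value(row[sa].to_numpy(), row[sb].to_numpy(), la, lb,
                        credibility=credibility)
            for _, row in cm.counts.iterrows()]
    return pd.Series(vals, index=cm.features, name="gfold")


def classify_promoter_distal(peaks: pd.DataFrame, gene_models: pd.DataFrame,
                             window: int = 2500,
                             chrom_sizes: dict[str, int] | None = None) -> pd.Series:
    """Label each peak ``promoter`` or ``distal``.

    The promoter window is TSS +/- ``window`` bp, closed on both ends in
    1-based terms, i.e. the 0-based half-open interval
    [TSS-window, TSS+window+1); a peak is a promoter peak iff it overlaps
    any window by >= 1 bp.
    """
    if chrom_sizes:
        for g in gene_models.itertuples():
            size = chrom_sizes.get(g.chrom)
            if size is not None and not (0 <= g.tss < size):
                raise StromaregError(f"TSS of {g.gene_id} outside chromosome bounds")
    win_by_chrom = {}
    for chrom, grp in gene_models.groupby("chrom", sort=False):
        tss = np.sort(grp["tss"].to_numpy())
        ws = np.maximum(tss - window, 0)
        we = tss + window + 1
        merged_s, merged_e = [], []
        for s, e in zip(ws, we):
            if merged_s and s <= merged_e[-1]:
                merged_e[-1] = max(merged_e[-1], e)
            else:
                merged_s.append(s)
                merged_e.append(e)
        win_by_chrom[chrom] = (np.array(merged_s), np.array(merged_e))
    labels = []
    for p in peaks.itertuples():
        ws, we = win_by_chrom.get(p.chrom, (np.array([]), np.array([])))
        if len(ws):
            i = np.searchsorted(ws, p.end, side="left")
            j = np.searchsorted(we, p.start, side="right")
            overlap = j < i
        else:
            overlap = False
        labels.append("promoter" if overlap else "distal")
    return pd.Series(labels, index=peaks["name"].to_numpy(), name="class")


def summit_windows(peaks: pd.DataFrame, half_width: int = 50,
                   chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """Summit +/- ``half_width`` windows (101 bp by default), clipped at ends."""
    if "summit" not in peaks.columns or (peaks["summit"].to_numpy() < 0).any():
        raise StromaregError("summit offsets required for summit windows")
    summit_abs = peaks["start"].to_numpy() + peaks["summit"].to_numpy()
    start = summit_abs - half_width
    end = summit_abs + half_width + 1
    clipped = start < 0
    if chrom_sizes:
        sizes = peaks["chrom"].map(chrom_sizes).to_numpy()
        clipped |= end > sizes
        end = np.minimum(end, sizes)
    if clipped.any():
        logger.warning("%d summit windows clipped at chromosome bounds",
                       int(clipped.sum()))
    start = np.maximum(start, 0)
    return pd.DataFrame({"chrom": peaks["chrom"].to_numpy(), "start": start,
                         "end": end, "name": peaks["name"].to_numpy()})
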