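"""GREAT-style peak-to-gene assignment and the multi-peak gene rule.

Each gene receives a basal regulatory domain (5 kb upstream / 1 kb
downstream of the TSS, strand-aware) extended in both directions up to 1 Mb
from the TSS but stopping at the nearest neighbouring basal domain; basal
domains are never truncated, so extended domains of neighbouring genes
share the inter-basal region.  A peak targets every gene whose extended
domain it overlaps by >= 1 bp.  The multi-peak rule retains genes that are
expressed and associated with more than two distinct peaks gaining
accessibility.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from stromareg.errors import StromaregError

__all__ = ["assign_regulatory_domains", "peaks_to_targets", "multi_peak_genes"]


def assign_regulatory_domains(gene_models: pd.DataFrame,
                              basal_up: int = 5000, basal_down: int = 1000,
                              max_ext: int = 1_000_000,
                              chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """Basal-plus-extension regulatory domains.

    ``gene_models`` needs columns ``gene_id, chrom, strand, tss``.  Returns a
    frame with ``gene_id, chrom, basal_start, basal_end, ext_start, ext_end``
    (0-based half-open).
    """
    if gene_models["gene_id"].duplicated().any():
        dup = gene_models.loc[gene_models["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise StromaregError(f"duplicate gene id: {dup!r}")
    out = []
    for chrom, grp in gene_models.groupby("chrom", sort=False):
        g = grp.sort_values(["tss", "gene_id"]).reset_index(drop=True)
        tss = g["tss"].to_numpy()
        plus = (g["strand"] == "+").to_numpy()
        bstart = np.where(plus, tss - basal_up, tss - basal_down)
        bend = np.where(plus, tss + basal_down, tss + basal_up)
        bstart = np.maximum(bstart, 0)
        size = (chrom_sizes or {}).get(chrom)
        if size is not None:
            bend = np.minimum(bend, size)
        n = len(g)
        # running max of basal ends to the left / running min of basal starts right
        left_limit = np.zeros(n, dtype=np.int64)
        running = 0
        for i in range(n):
            left_limit[i] = running
            running = max(running, int(bend[i]))
        right_limit = np.full(n, size if size is not None else np.iinfo(np.int64).max,
                              dtype=np.int64)
        running = right_limit[0]
        for i in range(n - 1, -1, -1):
            right_limit[i] = running
            running = min(running, int(bstart[i]))
        ext_start = np.minimum(bstart, np.maximum(tss - max_ext, left_limit))
        ext_start = np.maximum(ext_start, 0)
        ext_end = np.maximum(bend, np.minimum(tss + max_ext, right_limit))
        if size is not None:
            ext_end = np.minimum(ext_end, size)
        for i in range(n):
            out.append((g["gene_id"].iloc[i], chrom, int(bstart[i]), int(bend[i]),
                        int(ext_start[i]), int(ext_end[i])))
    return pd.DataFrame(out, columns=["gene_id", "chrom", "basal_start",
                                      "basal_end", "ext_start", "ext_end"])


def peaks_to_targets(peaks: pd.DataFrame, domains: pd.DataFrame) -> pd.DataFrame:
    """Peak-gene association table (one row per overlapping peak/domain pair)."""
    rows = []
    for chrom, dgrp in domains.groupby("chrom", sort=False):
        pgrp = peaks[peaks["chrom"] == chrom]
        if pgrp.empty:
            continue
        d = dgrp.sort_values("ext_start")
        dstart = d["ext_start"].to_numpy()
        dend = d["ext_end"].to_numpy()
        dgene = d["gene_id"].to_numpy()
        for p in pgrp.itertuples():
            # overlap iff ext_start < p.end and ext_end > p.start
            cand = np.searchsorted(dstart, p.end, side="left")
            for k in range(cand):
                if dend[k] > p.start:
                    rows.append((p.name, dgene[k]))
    return pd.DataFrame(rows, columns=["peak", "gene_id"])


def multi_peak_genes(associations: pd.DataFrame, increasing_peaks: list[str],
                     expressed_genes: list[str], min_peaks: int = 3,
                     distal_peaks: list[str] | None = None) -> list[str]:
    """Expressed genes associated with > 2 distinct accessibility-gaining peaks.

    ``distal_peaks``, when given, restricts the gaining peaks considered to
    the distal class.
    """
    if len(expressed_genes) == 0:
        raise StromaregError("empty expressed-gene set")
    inc = set(increasing_peaks)
    if distal_peaks is not None:
        inc &= set(distal_peaks)
    sub = associations[associations["peak"].isin(inc)]
    counts = sub.drop_duplicates(["peak", "gene_id"]).groupby("gene_id").size()
    expressed = set(expressed_genes)
    return sorted(g for g, c in counts.items() if c >= min_peaks and g in expressed)
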