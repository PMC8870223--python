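"""Gene-list and ranking statistics: preranked GSEA, hypergeometric set
enrichment, K-S expression-shift tests and contingency concordance."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from stromareg.containers import substream
from stromareg.errors import StromaregError

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "gsea_preranked",
    "gsea_collection",
    "hypergeom_enrichment",
    "ks_shift_test",
    "contingency_concordance",
]


@dataclass
class GeneSet:
    name: str
    members: list[str]
    description: str = ""

    def __post_init__(self):
        if not self.members:
            raise StromaregError(f"gene set {self.name!r} is empty")
        seen = set()
        uniq = []
        for m in self.members:
            if m not in seen:
                seen.add(m)
                uniq.append(m)
        self.members = uniq


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    pvalue: float
    fdr_q: float = float("nan")
    leading_edge: list[str] = field(default_factory=list)
    null_es: np.ndarray | None = None


def _es_from_positions(positions: np.ndarray, hit_w: np.ndarray, n: int):
    """Signed maximal running-sum deviation for hit positions in a ranked list.

    ``positions`` are sorted 0-based ranks of the set members; ``hit_w`` the
    corresponding |score|^weight increments.  Returns (ES, index of the rank
    at which the extremum is attained, hit order index of the extremum).
    """
    k = len(positions)
    wsum = hit_w.sum()
    if wsum == 0:
        hit_cum = np.arange(1, k + 1) / k  # all-zero scores: uniform hit steps
    else:
        hit_cum = np.cumsum(hit_w) / wsum
    miss = 1.0 / (n - k)
    # running value just after each hit, and just before each hit
    after = hit_cum - (positions + 1 - np.arange(1, k + 1)) * miss
    before = np.concatenate(([0.0], hit_cum[:-1])) - (positions - np.arange(k)) * miss
    i_max = int(np.argmax(after))
    i_min = int(np.argmin(before))
    if after[i_max] >= -before[i_min]:
        return float(after[i_max]), i_max
    return float(before[i_min]), i_min


def gsea_preranked(rnk: pd.Series, geneset: GeneSet, weight: float = 1.0,
                   n_perm: int = 1000, seed: int = 0) -> EnrichmentResult:
    """Classic weighted-KS preranked enrichment of a gene set in a ranking.

    ``rnk`` maps gene -> score.  The running sum increments by
    |score|^weight (normalised) at members and decrements uniformly at
    non-members; ES is the signed maximal deviation.  The null is a
    gene-label permutation; NES = ES / mean |null ES of matching sign| and
    the nominal p is the sign-matched null tail (with an add-one guard).
    """
    if not np.all(np.isfinite(rnk.to_numpy(dtype=float))):
        raise StromaregError("rnk scores must be finite")
    # deterministic ordering: descending score, ties by gene id
    order = sorted(rnk.index, key=lambda g: (-rnk[g], str(g)))
    scores = rnk.loc[order].to_numpy(dtype=float)
    genes = pd.Index(order)
    member_mask = genes.isin(geneset.members)
    k = int(member_mask.sum())
    n = len(genes)
    if k == 0:
        raise StromaregError(f"gene set {geneset.name!r} has no overlap with the ranking")
    if k == n:
        raise StromaregError("gene set covers the whole ranking")
    if n_perm < 100:
        import warnings

        warnings.warn("n_perm < 100 gives unstable GSEA p-values", stacklevel=2)

    absw = np.abs(scores) ** weight
    positions = np.flatnonzero(member_mask)
    es, i_ext = _es_from_positions(positions, absw[positions], n)
    if es >= 0:
        leading = genes[positions[: i_ext + 1]].tolist()
    else:
        leading = genes[positions[i_ext:]].tolist()

    rng = substream(seed, f"gsea:{geneset.name}")
    null_es = np.empty(n_perm)
    for b in range(n_perm):
        pos = np.sort(rng.choice(n, size=k, replace=False))
        null_es[b], _ = _es_from_positions(pos, absw[pos], n)
    same = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
    if len(same) == 0:
        nes = np.sign(es) * np.inf if es != 0 else 0.0
        p = 1.0 / (n_perm + 1)
    else:
        denom = np.mean(np.abs(same))
        nes = es / denom if denom > 0 else 0.0
        p = (1 + np.sum(np.abs(same) >= abs(es))) / (1 + len(same))
    return EnrichmentResult(geneset.name, es, float(nes), float(p),
                            leading_edge=leading, null_es=null_es)


def gsea_collection(rnk: pd.Series, genesets: list[GeneSet], weight: float = 1.0,
                    n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Run preranked GSEA over a collection and attach sign-matched FDR q."""
    results = [gsea_preranked(rnk, gs, weight=weight, n_perm=n_perm, seed=seed)
               for gs in genesets]
    # pooled-null NES FDR of the original recipe, sign-matched
    null_nes = []
    obs_nes = np.array([r.nes for r in results])
    for r in results:
        same = r.null_es[np.sign(r.null_es) == np.sign(r.es)] if r.es != 0 else r.null_es
        denom = np.mean(np.abs(same)) if len(same) else 1.0
        null_nes.append(r.null_es / denom if denom > 0 else r.null_es)
    pooled = np.concatenate(null_nes) if null_nes else np.array([])
    for r in results:
        if r.nes == 0 or not np.isfinite(r.nes):
            r.fdr_q = 1.0 if r.nes == 0 else 0.0
            continue
        s = np.sign(r.nes)
        pool_same = pooled[np.sign(pooled) == s]
        obs_same = obs_nes[np.sign(obs_nes) == s]
        num = np.mean(np.abs(pool_same) >= abs(r.nes)) if len(pool_same) else 0.0
        den = np.mean(np.abs(obs_same) >= abs(r.nes)) if len(obs_same) else 1.0
        r.fdr_q = float(min(1.0, num / den)) if den > 0 else 0.0
    return pd.DataFrame(
        {"set": [r.set_name for r in results], "es": [r.es for r in results],
         "nes": [r.nes for r in results], "pvalue": [r.pvalue for r in results],
         "fdr_q": [r.fdr_q for r in results],
         "leading_edge": [",".join(r.leading_edge) for r in results]}
    ).set_index("set")


def hypergeom_enrichment(hits: int, list_size: int, set_size: int,
                         universe: int) -> tuple[float, float]:
    """Upper-tail hypergeometric overlap p and observed/expected ratio."""
    if not (0 <= hits <= min(list_size, set_size) <= universe):
        raise StromaregError("inconsistent overlap counts")
    expected = list_size * set_size / universe if universe else 0.0
    ratio = hits / expected if expected > 0 else 0.0
    p = float(stats.hypergeom.sf(hits - 1, universe, set_size, list_size))
    return min(p, 1.0), ratio


def _ks_d_stat(a: np.ndarray, b: np.ndarray) -> float:
    pts = np.concatenate([a, b])
    fa = np.searchsorted(np.sort(a), pts, side="right") / len(a)
    fb = np.searchsorted(np.sort(b), pts, side="right") / len(b)
    return float(np.max(np.abs(fa - fb)))


def _ks_exact_enumeration(a: np.ndarray, b: np.ndarray) -> float:
    import itertools

    pooled = np.concatenate([a, b])
    n = len(a)
    d_obs = _ks_d_stat(a, b)
    count = total = 0
    idx_all = range(len(pooled))
    for idx in itertools.combinations(idx_all, n):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        total += 1
        if _ks_d_stat(pooled[mask], pooled[~mask]) >= d_obs - 1e-12:
            count += 1
    return count / total


def ks_shift_test(group_a, group_b) -> tuple[float, float]:
    """Two-sample K-S D and p; exact p when n*m <= 30, else asymptotic.

    The exact mode uses scipy's path-counting algorithm and falls back to
    direct enumeration of all label assignments when that fails (it can for
    small D or ties).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StromaregError("each group needs n >= 2 for the K-S test")
    exact = len(a) * len(b) <= 30
    if exact:
        import warnings

        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = stats.ks_2samp(a, b, method="exact")
        if any("unsuccessful" in str(w.message) for w in caught):
            return _ks_d_stat(a, b), _ks_exact_enumeration(a, b)
        return float(res.statistic), float(res.pvalue)
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def contingency_concordance(calls_a: pd.Series, calls_b: pd.Series) -> dict:
    """Fold-over-expected concordance of two up/down/unchanged call vectors.

    Observed = genes called in the same direction in both comparisons;
    expected under independence from the margins = (upA*upB + downA*downB)/N.
    Significance comes from Fisher's exact test on the 2x2 collapse of
    consistent co-calls vs the changed margins.
    """
    shared = calls_a.index.intersection(calls_b.index)
    if len(shared) == 0:
        raise StromaregError("call vectors share no genes")
    a = calls_a.loc[shared]
    b = calls_b.loc[shared]
    n = len(shared)
    up_a, down_a = int((a == "up").sum()), int((a == "down").sum())
    up_b, down_b = int((b == "up").sum()), int((b == "down").sum())
    observed = int(((a == "up") & (b == "up")).sum()
                   + ((a == "down") & (b == "down")).sum())
    expected = (up_a * up_b + down_a * down_b) / n
    ratio = observed / expected if expected > 0 else float("inf") if observed else 0.0
    ch_a, ch_b = up_a + down_a, up_b + down_b
    table = [[observed, ch_a - observed],
             [ch_b - observed, n - ch_a - ch_b + observed]]
    table = [[max(v, 0) for v in row] for row in table]
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return {"observed": observed, "expected": expected, "ratio": ratio, "pvalue": p}
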