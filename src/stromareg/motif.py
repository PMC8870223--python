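"""PWM motif scanning in summit windows and foreground/background enrichment.

The scanner follows the FIMO approach: a position weight matrix is turned
into a log-odds matrix against a background distribution, the null
distribution of scores of random background k-mers is computed exactly (by
enumeration for short motifs, by dynamic programming over discretised
scores otherwise), and every window position on both strands whose score
reaches p <= threshold is reported.  Enrichment compares the fraction of
foreground windows (differentially gaining peaks) containing >= 1 hit with
the fraction in background windows (peaks not differentially accessible)
by Fisher's exact test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from stromareg.errors import StromaregError

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_COMP = {0: 3, 1: 2, 2: 1, 3: 0}

__all__ = ["MotifModel", "ScoreDistribution", "scan_sequences", "motif_enrichment"]


@dataclass
class MotifModel:
    """Nucleotide probability matrix with background and log-odds form."""

    name: str
    matrix: np.ndarray  # width x 4, columns A C G T, rows sum to 1
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.1

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise StromaregError("motif matrix must be width x 4")
        if self.width < 4:
            raise StromaregError("motif width must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-3):
            raise StromaregError("motif probability rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise StromaregError("background frequencies must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def probs(self) -> np.ndarray:
        """Pseudocounted probabilities, renormalised per position."""
        p = self.matrix + self.pseudocount
        return p / p.sum(axis=1, keepdims=True)

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probs / self.background[None, :])

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "MotifModel":
        rc = self.matrix[::-1, ::-1].copy()
        bg = self.background[::-1].copy()
        return MotifModel(self.name + "_rc", rc, background=bg,
                          pseudocount=self.pseudocount)


class ScoreDistribution:
    """Null distribution of log-odds scores of random background k-mers.

    ``p(s) = P(score >= s)`` for a k-mer drawn i.i.d. from the motif's
    background.  Short motifs (4^w <= 4096) are enumerated exactly; longer
    ones use dynamic programming over scores discretised to ``resolution``
    bins across the total score range, which yields a conservative
    (slightly larger) p for any observed score.
    """

    def __init__(self, motif: MotifModel, resolution: int = 1000, method: str = "auto"):
        if resolution < 100:
            warnings.warn("score-distribution resolution < 100 is coarse", stacklevel=2)
        lom = motif.log_odds
        w = motif.width
        bg = motif.background
        if method == "auto":
            method = "exact" if 4 ** w <= 4096 else "dp"
        self.method = method
        if method == "exact":
            scores = np.zeros(1)
            probs = np.ones(1)
            for j in range(w):
                scores = (scores[:, None] + lom[j][None, :]).ravel()
                probs = (probs[:, None] * bg[None, :]).ravel()
            order = np.argsort(scores)[::-1]
            self._scores = scores[order]
            self._tail = np.cumsum(probs[order])
        else:
            col_min = lom.min(axis=1)
            col_max = lom.max(axis=1)
            total_range = float((col_max - col_min).sum())
            scale = resolution / total_range if total_range > 0 else 1.0
            self._offset = float(col_min.sum())
            self._scale = scale
            q = np.round((lom - col_min[:, None]) * scale).astype(int)
            pmf = np.zeros(1)
            pmf[0] = 1.0
            for j in range(w):
                width_j = q[j].max()
                new = np.zeros(len(pmf) + width_j)
                for letter in range(4):
                    new[q[j, letter]: q[j, letter] + len(pmf)] += bg[letter] * pmf
                pmf = new
            tail = np.cumsum(pmf[::-1])[::-1]
            self._tail_bins = np.minimum(tail, 1.0)

    def pvalue(self, score) -> np.ndarray:
        s = np.atleast_1d(np.asarray(score, dtype=float))
        if self.method == "exact":
            # first index with stored score < s  ->  tail at previous index
            idx = np.searchsorted(-self._scores, -(s - 1e-9), side="right") - 1
            out = np.where(idx >= 0, self._tail[np.clip(idx, 0, len(self._tail) - 1)], 0.0)
        else:
            bins = np.floor((s - self._offset) * self._scale).astype(int)
            bins = np.clip(bins, 0, len(self._tail_bins) - 1)
            out = self._tail_bins[bins]
            out = np.where(s > self._offset + (len(self._tail_bins) - 1) / self._scale,
                           0.0, out)
        out = np.asarray(out, dtype=float)
        return out if np.ndim(score) else float(out[0])

    def score_threshold(self, p_threshold: float) -> float:
        """Smallest score whose p-value is <= ``p_threshold``."""
        if self.method == "exact":
            ok = self._tail <= p_threshold
            if not ok.any():
                return np.inf
            return float(self._scores[np.flatnonzero(ok)[-1]])
        ok = self._tail_bins <= p_threshold
        if not ok.any():
            return np.inf
        b = int(np.flatnonzero(ok)[0])
        return self._offset + b / self._scale


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    code = np.full(arr.shape, -1, dtype=np.int8)
    for i, base in enumerate(ALPHABET):
        code[arr == ord(base)] = i
    bad = (code < 0) & (arr != ord("N"))
    if bad.any():
        raise StromaregError(f"sequence contains letters outside ACGTN")
    return code


def _strand_scores(code: np.ndarray, lom: np.ndarray) -> np.ndarray:
    w = len(lom)
    n_off = len(code) - w + 1
    if n_off <= 0:
        return np.empty(0)
    scores = np.zeros(n_off)
    valid = np.ones(n_off, dtype=bool)
    for j in range(w):
        letters = code[j: j + n_off]
        ok = letters >= 0
        valid &= ok
        scores += np.where(ok, lom[j, np.clip(letters, 0, 3)], 0.0)
    scores[~valid] = -np.inf  # offsets containing N are skipped
    return scores


def scan_sequences(sequences: dict[str, str], motif: MotifModel,
                   p_threshold: float = 1e-4, both_strands: bool = True,
                   distribution: ScoreDistribution | None = None) -> pd.DataFrame:
    """All motif hits with p <= threshold across the given sequences.

    Returns a frame with columns ``sequence, offset, strand, score, pvalue``
    (offset relative to the forward sequence).
    """
    dist = distribution or ScoreDistribution(motif)
    lom_f = motif.log_odds
    lom_r = motif.reverse_complement().log_odds
    rows = []
    for name, seq in sequences.items():
        if len(seq) < motif.width:
            logger.info("sequence %s shorter than motif width; skipped", name)
            continue
        code = _encode(seq)
        strands = [("+", lom_f)] + ([("-", lom_r)] if both_strands else [])
        for strand, lom in strands:
            scores = _strand_scores(code, lom)
            if scores.size == 0:
                continue
            pvals = dist.pvalue(scores)
            hit = np.isfinite(scores) & (pvals <= p_threshold)
            for off in np.flatnonzero(hit):
                rows.append((name, int(off), strand, float(scores[off]),
                             float(pvals[off])))
    return pd.DataFrame(rows, columns=["sequence", "offset", "strand",
                                       "score", "pvalue"])


def motif_enrichment(fg_windows: dict[str, str], bg_windows: dict[str, str],
                     motif: MotifModel, p_threshold: float = 1e-4,
                     both_strands: bool = True) -> dict:
    """Fraction of windows containing the motif, foreground vs background.

    The intended background is the summit windows of peaks that are not
    differentially accessible.  A window "contains" the motif iff it has
    >= 1 hit at p <= threshold; the 2x2 containment table is tested by
    Fisher's exact test.
    """
    if not fg_windows or not bg_windows:
        raise StromaregError("foreground and background window sets must be non-empty")
    dist = ScoreDistribution(motif)
    fg_hits = scan_sequences(fg_windows, motif, p_threshold, both_strands, dist)
    bg_hits = scan_sequences(bg_windows, motif, p_threshold, both_strands, dist)
    fg_with = fg_hits["sequence"].nunique()
    bg_with = bg_hits["sequence"].nunique()
    n_fg, n_bg = len(fg_windows), len(bg_windows)
    table = [[fg_with, n_fg - fg_with], [bg_with, n_bg - bg_with]]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return {
        "fraction_fg": fg_with / n_fg,
        "fraction_bg": bg_with / n_bg,
        "n_fg": n_fg,
        "n_bg": n_bg,
        "odds_ratio": float(odds),
        "pvalue": float(p),
    }
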