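"""Top-quartile prognostic-marker screen.

For each gene and cohort, patients are split into the top 25% and the rest
by expression; the split is evaluated with a log-rank test and a
single-covariate Cox proportional-hazards model (Breslow ties by default,
Efron optional).  A cohort supports a gene as an unfavorable marker when
p < 0.05 and HR > 1, and the gene is called a marker when the primary
cohort and at least one other cohort support it.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from stromareg.errors import DegenerateDataError, StromaregError

logger = logging.getLogger(__name__)

__all__ = [
    "top_quartile_split",
    "km_curve",
    "logrank_test",
    "cox_hr_binary",
    "screen_gene",
    "marker_call",
    "survival_screen",
]


def top_quartile_split(cohort: pd.DataFrame, expression_col: str = "expression") -> pd.Series:
    """Label ceil(0.25 n) patients ``top25`` by descending expression, rest ``rest``.

    Boundary ties are broken by patient id for determinism; a warning is
    logged when the expression values are all equal.
    """
    n = len(cohort)
    if n < 8:
        raise StromaregError(f"cohort of {n} patients is too small for a quartile split")
    expr = cohort[expression_col]
    if expr.nunique() == 1:
        logger.warning("all expression values equal; top-quartile split is id-ordered")
    k = int(np.ceil(0.25 * n))
    order = sorted(cohort.index, key=lambda pid: (-expr[pid], str(pid)))
    labels = pd.Series("rest", index=cohort.index, name="group")
    labels.loc[order[:k]] = "top25"
    return labels


def km_curve(time, event) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate; censored times do not drop the curve."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.size == 0:
        raise StromaregError("no records for the KM estimate")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(),
                         "survival": sf.iloc[:, 0].to_numpy()})


def logrank_test(time_a, event_a, time_b, event_b) -> tuple[float, float]:
    """Standard two-group log-rank chi-square statistic and p (1 df)."""
    ea = np.asarray(event_a, dtype=int)
    eb = np.asarray(event_b, dtype=int)
    if ea.sum() + eb.sum() == 0:
        raise DegenerateDataError("log-rank test with zero observed events")
    res = _ll_logrank(np.asarray(time_a, float), np.asarray(time_b, float),
                      event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def _breslow_score(beta, t, e, x):
    """Log partial likelihood derivative terms (Breslow ties) for binary x."""
    order = np.argsort(-t, kind="stable")  # decreasing time
    t, e, x = t[order], e[order], x[order]
    eta = np.exp(beta * x)
    s0 = np.cumsum(eta)
    s1 = np.cumsum(eta * x)
    s2 = s1  # x binary: x^2 = x
    # events grouped by time share the risk set at that time (Breslow)
    u = 0.0
    info = 0.0
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        # risk set = all with time >= t[i] -> indices 0..j-1 in this ordering
        d_idx = [k for k in range(i, j) if e[k] == 1]
        if d_idx:
            S0, S1, S2 = s0[j - 1], s1[j - 1], s2[j - 1]
            d = len(d_idx)
            u += sum(x[k] for k in d_idx) - d * S1 / S0
            info += d * (S2 / S0 - (S1 / S0) ** 2)
        i = j
    return u, info


def _efron_score(beta, t, e, x):
    order = np.argsort(-t, kind="stable")
    t, e, x = t[order], e[order], x[order]
    eta = np.exp(beta * x)
    s0 = np.cumsum(eta)
    s1 = np.cumsum(eta * x)
    u = 0.0
    info = 0.0
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d_idx = [k for k in range(i, j) if e[k] == 1]
        d = len(d_idx)
        if d:
            S0, S1 = s0[j - 1], s1[j - 1]
            t0 = sum(eta[k] for k in d_idx)
            t1 = sum(eta[k] * x[k] for k in d_idx)
            for r in range(d):
                f = r / d
                a0 = S0 - f * t0
                a1 = S1 - f * t1
                u += -a1 / a0
                info += (a1 / a0) * (1 - a1 / a0)
            u += sum(x[k] for k in d_idx)
        i = j
    return u, info


def cox_hr_binary(group_labels, time, event, positive_label="top25",
                  ties: str = "breslow", max_iter: int = 50,
                  tol: float = 1e-9) -> dict:
    """Single binary-covariate Cox model fitted by Newton iteration.

    Returns ``hr``, ``beta``, ``se``, ``ci`` (95% Wald) and an ``unbounded``
    flag raised when the partial likelihood is monotone (one group's events
    all precede the other's first event), in which case the HR estimate
    diverges and is reported as +/-inf with a warning.
    """
    x = np.asarray([1.0 if g == positive_label else 0.0 for g in group_labels])
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if e[x == 1].sum() == 0 or e[x == 0].sum() == 0:
        raise DegenerateDataError("both groups need >= 1 observed event for Cox")
    score = _breslow_score if ties == "breslow" else _efron_score
    beta = 0.0
    unbounded = False
    for _ in range(max_iter):
        u, info = score(beta, t, e, x)
        if info <= 0:
            unbounded = True
            break
        step = u / info
        beta += np.clip(step, -5, 5)
        if abs(beta) > 25:
            unbounded = True
            break
        if abs(step) < tol:
            break
    if unbounded:
        warnings.warn("monotone partial likelihood: hazard ratio unbounded", stacklevel=2)
        hr = np.inf if beta > 0 else 0.0
        return {"hr": hr, "beta": np.sign(beta) * np.inf, "se": np.inf,
                "ci": (0.0, np.inf), "unbounded": True}
    _, info = score(beta, t, e, x)
    se = 1.0 / np.sqrt(info)
    ci = (float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se)))
    return {"hr": float(np.exp(beta)), "beta": float(beta), "se": float(se),
            "ci": ci, "unbounded": False}


def screen_gene(cohort: pd.DataFrame, expression_col: str = "expression",
                ties: str = "breslow") -> dict:
    """Quartile split + log-rank + Cox for one gene in one cohort.

    ``cohort`` needs columns ``expression_col``, ``time`` and ``event`` and
    is indexed by patient id.
    """
    groups = top_quartile_split(cohort, expression_col=expression_col)
    top = groups == "top25"
    stat, p = logrank_test(cohort.loc[top, "time"], cohort.loc[top, "event"],
                           cohort.loc[~top, "time"], cohort.loc[~top, "event"])
    cox = cox_hr_binary(groups, cohort["time"], cohort["event"], ties=ties)
    return {"logrank_stat": stat, "pvalue": p, "hr": cox["hr"],
            "support": bool(p < 0.05 and cox["hr"] > 1.0)}


def marker_call(per_cohort_results: dict[str, dict], primary_cohort_id: str) -> dict:
    """Multi-cohort unfavorable-marker rule.

    Per-cohort support iff p < 0.05 and HR > 1; the gene is a marker iff the
    primary cohort supports it and at least one other cohort does too.
    """
    if primary_cohort_id not in per_cohort_results:
        raise StromaregError(f"primary cohort {primary_cohort_id!r} missing from results")
    support = {c: bool(r["pvalue"] < 0.05 and r["hr"] > 1.0)
               for c, r in per_cohort_results.items()}
    others = sum(v for c, v in support.items() if c != primary_cohort_id)
    return {"support": support,
            "marker": bool(support[primary_cohort_id] and others >= 1)}


def survival_screen(cohorts: dict[str, pd.DataFrame], genes: list[str],
                    primary_cohort_id: str, ties: str = "breslow") -> pd.DataFrame:
    """Run the marker screen for each gene over all cohorts.

    Each cohort frame is indexed by patient id with columns ``time``,
    ``event`` and one expression column per gene.
    """
    if primary_cohort_id not in cohorts:
        raise StromaregError(f"primary cohort {primary_cohort_id!r} not supplied")
    rows = []
    for gene in genes:
        per = {}
        for cname, cdf in cohorts.items():
            if gene not in cdf.columns:
                continue
            per[cname] = screen_gene(cdf[[gene, "time", "event"]].rename(
                columns={gene: "expression"}), ties=ties)
        call = marker_call(per, primary_cohort_id)
        row = {"gene_id": gene, "marker": call["marker"]}
        for cname, r in per.items():
            row[f"{cname}_p"] = r["pvalue"]
            row[f"{cname}_hr"] = r["hr"]
            row[f"{cname}_support"] = call["support"][cname]
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")
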