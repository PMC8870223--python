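"""Seeded synthetic data with the statistical structure of the coculture study.

The generator emulates a three-condition design (MONO, TSW, CO) on a toy
linear chromosome: negative-binomial RNA counts with planted fold changes
and a <5% stromal admixture in the CO columns, per-sample ATAC peak calls
drawn from a master peak set (so reference compilation is exercised) with
planted accessibility gains/losses and genes carrying >2 gaining distal
sites, summit-window sequences with PWM instances planted at different
rates in gaining vs background windows, and patient cohorts whose hazard
depends on top-quartile carrier status of planted marker genes.  Every
draw flows from a single seed through named substreams, and a truth table
records all planted effects for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from stromareg.containers import CountMatrix, substream
from stromareg.errors import StromaregError
from stromareg.motif import MotifModel, ALPHABET

__all__ = [
    "SimConfig",
    "TruthTable",
    "default_motif",
    "simulate_genome",
    "simulate_expression",
    "simulate_accessibility",
    "simulate_sequences",
    "simulate_cohorts",
    "simulate_all",
]

CONDITION_ORDER = ("MONO", "TSW", "CO")


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with the study-design defaults."""

    seed: int = 0
    # genome / genes
    chrom_name: str = "chr1"
    chrom_length: int = 20_000_000
    n_genes: int = 400
    # expression
    conditions: dict = field(default_factory=lambda: {"MONO": 3, "TSW": 3, "CO": 3})
    de_fraction: float = 0.10
    de_log2fc: float = 2.0
    adhesion_fraction: float = 0.05
    adhesion_log2fc: float = 1.5
    dispersion: float = 0.1
    contamination_fraction: float = 0.03
    base_mean: float = 100.0
    base_sigma: float = 1.2
    mm_silent_fraction: float = 0.05
    # accessibility
    n_peaks: int = 1200
    peak_width: int = 400
    peak_mean_reads: float = 60.0
    presence_prob: float = 0.95
    rare_peak_fraction: float = 0.03
    coord_jitter: int = 10
    read_length: int = 50
    acc_gain_fraction: float = 0.03
    acc_loss_fraction: float = 0.03
    acc_log2fc: float = 2.0
    multipeak_gene_count: int = 10
    promoter_open_fraction: float = 0.85
    promoter_induced_fraction: float = 0.05
    # motif windows
    motif_plant_rate_fg: float = 0.25
    motif_plant_rate_bg: float = 0.05
    # cohorts
    n_cohorts: int = 5
    cohort_size: int = 500
    censoring_rate: float = 0.2
    marker_hr: float = 2.0
    marker_gene_count: int = 10
    baseline_hazard: float = 0.1

    def __post_init__(self):
        if not (0 <= self.contamination_fraction < 0.05):
            raise StromaregError(
                "contamination_fraction must be < 0.05 (minimal stromal carry-over)")
        for name in ("de_fraction", "acc_gain_fraction", "acc_loss_fraction",
                     "motif_plant_rate_fg", "motif_plant_rate_bg",
                     "censoring_rate", "presence_prob",
                     "promoter_open_fraction", "promoter_induced_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise StromaregError(f"{name} must lie in [0, 1]")
        for cond, reps in self.conditions.items():
            if reps < 2:
                raise StromaregError(f"condition {cond!r} needs >= 2 replicates")
        if self.marker_hr <= 0:
            raise StromaregError("marker_hr must be positive")
        if self.multipeak_gene_count > self.n_genes:
            raise StromaregError("multipeak_gene_count exceeds available genes")
        if self.dispersion < 0:
            raise StromaregError("dispersion must be >= 0")

    def sample_names(self) -> list[str]:
        return [f"{cond}_{i+1}" for cond in self.conditions
                for i in range(self.conditions[cond])]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthTable:
    """Planted ground truth for recovery testing."""

    genes: pd.DataFrame          # gene_id, de_log2fc, base_mean, promoter_class
    peaks: pd.DataFrame          # peak_id, chrom, start, end, summit, acc_log2fc,
    #                              peak_class, planted_gene, rare
    multipeak_planted: list = field(default_factory=list)
    multipeak_implied: list = field(default_factory=list)
    markers: list = field(default_factory=list)
    motif_planted: pd.Series | None = None
    stromal_share: pd.Series | None = None


def default_motif() -> MotifModel:
    """AP-1-like (JUNB) TGACTCA position weight matrix."""
    consensus = "TGACTCA"
    w = len(consensus)
    mat = np.full((w, 4), 0.05)
    for i, base in enumerate(consensus):
        mat[i, ALPHABET.index(base)] = 0.85
    return MotifModel("AP1_JUNB", mat)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, var = mean + phi mean^2); Poisson when dispersion is 0."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_genome(config: SimConfig) -> pd.DataFrame:
    """Toy gene models: non-overlapping TSSs on one linear chromosome."""
    rng = substream(config.seed, "genome")
    n = config.n_genes
    margin = 60_000
    spacing = (config.chrom_length - 2 * margin) / n
    if spacing < 24_000:
        raise StromaregError("chromosome too short for the requested gene count")
    jitter = rng.uniform(-0.2, 0.2, size=n)
    tss = (margin + (np.arange(n) + 0.5 + jitter) * spacing).astype(np.int64)
    strand = rng.choice(["+", "-"], size=n)
    length = np.clip(rng.lognormal(np.log(2000), 0.6, size=n), 300, 30_000).astype(int)
    return pd.DataFrame({
        "gene_id": [f"gene_{i:04d}" for i in range(n)],
        "chrom": config.chrom_name,
        "strand": strand,
        "tss": tss,
        "length": length,
    })


def _plant_gene_effects(rng, config, gene_models):
    """Base means plus planted soluble-factor (TSW+CO) and adhesion (CO-only)
    effects; a small set of MM-silent genes carries the stromal signature."""
    n = config.n_genes
    base = rng.lognormal(np.log(config.base_mean), config.base_sigma, size=n)
    silent = np.zeros(n, dtype=bool)
    n_silent = int(round(config.mm_silent_fraction * n))
    if n_silent:
        silent[rng.choice(n, size=n_silent, replace=False)] = True
        base[silent] *= 1e-3  # silenced in MM cells, high in stroma
    effect = np.zeros(n)
    active = np.flatnonzero(~silent)
    n_de = int(round(config.de_fraction * n))
    if n_de:
        de_idx = rng.choice(active, size=min(n_de, len(active)), replace=False)
        half = len(de_idx) // 2
        effect[de_idx[:half]] = config.de_log2fc
        effect[de_idx[half:]] = -config.de_log2fc
    # adhesion-only effect, half drawn from already-changed genes with the
    # same sign so the two comparisons show direction-consistent calls
    adhesion = np.zeros(n)
    n_adh = int(round(config.adhesion_fraction * n))
    if n_adh:
        changed = np.flatnonzero(effect != 0)
        n_shared = min(n_adh // 2, len(changed))
        shared = rng.choice(changed, size=n_shared, replace=False)
        adhesion[shared] = np.sign(effect[shared]) * config.adhesion_log2fc
        pool = np.array([i for i in active if adhesion[i] == 0])
        rest = rng.choice(pool, size=min(n_adh - n_shared, len(pool)), replace=False)
        signs = rng.choice([-1.0, 1.0], size=len(rest))
        adhesion[rest] = signs * config.adhesion_log2fc
    return base, effect, adhesion, silent


def simulate_expression(config: SimConfig, gene_models: pd.DataFrame | None = None,
                        truth_genes: pd.DataFrame | None = None
                        ) -> tuple[CountMatrix, pd.DataFrame, pd.Series, pd.Series]:
    """NB gene counts for MONO/TSW/CO with planted effects and CO contamination.

    Returns (counts, truth frame, stromal expression profile, realised
    stromal read share per CO sample).  ``truth_genes`` lets a caller pin
    the planted means/effects (used by :func:`simulate_all` so the planted
    multi-peak genes are guaranteed to be expressed).
    """
    if gene_models is None:
        gene_models = simulate_genome(config)
    rng = substream(config.seed, "expression")
    gene_ids = gene_models["gene_id"].to_numpy()
    if truth_genes is None:
        base, effect, adhesion, silent = _plant_gene_effects(rng, config, gene_models)
    else:
        base = truth_genes["base_mean"].to_numpy()
        effect = truth_genes["de_log2fc"].to_numpy()
        adhesion = truth_genes["adhesion_log2fc"].to_numpy()
        silent = truth_genes["mm_silent"].to_numpy()

    mu = {"MONO": base, "TSW": base * 2.0 ** effect,
          "CO": base * 2.0 ** (effect + adhesion)}
    stromal_mu = rng.lognormal(np.log(config.base_mean), config.base_sigma,
                               size=len(base))
    # the MM-silent genes are the highly expressed stromal signature
    if silent.any():
        stromal_mu[silent] = np.maximum(
            stromal_mu[silent], np.quantile(stromal_mu, 0.999) * (1 + rng.random(silent.sum())))
    stromal_mu *= mu["CO"].sum() / stromal_mu.sum()

    f = config.contamination_fraction
    cols = {}
    share = {}
    for cond, reps in config.conditions.items():
        for i in range(reps):
            name = f"{cond}_{i+1}"
            if cond == "CO" and f > 0:
                mm = _nb_draw(rng, (1 - f) * mu[cond], config.dispersion)
                st = _nb_draw(rng, f * stromal_mu, config.dispersion)
                cols[name] = mm + st
                total = mm.sum() + st.sum()
                share[name] = st.sum() / total if total else 0.0
            else:
                cols[name] = _nb_draw(rng, mu[cond], config.dispersion)
                if cond == "CO":
                    share[name] = 0.0
    counts = pd.DataFrame(cols, index=gene_ids)
    lengths = pd.Series(gene_models["length"].to_numpy(), index=gene_ids)
    conditions = pd.Series({s: s.rsplit("_", 1)[0] for s in counts.columns})
    cm = CountMatrix(counts, conditions, lengths=lengths)
    truth = pd.DataFrame({"gene_id": gene_ids, "de_log2fc": effect,
                          "adhesion_log2fc": adhesion, "base_mean": base,
                          "mm_silent": silent}).set_index("gene_id")
    stromal = pd.Series(stromal_mu, index=gene_ids, name="stromal")
    # express the stromal profile in RPKM-like units for the signature filter
    stromal_rpkm = stromal / (lengths / 1e3) / (stromal.sum() / 1e6)
    return cm, truth, stromal_rpkm, pd.Series(share)


def simulate_accessibility(config: SimConfig, gene_models: pd.DataFrame
                           ) -> tuple[dict, dict, pd.DataFrame, list[str], pd.DataFrame]:
    """Per-sample peak calls and reads with planted accessibility effects.

    Returns (peaks per sample, reads per sample, truth peak frame, planted
    multi-peak gene list, promoter-class frame).  Each planted multi-peak
    gene receives 4 gaining distal peaks split two per side of the TSS so
    that no single neighbouring gene inherits more than two of them.
    """
    if config.multipeak_gene_count > config.n_genes // 3:
        raise StromaregError("multipeak_gene_count exceeds available genes "
                             "(needs non-adjacent placement)")
    rng = substream(config.seed, "accessibility")
    g = gene_models.reset_index(drop=True)
    n_genes = len(g)

    # promoter classes: open everywhere / induced (TSW+CO only) / closed
    classes = np.array(["open"] * n_genes, dtype=object)
    u = rng.random(n_genes)
    closed_cut = 1.0 - config.promoter_open_fraction - config.promoter_induced_fraction
    classes[u < closed_cut] = "closed"
    classes[(u >= closed_cut)
            & (u < closed_cut + config.promoter_induced_fraction)] = "induced"
    promoter_class = pd.DataFrame({"gene_id": g["gene_id"], "promoter_class": classes}
                                  ).set_index("gene_id")

    open_idx = np.flatnonzero(classes == "open")
    # planted multi-peak genes: open promoters, pairwise non-adjacent gene indices
    chosen: list[int] = []
    for idx in rng.permutation(open_idx):
        if len(chosen) == config.multipeak_gene_count:
            break
        if all(abs(idx - c) >= 2 for c in chosen):
            chosen.append(int(idx))
    if len(chosen) < config.multipeak_gene_count:
        raise StromaregError("could not place the requested multi-peak genes")
    multipeak_genes = sorted(g["gene_id"].iloc[chosen])

    width = config.peak_width
    rows = []  # chrom,start,end,kind,acc_log2fc,planted_gene

    def add_peak(center, kind, lfc, gene=None):
        start = int(center - width // 2)
        rows.append((config.chrom_name, start, start + width, kind, lfc, gene))

    for i in range(n_genes):
        if classes[i] == "open":
            add_peak(g["tss"].iloc[i], "promoter", 0.0, None)
        elif classes[i] == "induced":
            add_peak(g["tss"].iloc[i], "promoter_induced", config.acc_log2fc, None)
    for idx in chosen:
        tss = int(g["tss"].iloc[idx])
        offsets = rng.integers(4000, 18000, size=4)
        for k, off in enumerate(offsets):
            side = 1 if k % 2 == 0 else -1
            add_peak(tss + side * int(off), "multipeak_distal", config.acc_log2fc,
                     g["gene_id"].iloc[idx])

    n_bg = config.n_peaks - len(rows)
    if n_bg < 0:
        raise StromaregError("n_peaks too small for the planted structure")
    taken = np.array(sorted(r[1] + width // 2 for r in rows))
    margin = 30_000
    centers = []
    grid = np.linspace(margin, config.chrom_length - margin, n_bg)
    jit = rng.uniform(-0.4, 0.4, size=n_bg) * (grid[1] - grid[0] if n_bg > 1 else 1)
    for c in (grid + jit).astype(np.int64):
        j = np.searchsorted(taken, c)
        near = [taken[k] for k in (j - 1, j) if 0 <= k < len(taken)]
        if all(abs(c - t) > width + 150 for t in near):
            centers.append(int(c))
    n_gain = int(round(config.acc_gain_fraction * len(centers)))
    n_loss = int(round(config.acc_loss_fraction * len(centers)))
    eff_idx = rng.permutation(len(centers))
    for rank, ci in enumerate(eff_idx):
        lfc = (config.acc_log2fc if rank < n_gain
               else -config.acc_log2fc if rank < n_gain + n_loss else 0.0)
        add_peak(centers[ci], "background", lfc, None)

    truth = pd.DataFrame(rows, columns=["chrom", "start", "end", "kind",
                                        "acc_log2fc", "planted_gene"])
    truth = truth.sort_values("start").reset_index(drop=True)
    truth["peak_id"] = [f"peak_{i:05d}" for i in range(len(truth))]
    truth["summit"] = width // 2
    truth["rare"] = rng.random(len(truth)) < config.rare_peak_fraction
    truth.loc[truth["kind"] != "background", "rare"] = False

    samples = config.sample_names()
    mono_samples = {s for s in samples if s.startswith("MONO")}
    base_reads = config.peak_mean_reads * rng.lognormal(0, 0.3, size=len(truth))

    peaks_per_sample = {}
    reads_per_sample = {}
    for sample in samples:
        is_mono = sample in mono_samples
        present = rng.random(len(truth)) < np.where(
            truth["rare"], 0.2, config.presence_prob)
        induced = (truth["kind"] == "promoter_induced").to_numpy()
        present = np.where(induced, not is_mono, present).astype(bool)
        shift = rng.integers(-config.coord_jitter, config.coord_jitter + 1,
                             size=len(truth))
        pstart = truth["start"].to_numpy() + shift
        pend = truth["end"].to_numpy() + shift
        sub = pd.DataFrame({
            "chrom": truth["chrom"], "start": pstart, "end": pend,
            "name": [f"{sample}_{pid}" for pid in truth["peak_id"]],
            "score": 0, "strand": ".", "signal": 0.0, "pvalue": -1.0,
            "qvalue": -1.0, "summit": width // 2,
        })[present]
        peaks_per_sample[sample] = sub.reset_index(drop=True)

        lfc = truth["acc_log2fc"].to_numpy()
        mu = base_reads * np.where(is_mono, 1.0, 2.0 ** lfc)
        counts = _nb_draw(rng, mu, config.dispersion)
        summit_abs = truth["start"].to_numpy() + truth["summit"].to_numpy()
        mids = []
        for p_i, n_reads in enumerate(counts):
            if n_reads == 0:
                continue
            jitter = rng.normal(0, width / 8, size=n_reads)
            m = np.clip(summit_abs[p_i] + jitter,
                        truth["start"].iloc[p_i] + 1,
                        truth["end"].iloc[p_i] - 2).astype(np.int64)
            mids.append(m)
        mids = np.concatenate(mids) if mids else np.empty(0, dtype=np.int64)
        half = config.read_length // 2
        reads = pd.DataFrame({
            "chrom": config.chrom_name,
            "start": np.maximum(mids - half, 0),
            "end": mids - half + config.read_length,
            "name": [f"read_{i}" for i in range(len(mids))],
            "score": 0, "strand": ".",
        })
        reads_per_sample[sample] = reads

    return peaks_per_sample, reads_per_sample, truth, multipeak_genes, promoter_class


def simulate_sequences(windows: pd.DataFrame, motif: MotifModel, config: SimConfig,
                       fg_names: set[str] | None = None,
                       detectable_p: float = 1e-4
                       ) -> tuple[dict[str, str], pd.Series]:
    """Summit-window sequences with motif instances planted at two rates.

    ``windows`` is a frame with ``name`` and ``start``/``end``; foreground
    windows (``fg_names``) receive a planted instance with probability
    ``motif_plant_rate_fg``, others with ``motif_plant_rate_bg``; remaining
    bases are i.i.d. from the motif background.  Planted instances are
    sampled from the PWM conditioned on scoring at p <= ``detectable_p``
    (rejection sampling, consensus fallback), so a planted flag means the
    window genuinely contains the motif at scanning stringency.
    """
    from stromareg.motif import ScoreDistribution

    rng = substream(config.seed, "sequences")
    fg_names = fg_names or set()
    w = motif.width
    dist = ScoreDistribution(motif)
    lom = motif.log_odds
    seqs = {}
    planted = {}
    bases = np.array(list(ALPHABET))
    for win in windows.itertuples():
        length = int(win.end - win.start)
        if length < w:
            raise StromaregError(
                f"window {win.name} shorter than motif width {w}")
        rate = (config.motif_plant_rate_fg if win.name in fg_names
                else config.motif_plant_rate_bg)
        seq = bases[rng.choice(4, size=length, p=motif.background)]
        plant = rng.random() < rate
        if plant:
            off = int(rng.integers(0, length - w + 1))
            inst = None
            for _ in range(50):
                letters = [int(rng.choice(4, p=motif.matrix[j])) for j in range(w)]
                score = sum(lom[j, letters[j]] for j in range(w))
                if dist.pvalue(score) <= detectable_p:
                    inst = [bases[k] for k in letters]
                    break
            if inst is None:
                inst = [bases[int(motif.matrix[j].argmax())] for j in range(w)]
            seq[off: off + w] = inst
        seqs[win.name] = "".join(seq)
        planted[win.name] = plant
    return seqs, pd.Series(planted, name="motif_planted")


def simulate_cohorts(config: SimConfig, genes: list[str],
                     marker_genes: list[str] | None = None
                     ) -> tuple[dict[str, pd.DataFrame], list[str]]:
    """Survival cohorts with expression-dependent hazards for marker genes.

    Exponential survival; a patient in the top expression quartile of a
    planted marker gene has their hazard multiplied by ``marker_hr``;
    censoring is independent exponential tuned to the configured rate.  The
    first cohort (``CoMMpass``) is the primary one.
    """
    if config.n_cohorts < 2:
        raise StromaregError("need >= 2 cohorts (one primary plus validation)")
    rng = substream(config.seed, "cohorts")
    if marker_genes is None:
        k = min(config.marker_gene_count, len(genes))
        marker_genes = sorted(str(g) for g in rng.choice(genes, size=k, replace=False))
    names = ["CoMMpass", "MAQC2", "APEX", "TT2", "TT6"]
    while len(names) < config.n_cohorts:
        names.append(f"cohort{len(names)+1}")
    cohorts = {}
    q75 = 0.6744897501960817  # 75th percentile of N(0,1)
    for cname in names[: config.n_cohorts]:
        n = config.cohort_size
        expr = pd.DataFrame(rng.normal(size=(n, len(genes))), columns=genes,
                            index=[f"{cname}_p{i:04d}" for i in range(n)])
        log_hr = np.zeros(n)
        for gmark in marker_genes:
            log_hr += np.log(config.marker_hr) * (expr[gmark].to_numpy() > q75)
        hazard = config.baseline_hazard * np.exp(log_hr)
        t_event = rng.exponential(1.0 / hazard)
        cr = config.censoring_rate
        if cr > 0:
            c_rate = config.baseline_hazard * cr / max(1e-9, 1 - cr)
            t_cens = rng.exponential(1.0 / c_rate, size=n)
        else:
            t_cens = np.full(n, np.inf)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        df = expr.copy()
        df.insert(0, "event", event)
        df.insert(0, "time", np.maximum(time, 1e-6))
        df.index.name = "patient"
        cohorts[cname] = df
    return cohorts, list(marker_genes)


def simulate_all(config: SimConfig, motif: MotifModel | None = None) -> dict:
    """Generate every data type plus a consistent cross-stage truth table."""
    from stromareg import accessibility as acc
    from stromareg import targets as tg

    motif = motif or default_motif()
    gene_models = simulate_genome(config)

    # pin planted multi-peak genes to be well expressed before drawing counts
    peaks_per_sample, reads_per_sample, truth_peaks, mp_planted, promoter_class = \
        simulate_accessibility(config, gene_models)
    rng_pin = substream(config.seed, "pin")
    base, effect, adhesion, silent = _plant_gene_effects(rng_pin, config, gene_models)
    gidx = {gid: i for i, gid in enumerate(gene_models["gene_id"])}
    for gid in mp_planted:
        i = gidx[gid]
        if silent[i]:
            silent[i] = False
            base[i] = config.base_mean
        base[i] = max(base[i], config.base_mean)
        if effect[i] < 0:  # keep multi-peak genes non-repressed
            effect[i] = 0.0
    pinned = pd.DataFrame({"de_log2fc": effect, "adhesion_log2fc": adhesion,
                           "base_mean": base, "mm_silent": silent},
                          index=gene_models["gene_id"])
    cm, truth_genes, stromal_rpkm, share = simulate_expression(
        config, gene_models, truth_genes=pinned)
    truth_genes = truth_genes.join(promoter_class)

    # implied multi-peak truth: expressed genes with >2 truly gaining distal
    # peaks inside their regulatory domain
    chrom_sizes = {config.chrom_name: config.chrom_length}
    domains = tg.assign_regulatory_domains(gene_models, chrom_sizes=chrom_sizes)
    classes = acc.classify_promoter_distal(
        truth_peaks.rename(columns={"peak_id": "name"}), gene_models,
        chrom_sizes=chrom_sizes)
    truth_peaks = truth_peaks.copy()
    truth_peaks["peak_class"] = classes.to_numpy()
    # any-class gaining peaks, matching the default multi-peak caller
    gaining = truth_peaks[truth_peaks["acc_log2fc"] > 0]
    assoc = tg.peaks_to_targets(gaining.rename(columns={"peak_id": "name"}), domains)
    lengths = gene_models.set_index("gene_id")["length"]
    true_rpkm = (truth_genes["base_mean"] * 2.0 ** truth_genes["de_log2fc"]
                 / (lengths / 1e3))
    true_rpkm = true_rpkm / (truth_genes["base_mean"].sum() / 1e6)
    expressed = set(true_rpkm[true_rpkm >= 1.0].index)
    counts = assoc.groupby("gene_id")["peak"].nunique()
    implied = sorted(gid for gid, c in counts.items() if c >= 3 and gid in expressed)

    # summit-window sequences for the reference-scale motif stage
    windows = pd.DataFrame({
        "name": truth_peaks["peak_id"],
        "start": truth_peaks["start"] + truth_peaks["summit"] - 50,
        "end": truth_peaks["start"] + truth_peaks["summit"] + 51,
    })
    fg_names = set(truth_peaks.loc[truth_peaks["acc_log2fc"] > 0, "peak_id"])
    seqs, motif_planted = simulate_sequences(windows, motif, config,
                                             fg_names=fg_names)

    # planted markers: a few multi-peak genes (the clinically relevant overlap)
    # plus random others
    rng_mk = substream(config.seed, "markers")
    n_from_mp = min(3, len(mp_planted), config.marker_gene_count)
    from_mp = [str(g) for g in rng_mk.choice(mp_planted, size=n_from_mp,
                                             replace=False)]
    pool = [g for g in gene_models["gene_id"] if g not in from_mp]
    n_rest = max(0, config.marker_gene_count - n_from_mp)
    rest = [str(g) for g in rng_mk.choice(pool, size=n_rest, replace=False)]
    cohorts, markers = simulate_cohorts(config, list(gene_models["gene_id"]),
                                        marker_genes=sorted(from_mp + rest))

    genesets = _make_genesets(config, truth_genes)

    truth = TruthTable(genes=truth_genes, peaks=truth_peaks,
                       multipeak_planted=mp_planted, multipeak_implied=implied,
                       markers=markers, motif_planted=motif_planted,
                       stromal_share=share)
    return {
        "config": config, "gene_models": gene_models, "expression": cm,
        "stromal_rpkm": stromal_rpkm, "peaks_per_sample": peaks_per_sample,
        "reads_per_sample": reads_per_sample, "sequences": seqs,
        "windows": windows, "cohorts": cohorts, "genesets": genesets,
        "motif": motif, "truth": truth,
    }


def _make_genesets(config: SimConfig, truth_genes: pd.DataFrame):
    from stromareg.enrichment import GeneSet

    rng = substream(config.seed, "genesets")
    up = truth_genes.index[truth_genes["de_log2fc"] > 0].tolist()
    down = truth_genes.index[truth_genes["de_log2fc"] < 0].tolist()
    sets = []
    if up:
        sets.append(GeneSet("PLANTED_UP", up, "genes with planted induction"))
    if down:
        sets.append(GeneSet("PLANTED_DOWN", down, "genes with planted repression"))
    all_genes = truth_genes.index.to_numpy()
    for i in range(3):
        members = sorted(rng.choice(all_genes, size=min(50, len(all_genes)),
                                    replace=False))
        sets.append(GeneSet(f"RANDOM_{i+1}", members, "random control set"))
    return sets
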