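"""End-to-end pipeline: simulate (or load) inputs, run every stage, report.

The driver chains the stages of the coculture analysis: differential
expression for the three condition pairs, reference-peak compilation and
differential accessibility, promoter/distal classification, GREAT-style
target assignment and the multi-peak rule, gene filters and the rnk file,
preranked GSEA, motif enrichment in summit windows, and the multi-cohort
prognostic-marker screen.  A machine-readable manifest records seed,
thresholds, versions and per-stage counts; with simulated inputs it also
records recovery metrics against the planted truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from stromareg import __version__, accessibility as acc, expression as expr
from stromareg import enrichment as enr, io as sio, motif as mot
from stromareg import survival as surv, targets as tg
from stromareg.errors import StromaregError
from stromareg.synthetic import SimConfig, simulate_all

__all__ = ["PipelineConfig", "run_pipeline", "write_dataset", "promoter_open_status"]


@dataclass
class PipelineConfig:
    """Stage thresholds (study defaults) plus simulation settings."""

    outdir: str = "stromareg_out"
    seed: int = 0
    baseline: str = "MONO"
    comparison: str = "TSW"
    de_fdr: float = 0.05
    de_fc: float = 1.5
    de_min_log2cpm: float = 0.0
    peak_fdr: float = 0.01
    peak_fc: float = 1.5
    gfold_cutoff: float = acc.GFOLD_CUTOFF
    gfold_credibility: float = 0.99
    min_support: int = 3
    promoter_window: int = 2500
    summit_half_width: int = 50
    min_peaks: int = 3
    expressed_rpkm: float = 1.0
    motif_pthresh: float = 1e-4
    gsea_n_perm: int = 1000
    quartile: float = 0.25
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self):
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        self.sim.seed = self.seed
        for name, lo, hi in (("de_fdr", 0, 1), ("peak_fdr", 0, 1),
                             ("quartile", 0, 0.5), ("gfold_credibility", 0, 1)):
            v = getattr(self, name)
            if not (lo < v < hi):
                raise StromaregError(f"{name}={v} outside ({lo}, {hi})")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def write_dataset(data: dict, outdir) -> None:
    """Emit every simulated input as plain-text files under ``outdir``."""
    out = Path(outdir)
    (out / "peaks").mkdir(parents=True, exist_ok=True)
    (out / "reads").mkdir(exist_ok=True)
    (out / "cohorts").mkdir(exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    sio.write_counts(data["expression"], out / "counts.tsv")
    sio.write_gene_models(data["gene_models"], out / "gene_models.tsv")
    data["stromal_rpkm"].rename("rpkm").to_csv(out / "stromal_rpkm.tsv", sep="\t")
    for sample, df in data["peaks_per_sample"].items():
        sio.write_narrowpeak(df, out / "peaks" / f"{sample}.narrowPeak")
    for sample, df in data["reads_per_sample"].items():
        sio.write_bed6(df, out / "reads" / f"{sample}.bed")
    sio.write_fasta(data["sequences"], out / "windows.fasta")
    sio.write_gmt(data["genesets"], out / "genesets.gmt")
    sio.write_meme_motifs([data["motif"]], out / "motif.meme")
    for cname, df in data["cohorts"].items():
        sio.write_cohort(df, out / "cohorts" / f"{cname}.tsv")
    truth = data["truth"]
    truth.genes.to_csv(out / "truth" / "genes.tsv", sep="\t")
    truth.peaks.to_csv(out / "truth" / "peaks.tsv", sep="\t", index=False)
    pd.Series(truth.multipeak_implied, name="gene_id").to_csv(
        out / "truth" / "multipeak_genes.tsv", sep="\t", index=False)
    pd.Series(truth.markers, name="gene_id").to_csv(
        out / "truth" / "marker_genes.tsv", sep="\t", index=False)
    truth.motif_planted.rename("planted").to_csv(
        out / "truth" / "motif_planted.tsv", sep="\t")


def promoter_open_status(gene_models: pd.DataFrame,
                         peaks_per_sample: dict[str, pd.DataFrame],
                         conditions: pd.Series, window: int = 2500) -> pd.DataFrame:
    """Boolean gene-by-condition frame: promoter overlaps >=1 call in >=1 sample."""
    conds = sorted(set(conditions))
    status = pd.DataFrame(False, index=gene_models["gene_id"], columns=conds)
    for cond in conds:
        samples = [s for s in peaks_per_sample if conditions.get(s) == cond]
        merged = pd.concat([peaks_per_sample[s] for s in samples], ignore_index=True)
        for chrom, grp in merged.groupby("chrom"):
            g = grp.sort_values("start")
            starts = g["start"].to_numpy()
            ends_cummax = np.maximum.accumulate(g["end"].to_numpy())
            sub = gene_models[gene_models["chrom"] == chrom]
            ws = np.maximum(sub["tss"].to_numpy() - window, 0)
            we = sub["tss"].to_numpy() + window + 1
            i = np.searchsorted(starts, we, side="left")
            open_ = np.zeros(len(sub), dtype=bool)
            nz = i > 0
            open_[nz] = ends_cummax[i[nz] - 1] > ws[nz]
            status.loc[sub["gene_id"], cond] = open_
    return status


def _match_reference_to_windows(ref: pd.DataFrame, windows: pd.DataFrame) -> dict:
    """Map each reference peak to the master summit window containing its summit."""
    w = windows.sort_values("start")
    starts = w["start"].to_numpy()
    ends = w["end"].to_numpy()
    names = w["name"].to_numpy()
    mapping = {}
    summit_abs = ref["start"].to_numpy() + ref["summit"].to_numpy()
    j = np.searchsorted(starts, summit_abs, side="right") - 1
    for i, rname in enumerate(ref["name"]):
        k = j[i]
        if k >= 0 and summit_abs[i] < ends[k]:
            mapping[rname] = names[k]
    return mapping


def run_pipeline(config: PipelineConfig, data: dict | None = None) -> dict:
    """Run every stage; returns the manifest (also written to the outdir)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if data is None:
        data = simulate_all(config.sim)
        write_dataset(data, out / "inputs")

    manifest: dict = {
        "package_version": __version__,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "seed": config.seed,
        "thresholds": {k: v for k, v in asdict(config).items() if k != "sim"},
        "stages": {},
    }
    cm = data["expression"]
    gene_models = data["gene_models"]
    truth = data.get("truth")

    # --- differential expression over the three condition pairs
    de = {}
    for base, comp in (("MONO", "TSW"), ("MONO", "CO"), ("TSW", "CO")):
        res = expr.differential_expression(cm, base, comp, fdr=config.de_fdr,
                                           fc=config.de_fc,
                                           min_avg_log2cpm=config.de_min_log2cpm)
        de[(base, comp)] = res
        res.to_csv(out / f"de_{comp}_vs_{base}.tsv", sep="\t")
        manifest["stages"][f"de_{comp}_vs_{base}"] = {
            "up": int((res["call"] == "up").sum()),
            "down": int((res["call"] == "down").sum()),
            "n_genes": len(res)}

    # --- accessibility
    ref = acc.compile_reference_peaks(list(data["peaks_per_sample"].values()),
                                      min_support=config.min_support)
    sio.write_narrowpeak(ref.assign(strand=".", signal=0.0, pvalue=-1.0,
                                    qvalue=-1.0, score=ref["support"]),
                         out / "reference_peaks.narrowPeak")
    sample_conditions = pd.Series({s: s.rsplit("_", 1)[0]
                                   for s in data["peaks_per_sample"]})
    peak_cm = acc.count_reads_in_peaks(data["reads_per_sample"], ref,
                                       conditions=sample_conditions)
    sio.write_counts(peak_cm, out / "peak_counts.tsv")
    pk = acc.differential_peaks(peak_cm, config.baseline, config.comparison,
                                fdr=config.peak_fdr, fc=config.peak_fc)
    pk["gfold"] = acc.gfold_table(peak_cm, config.baseline, config.comparison,
                                  credibility=config.gfold_credibility)
    pk.to_csv(out / f"peaks_{config.comparison}_vs_{config.baseline}.tsv", sep="\t")
    classes = acc.classify_promoter_distal(ref, gene_models,
                                           window=config.promoter_window)
    classes.rename("class").to_csv(out / "peak_classes.tsv", sep="\t")
    manifest["stages"]["accessibility"] = {
        "reference_peaks": len(ref),
        "up": int((pk["call"] == "up").sum()),
        "down": int((pk["call"] == "down").sum()),
        "gfold_up": int((pk["gfold"] > config.gfold_cutoff).sum()),
        "gfold_down": int((pk["gfold"] < -config.gfold_cutoff).sum()),
        "promoter": int((classes == "promoter").sum()),
        "distal": int((classes == "distal").sum())}

    # --- gene filters and the rnk file
    rpkm = expr.compute_rpkm(cm)
    stromal_excluded = expr.stromal_signature_filter(
        rpkm, data["stromal_rpkm"],
        top_n=min(1000, max(1, len(data["stromal_rpkm"]) // 4)))
    open_status = promoter_open_status(gene_models, data["peaks_per_sample"],
                                       sample_conditions,
                                       window=config.promoter_window)
    promoter_excluded = expr.promoter_open_filter(open_status)
    excluded = sorted(set(stromal_excluded) | set(promoter_excluded))
    pd.Series(excluded, name="gene_id").to_csv(out / "excluded_genes.tsv",
                                               sep="\t", index=False)
    de_main = de[(config.baseline, config.comparison)]
    rnk = expr.make_rnk(de_main, excluded=excluded)
    sio.write_rnk(rnk, out / f"{config.comparison}_vs_{config.baseline}.rnk")
    manifest["stages"]["filters"] = {"stromal_excluded": len(stromal_excluded),
                                     "promoter_excluded": len(promoter_excluded)}

    # --- target assignment and multi-peak genes
    chrom_sizes = {data["config"].chrom_name: data["config"].chrom_length} \
        if "config" in data else None
    domains = tg.assign_regulatory_domains(gene_models, chrom_sizes=chrom_sizes)
    assoc = tg.peaks_to_targets(ref, domains)
    assoc.to_csv(out / "peak_gene_associations.tsv", sep="\t", index=False)
    increasing = pk.index[pk["call"] == "up"].tolist()
    comp_rpkm = rpkm[cm.samples_of(config.comparison)].mean(axis=1)
    expressed = comp_rpkm[comp_rpkm >= config.expressed_rpkm].index.tolist()
    multipeak = tg.multi_peak_genes(assoc, increasing, expressed,
                                    min_peaks=config.min_peaks)
    pd.Series(multipeak, name="gene_id").to_csv(out / "multipeak_genes.tsv",
                                                sep="\t", index=False)
    manifest["stages"]["targets"] = {"associations": len(assoc),
                                     "increasing_peaks": len(increasing),
                                     "multipeak_genes": len(multipeak)}

    # --- GSEA and the expression shift of multi-peak genes
    gsea = enr.gsea_collection(rnk, data["genesets"], n_perm=config.gsea_n_perm,
                               seed=config.seed)
    gsea.to_csv(out / "gsea.tsv", sep="\t")
    in_mp = de_main.index.isin(multipeak)
    if in_mp.sum() >= 2 and (~in_mp).sum() >= 2:
        ks_d, ks_p = enr.ks_shift_test(de_main.loc[in_mp, "log2fc"],
                                       de_main.loc[~in_mp, "log2fc"])
    else:
        ks_d, ks_p = float("nan"), float("nan")
    conc = enr.contingency_concordance(de[("MONO", "TSW")]["call"],
                                       de[("TSW", "CO")]["call"]) \
        if (de[("TSW", "CO")]["call"] != "unchanged").any() else None
    manifest["stages"]["enrichment"] = {
        "gsea_sets": len(gsea),
        "multipeak_shift_D": None if np.isnan(ks_d) else round(ks_d, 4),
        "multipeak_shift_p": None if np.isnan(ks_p) else float(ks_p),
        "concordance_ratio": None if conc is None else round(conc["ratio"], 3)}

    # --- motif enrichment in summit windows
    windows = acc.summit_windows(ref, half_width=config.summit_half_width,
                                 chrom_sizes=chrom_sizes)
    sio.write_bed6(windows, out / "summit_windows.bed")
    if "windows" in data:
        master_windows = data["windows"]
        mapping = _match_reference_to_windows(ref, master_windows)
    else:
        mapping = {}
    seqs = data["sequences"]
    fg = {mapping[r]: seqs[mapping[r]] for r in increasing if r in mapping}
    unchanged = pk.index[pk["call"] == "unchanged"].tolist()
    bg = {mapping[r]: seqs[mapping[r]] for r in unchanged if r in mapping}
    if fg and bg:
        menr = mot.motif_enrichment(fg, bg, data["motif"],
                                    p_threshold=config.motif_pthresh)
    else:
        menr = {"fraction_fg": float("nan"), "fraction_bg": float("nan"),
                "odds_ratio": float("nan"), "pvalue": float("nan"),
                "n_fg": len(fg), "n_bg": len(bg)}
    manifest["stages"]["motif"] = {k: (round(v, 5) if isinstance(v, float) else v)
                                   for k, v in menr.items()}

    # --- survival marker screen over all genes present in the cohorts
    cohorts = data["cohorts"]
    primary = next(iter(cohorts))
    genes_in_cohorts = [c for c in next(iter(cohorts.values())).columns
                        if c not in ("time", "event")]
    marker_table = surv.survival_screen(cohorts, genes_in_cohorts, primary)
    marker_table.to_csv(out / "marker_table.tsv", sep="\t")
    markers_called = marker_table.index[marker_table["marker"]].tolist()
    mp_markers = sorted(set(markers_called) & set(multipeak))
    manifest["stages"]["survival"] = {
        "primary_cohort": primary,
        "genes_screened": len(genes_in_cohorts),
        "markers_called": len(markers_called),
        "multipeak_marker_fraction": (len(mp_markers) / len(multipeak)
                                      if multipeak else None)}

    # --- recovery metrics against the planted truth
    if truth is not None:
        manifest["recovery"] = _recovery_metrics(
            de_main, pk, ref, multipeak, markers_called, menr, truth, config)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _recovery_metrics(de_main, pk, ref, multipeak, markers_called, menr,
                      truth, config) -> dict:
    genes = truth.genes
    planted_up = set(genes.index[genes["de_log2fc"] > 0])
    planted_dn = set(genes.index[genes["de_log2fc"] < 0])
    called_up = set(de_main.index[de_main["call"] == "up"])
    called_dn = set(de_main.index[de_main["call"] == "down"])
    planted = planted_up | planted_dn
    correct = len(called_up & planted_up) + len(called_dn & planted_dn)
    called = called_up | called_dn
    de_sens = correct / len(planted) if planted else None
    de_fdr = (len(called - planted) / len(called)) if called else 0.0

    tp = truth.peaks.sort_values("start")
    t_starts = tp["start"].to_numpy()
    t_ends = tp["end"].to_numpy()
    t_lfc = tp["acc_log2fc"].to_numpy()
    summit_abs = ref["start"].to_numpy() + ref["summit"].to_numpy()
    j = np.searchsorted(t_starts, summit_abs, side="right") - 1
    ref_true_lfc = np.full(len(ref), np.nan)
    ok = (j >= 0) & (summit_abs < t_ends[np.clip(j, 0, len(t_ends) - 1)])
    ref_true_lfc[ok] = t_lfc[j[ok]]
    up_called = (pk["call"] == "up").to_numpy()
    truly_up = ref_true_lfc > 0
    peak_sens = (float((up_called & truly_up).sum() / truly_up.sum())
                 if truly_up.sum() else None)
    peak_fdr_emp = (float((up_called & ~truly_up).sum() / up_called.sum())
                    if up_called.sum() else 0.0)

    planted_mp = set(truth.multipeak_planted)
    implied = set(truth.multipeak_implied)
    called_mp = set(multipeak)
    mp_sens = len(called_mp & planted_mp) / len(planted_mp) if planted_mp else None
    mp_prec = len(called_mp & implied) / len(called_mp) if called_mp else None

    planted_markers = set(truth.markers)
    called_mk = set(markers_called)
    mk_sens = (len(called_mk & planted_markers) / len(planted_markers)
               if planted_markers else None)

    return {
        "de_sensitivity": de_sens, "de_empirical_fdr": de_fdr,
        "peak_up_sensitivity": peak_sens, "peak_up_empirical_fdr": peak_fdr_emp,
        "multipeak_sensitivity": mp_sens, "multipeak_precision": mp_prec,
        "marker_sensitivity": mk_sens,
        "motif_fraction_fg": menr.get("fraction_fg"),
        "motif_fraction_bg": menr.get("fraction_bg"),
        "stromal_share_max": (float(truth.stromal_share.max())
                              if truth.stromal_share is not None else None),
    }
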