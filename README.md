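# stromareg

Multiple myeloma (MM) cells remodel their transcriptome and chromatin
landscape when cultured with bone-marrow stromal cells (BMSCs), and those
changes track with drug resistance and patient survival.  `stromareg`
implements, as a tested and reusable Python pipeline, the analysis of a
three-condition coculture design — **MONO** (myeloma alone), **TSW**
(transwell, soluble factors only) and **CO** (lower chamber, soluble factors
plus adhesion) — integrating RNA-seq, Omni-ATAC accessibility, motif and
survival data.  It is aimed at computational biologists who want the whole
analysis chain, or any single stage, with explicit thresholds and seeded,
testable behaviour.

## What it computes

* **Differential expression** — an NB exact-style test with TMM library
  normalisation and empirical-Bayes dispersion shrinkage; a gene is called
  when FDR < 0.05, fold change > 1.5 and average log2 CPM > 0.  Gene filters
  remove the stromal signature (top 1000 stromal-expressed genes with MM
  RPKM < 2, guarding against the <5% stromal carry-over in CO) and genes
  whose promoter is closed in all three conditions.
* **Reference peaks & differential accessibility** — consensus peaks are
  bases covered by calls in ≥ 3 samples; reads are counted by the midpoint
  rule; differential peaks need FDR < 0.01 and FC > 1.5, or a GFOLD-style
  posterior log2 fold-change bound |value| > 0.585 (= log2 1.5).  Peaks are
  promoter (within TSS ± 2500 bp) or distal.
* **Target assignment** — GREAT-style basal-plus-extension domains (5 kb up /
  1 kb down, ≤ 1 Mb, truncated at neighbouring basal domains); the
  *multi-peak genes* are expressed genes with > 2 accessibility-gaining
  associated peaks.
* **Enrichment statistics** — preranked GSEA (weighted running sum,
  permutation null, NES/FDR), hypergeometric gene-set overlap, two-sample
  K-S expression-shift tests (exact for n·m ≤ 30), and the directional
  contingency concordance (observed consistent calls over the independence
  expectation).
* **Motif analysis** — FIMO-style PWM scanning of summit ± 50 bp windows
  with exact score-distribution p-values (p ≤ 1e-4), and Fisher-exact
  enrichment of foreground (gaining) versus background (non-differential)
  windows.
* **Survival screen** — per cohort, patients split into the top 25% by a
  gene's expression; log-rank p and single-covariate Cox HR (Breslow ties);
  a gene is an unfavorable marker when the primary cohort and ≥ 1 other
  cohort each show p < 0.05 and HR > 1.
* **Synthetic study generator** — seeded negative-binomial counts with
  planted fold changes, <5% stromal contamination in CO, per-sample peak
  calls with planted gains/losses and multi-peak genes, PWM-planted
  sequences, and survival cohorts with expression-dependent hazards — plus
  the ground-truth tables used for recovery testing.

## Worked example

Run the whole pipeline on a simulated study (one seed controls everything):

```
stromareg run --simulate --seed 1 --out out/
```

This prints, among the per-stage summaries, the recovery metrics against the
planted truth:

```
recovery: {"de_sensitivity": 0.975, "de_empirical_fdr": 0.0714,
 "peak_up_sensitivity": 0.9302, "peak_up_empirical_fdr": 0.0123,
 "multipeak_sensitivity": 1.0, "multipeak_precision": 1.0,
 "marker_sensitivity": 0.9, "motif_fraction_fg": 0.3704,
 "motif_fraction_bg": 0.0739, "stromal_share_max": 0.0282}
```

meaning: 97.5% of genes planted with a 4-fold expression change were called
in the right direction with 7.1% false calls; 93.0% of peaks planted with an
accessibility gain were called up; every planted multi-peak gene was
recovered and every called one genuinely carries > 2 gaining peaks; 9 of the
10 planted HR = 2 prognostic markers passed the multi-cohort rule; and the
realised stromal read share in CO stayed close to the configured 3%.
`out/` holds the differential tables, reference peaks, associations,
multi-peak list, GSEA/motif/marker tables and a `manifest.json` with seed,
thresholds and versions; re-running with the same seed reproduces every file
byte for byte.

Library use mirrors the CLI:

```python
from stromareg.synthetic import SimConfig, simulate_all
from stromareg.expression import differential_expression

data = simulate_all(SimConfig(seed=1))
de = differential_expression(data["expression"], "MONO", "TSW")
print(de["call"].value_counts())
```

## Layout

```
src/stromareg/
  synthetic.py       seeded generator + ground truth
  nbdiff.py          TMM, dispersion shrinkage, NB exact-style test, BH
  expression.py      CPM/RPKM, DE calls, filters, rnk, PCA, z-scores
  accessibility.py   reference peaks, counting, GFOLD, promoter/distal
  targets.py         GREAT-style domains, associations, multi-peak rule
  enrichment.py      GSEA, hypergeometric, K-S, concordance
  motif.py           PWM model, exact score distribution, scan, enrichment
  survival.py        quartile split, KM, log-rank, Cox, marker rule
  io.py              TSV/narrowPeak/BED/GMT/rnk/FASTA/MEME/cohort I/O
  pipeline.py        end-to-end driver + manifest
  cli.py             `stromareg` subcommands
```

See `docs/methods.md` for the statistical details and design choices.
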