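# Methods

This note documents the statistical models, numerical choices and
limitations behind each stage of the pipeline, and what the synthetic study
does and does not emulate.

## Differential counts (expression and accessibility)

Both RNA counts and peak read counts are modelled as negative binomial,
var = mu + phi·mu².  The test is an edgeR-inspired approximation, not a
re-derivation of edgeR; it is validated by null calibration (see below)
rather than by numerical equality with edgeR.

* **Normalisation.** Trimmed mean of M-values (30% trim on log-ratios, 5%
  on abundance, precision weights), reference sample chosen by the
  upper-quartile rule; factors are rescaled to geometric mean 1 and define
  effective library sizes.
* **Dispersion.** Per-feature method-of-moments estimates, computed within
  each group on counts scaled to a common library size and pooled by group
  degrees of freedom, are shrunk toward the common (mean over expressed
  features) estimate with weight `prior_df / (prior_df + residual_df)`,
  `prior_df = 10`.  At 3 replicates per group the per-feature moment
  estimate alone is far too noisy: features with lucky-small sample
  variance would receive inflated significance, which a fixed 50/50
  average does not cure.  The empirical-Bayes-style weight restores null
  calibration (~5% of null features at p < 0.05, empirical FDR of planted
  runs ≤ 0.1).
* **Test.** Counts are scaled to the geometric-mean effective library and
  summed per group; the two group sums are treated as NB with sizes
  n_g/phi.  Conditioning on their total, the two-sided p-value sums the
  probabilities of all outcomes no more likely than the observed one
  (support truncated at ±30 SD for large totals; the truncated mass is
  negligible).  This equal-library approximation is accurate when effective
  library sizes are similar, which TMM enforces.
* **Calls.** log2FC is the ratio of normalised group means with a prior
  count of 0.5; average log2 CPM uses a 0.5 pseudo-count.  Expression calls
  need BH FDR < 0.05, |FC| > 1.5 (two-sided) and average log2 CPM > 0 — the
  CPM threshold is applied to the per-gene average, one of two readings of
  the convention; accessibility calls need FDR < 0.01 and |FC| > 1.5 with
  no CPM floor.

## GFOLD-style posterior bound

Under a Gamma–Poisson model with Jeffreys prior, each group's normalised
rate has posterior Gamma(Σy + 0.5, ΣL).  The ratio of two independent Gamma
rates is a scaled beta-prime variable, so the equal-tailed 99% credible
interval of log2(rate_B/rate_A) is computed analytically from beta-prime
quantiles (no posterior sampling).  The reported value is the interval
bound nearest zero, or 0 when the interval spans zero; |value| > 0.585
(= log2 1.5 to three decimals) calls the peak differential.  Tests verify
the analytic bound against direct Monte-Carlo posterior sampling.

## Reference peaks and read counting

"Present in at least three samples" is realised as a per-base support
sweep: each sample contributes its union coverage, and maximal runs of
bases covered by ≥ 3 distinct samples become reference peaks.  (A
block-merge-then-count-support alternative disagrees on partially
overlapping calls; the sweep is the definition tested against the
brute-force per-base oracle.)  The retained peak's support is the number of
samples with ≥ 1 overlapping call, and its consensus summit the lower
median of contributing call summits falling inside the peak (midpoint if
none do).  Reads are assigned by the midpoint rule — a read counts for the
unique peak containing floor((start+end)/2) — so every read is counted at
most once regardless of boundary overlaps.

## Coordinates

All interval arithmetic is 0-based half-open.  The promoter window is
TSS ± 2500 bp closed on both ends in 1-based terms, i.e. [TSS−2500,
TSS+2501); summit windows are summit ± 50 bp (101 bp), clipped at
chromosome bounds with a logged warning.

## GREAT-style regulatory domains

Basal domain: 5 kb upstream / 1 kb downstream of the TSS, strand-aware,
never truncated.  Extension: up to 1 Mb from the TSS on each side, stopping
at the nearest neighbouring basal domain boundary and at chromosome ends.
Because extension stops at the neighbour's *basal* domain, the region
between two adjacent basal domains belongs to both genes' extended domains
— a deliberate property of the rule, and the reason multi-peak precision is
defined against the domain-level truth (below).  A peak targets every gene
whose extended domain it overlaps by ≥ 1 bp.  The curated-domain
corrections of the web service are not replicated.  "Expressed" for the
multi-peak rule means mean RPKM ≥ 1 in the comparison condition
(configurable); the multi-peak rule counts gaining peaks of any class by
default, with a distal-only switch.

## Enrichment statistics

* **Preranked GSEA.**  Ranking is by score descending, ties broken by gene
  id.  Hits increment the running sum by |score|^w (w = 1) normalised by
  the in-set total; misses decrement uniformly; ES is the signed maximal
  deviation.  The null permutes gene labels (`n_perm` = 1000); NES divides
  ES by the mean |null ES| of matching sign, the nominal p is the
  sign-matched tail with an add-one guard, and FDR q follows the
  sign-matched pooled-NES recipe of the original method.
* **Hypergeometric overlap.**  Upper-tail p with ratio observed/expected,
  expected = list·set/universe; BH across sets.
* **K-S shift test.**  Exact p when n·m ≤ 30 (scipy's path-counting
  algorithm, with a direct label-enumeration fallback when it fails),
  asymptotic otherwise.
* **Concordance.**  Observed = genes changed in the same direction in both
  comparisons; expected = (upA·upB + downA·downB)/N from the margins; the
  reported p is Fisher's exact test on the consistent-vs-changed 2×2
  collapse (the direction requirement makes the ratio, not the p, the
  primary quantity; the test choice is this package's own).

## Motif scanning

PWMs carry a per-cell pseudo-count of 0.1 (renormalised) before log2-odds
against the background (uniform unless estimated).  The null score
distribution of background k-mers is exact: full enumeration for widths ≤ 6
(4^w ≤ 4096), otherwise dynamic programming over scores discretised to
1/1000 of the total score range per the column-offset scheme, whose
floor-binned p-values are conservative and converge to enumeration as the
resolution grows.  Scanning reports every offset on both strands with
p ≤ 1e-4 (the scanner's conventional default); offsets containing N are
skipped.  Enrichment compares per-window containment (≥ 1 hit) in
foreground versus background windows by Fisher's exact test; the background
is the summit windows of peaks *not* differentially accessible.

## Survival screen

The top ceil(0.25·n) patients by expression (ties broken by patient id,
all-equal input logged) form the exposed group.  The log-rank test uses the
standard hypergeometric variance without continuity correction (via
lifelines).  The Cox model is a single binary covariate fitted by Newton
iteration on the Breslow partial likelihood (Efron available by flag);
monotone likelihoods are flagged and reported as unbounded HR rather than a
spurious finite estimate.  Cohorts are treated independently in their own
time units.  A cohort supports a gene when log-rank p < 0.05 and HR > 1; a
gene is an unfavorable marker when the primary cohort and ≥ 1 other cohort
support it.

## Synthetic study

The generator emulates the design every stage assumes, with one seed
feeding named substreams per data type (regenerating one data type never
perturbs another).

* **Genome.**  One linear 20 Mb chromosome, 400 genes at jittered
  evenly-spaced TSSs (~50 kb apart, so regulatory domains truncate at
  neighbours), lognormal gene lengths.
* **Expression.**  Lognormal baseline means (median 100, σ = 1.2), NB
  dispersion 0.1, 3 replicates per condition (the replicate count is a free
  parameter; 3 is the common design).  10% of genes carry a ±2 log2 effect
  in TSW and CO; 5% carry an extra ±1.5 log2 adhesion effect in CO only,
  half of them on already-changed genes with matching sign so the
  TSW/MONO–CO/TSW concordance is a planted property.  5% of genes are
  MM-silent (means ×10⁻³) and double as the highly expressed stromal
  signature.  CO columns are a (1−f)/f mixture with an independent stromal
  profile, f = 3% (< 5% by construction); the realised stromal read share
  is tracked and stays within ±1 point of f.
* **Accessibility.**  ~1200 master peaks (400 bp): promoter peaks for 85%
  of genes (open), 5% induced promoters present only in TSW/CO calls and
  gaining reads, 10% closed; 10 planted multi-peak genes each receive 4
  gaining distal peaks split two per side of the TSS (so no single
  neighbour inherits more than two) at 4–18 kb, outside every ±2500 bp
  promoter window; remaining background peaks gain/lose at 3%/3% with ±2
  log2 effects.  Per-sample calls subsample the master set (presence 0.95;
  3% rare peaks at 0.2 to exercise the support threshold) with ±10 bp
  coordinate jitter; reads are 50 bp intervals with Gaussian midpoint
  jitter around the summit, NB-distributed per peak (mean 60, dispersion
  0.1).  The truth table stores both the planted multi-peak list and the
  implied list — every gene whose true domain holds > 2 truly gaining
  peaks, including neighbours — and recovery uses planted for sensitivity,
  implied for precision.
* **Sequences.**  Summit ± 50 bp windows, i.i.d. background bases; an
  AP-1-like TGACTCA PWM instance is planted at rate 0.25 in gaining-peak
  windows and 0.05 elsewhere.  Planted instances are sampled from the PWM
  conditioned on scoring at the scan threshold (rejection sampling,
  consensus fallback), so a planted flag means the window genuinely
  contains the motif at scanning stringency.
* **Cohorts.**  Five cohorts (primary first) of 500 patients, standard
  normal expression per gene, exponential survival with baseline hazard
  0.1; each planted marker gene (10, a few drawn from the multi-peak genes)
  multiplies a top-quartile carrier's hazard by 2.  Censoring is
  independent exponential tuned to ~20%.  With several markers the
  per-gene marginal hazard ratio is mildly attenuated by the others acting
  as frailty — as in real cohorts.

What the generator does **not** emulate: base-level reads or sequencing
error, GC or mappability bias, correlated gene programs, batch effects,
real stromal expression profiles, or cohort heterogeneity in assay
platform.  Passing recovery tests therefore demonstrates the correctness
and calibration of the inference chain under its stated model, not
robustness to those real-data complications.

## Problem sizes and determinism

Default simulations (400 genes, ~1200 peaks, 9 samples, 5×500 patients)
complete the full pipeline in about a minute on one CPU; null calibrations
use 2000 features or 2000 replicates.  These sizes give Monte-Carlo errors
small enough for the calibration and recovery checks while keeping runs
interactive.  All randomness flows from one seed through named substreams;
identical configuration yields byte-identical outputs, which the test suite
asserts file-by-file.

## Known limitations

* The NB exact-style test assumes near-equal effective library sizes after
  TMM; grossly unequal designs would need the full quantile adjustment.
* GFOLD here is a re-derivation of the published posterior-bound idea with
  a Jeffreys prior, not a port of the original implementation.
* GSEA p/FDR resolution is limited by `n_perm`; the pooled-NES FDR can be
  coarse for small collections.
* The motif stage scans user-supplied PWMs only; de novo discovery and
  motif-database matching are out of scope.
* The survival screen is univariate by design (no covariate adjustment, no
  proportional-hazards diagnostics).
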