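# Methods

This note documents the statistical models behind `neuroimmune`, the
choices made where the design was genuinely open, and what the synthetic
generators do and do not emulate.

## Differential expression (desk-scale NB Wald test)

Counts are modeled per gene as negative binomial with shared
median-of-ratios size factors. Size factors use only reference genes with
strictly positive counts in every sample (positive geometric mean). The
Wald statistic is the log2 fold change (case vs control means of
size-factor-normalized counts) divided by a delta-method standard error

    se_ln(g)^2 = (c_ctrl/mu_ctrl + alpha_g)/n_ctrl + (c_case/mu_case + alpha_g)/n_case

where `c` is the group mean of 1/size-factor and `alpha_g` the gene's
dispersion; p-values come from a standard normal reference and are BH
adjusted over tested genes (genes with all-zero counts are excluded; a
group with an all-zero mean gets a 0.5 pseudo-count and is flagged).

Dispersion is estimated per gene by method of moments from pooled
within-group variances, floored at 1e-8. With 3 samples per group a raw
per-gene moment estimate has about 4 degrees of freedom, and the genes
whose variance happens to be underestimated produce severely inflated Wald
statistics — enough to defeat BH control at the smallest p-values. We
therefore additionally floor every gene's dispersion at the **median of the
positive per-gene estimates** (`dispersion_floor="median"`, switchable to
`"none"`). This is a global floor, not empirical-Bayes shrinkage: no gene's
estimate is ever pulled downward. It makes the test conservative for the
less-variable half of the genome, which is the right trade at n = 3. This
is deliberately a transparent desk-scale test; bit-compatibility with full
NB regression packages is not a goal, and its operating characteristics
(null false-discovery proportion, planted-module sensitivity) are verified
by simulation in the test suite.

VST is `log2(count/size_factor + 1)` — the same +1 pseudo-count structure
the surrogate-index formulas use. DEG thresholds are strict inequalities:
padj < 0.05 and |log2FC| > 0.585 (= log2 1.5 to three decimals), with
log2FC > 0 meaning higher in the case group.

## Surrogate indices and robust correlation

Panel scores are **sums** (not means) of VST values, so panel size affects
scale; the indices only ever compare the same panels across samples, where
this is immaterial. `tNLR` and `tSII` are exact formula evaluations; the
identity `tSII = tNLR + log2(Splt + 1)` is property-tested.

"Weighted r" is not a standard named statistic; here it is defined as the
Pearson correlation computed with the final robustness weights of a Huber
M-estimator regression of the index on the hub gene (IRLS, tuning constant
1.345 × MAD scale, tolerance 1e-8, max 50 iterations). Its sign always
matches the robust slope because the same weights define both. The p-value
refers slope/SE to t(n−2); at n = 6 this is approximate and should be read
as indicative. With unit weights the fit reduces exactly to OLS (verified
to 1e-10), and an independent Huber implementation (statsmodels RLM) is
used as a cross-check in the tests, never as the implementation. Gene
symbols are matched case-insensitively with an optional alias table,
because mouse (Stat3) and human (STAT3) conventions are mixed in regulon
libraries.

## TF over-representation and consensus

Enrichment is a one-sided hypergeometric tail P(X ≥ k) over an explicit
universe (in the pipeline: all genes surviving the low-count filter).
Ranking is by ascending p, ties broken by descending odds ratio (Haldane
0.5 correction when a contingency cell is zero) then TF name, making the
top-k boundary deterministic. Consensus is the exact-name intersection of
per-library top-20 lists; an empty intersection is a valid "no consensus"
result. Web-tool enrichment backends are not reproducible offline; this
documented ORA is the testable equivalent, validated against exhaustive
enumeration for all universes up to N = 15.

## Clinical cohort models

* **Gating:** age ≤ 14 years (boundary included), total WBC within a
  configurable age-band upper-limit table (conservative pediatric
  reference values shipped as defaults), and boolean exclusion flags
  (infection, hematologic disorder, recent steroid exposure). Records
  missing required fields are rejected with a reason; per-rule removal
  counts are logged.
* **Indices:** absolute neutrophils = WBC × neutrophil%/100 (likewise
  lymphocytes); NLR = neut/lymph, SII = platelets × NLR. Z-scores are
  pooled across groups with ddof = 1.
* **Summaries:** per-group Shapiro–Wilk at α = 0.05 routes each continuous
  variable to mean (SD) + Welch t or median [IQR] + Mann–Whitney;
  categoricals get counts (%) and chi-square without continuity correction
  (Yates is a flag). Constant variables are flagged, not tested.
* **Logistic models:** one model per z-scored marker, adjusted for age at
  onset, sex and BMI; ML by IRLS (tol 1e-8, max 100 iterations), Wald SEs,
  CI = exp(estimate ± 1.96 SE). Wald intervals are symmetric on the log
  scale; published intervals for small samples may be profile-likelihood
  and hence asymmetric. Separation is detected as a non-finite or
  implausibly large per-SD effect (|coef| × column SD > 15) and raised as
  an error. Complete-case analysis per model.
* **RCS dose–response:** restricted cubic splines in the Harrell
  parameterization, default 4 knots at the 5th/35th/65th/95th percentiles
  (a standard convention; the knot rule is configurable). k knots yield
  1 linear + (k−2) nonlinear columns and linearity beyond the boundary
  knots by construction (verified numerically to < 1e-6 of scale).
  Predictions are at covariate reference values (means / modal level) with
  pointwise Wald CIs mapped through the logistic link.
* **ROC:** AUC via the Mann–Whitney U identity with midrank ties, verified
  against exhaustive pair counting. The combined panel is the in-sample
  logistic linear predictor over the three z-scored markers (the
  combination rule is otherwise unspecified); in-sample, the panel AUC
  cannot fall below the best single marker's.

## Synthetic-data generators

All generators are pure functions of their config (seed included).

**Expression counts.** 3 + 3 samples; gene baselines uniform on
log2 ∈ [3, 9]; NB dispersion 0.05; lognormal size-factor spread (σ = 0.1
on the log scale). A nine-gene inflammatory module (Stat3, Ptx3, and the
seven panel markers) is planted with a case-group effect of
`module_log2fc = 2` (4-fold), scaled per case sample by a latent severity
~N(1, 0.15) — a shared driver is required to induce the hub-index
correlations; independent group shifts would not. Two asymmetries reflect
the biology being emulated: lymphoid markers receive only 25% of the
module effect (an elevated neutrophil-to-lymphocyte ratio *means*
myeloid-dominant activation), and module baselines are floored at
log2 = 5 so the panel survives low-count filtering, as marker genes do in
brain tissue. The hub's baseline and effect are pinned so its WT/case VST
medians center on 10.25 and 11.21; with `module_log2fc = 0` the hub
effect is also disabled and the two groups are exchangeable. The planted
module is 9 of ~2000 genes, so PC1 of the simulated data does not reach
the transcriptome-wide variance fractions seen in real brain data with
global dysregulation — tests of PCA use constructed dominant-axis
fixtures instead.

**Regulon libraries.** Three libraries drawing 50 TFs from a shared
200-name pool; every TF has 50 targets from a 2000-gene universe. The
planted hub appears in all libraries with 30 of its targets inside the
100-gene planted query set (expected chance overlap ≈ 2.5), making it
essentially always the top-ranked TF while non-hub top-20 members rarely
agree across libraries.

**Clinical cohort.** 71 controls (SeLECTS) and 69 cases (DRE). Skewed
variables (age at onset, BMI, WBC, platelets, CRP, NLR) are log-normal
with (median, IQR) quantile matching to the default baseline values
(σ = ΔlogIQR / (2·z₀.₇₅)). Neutrophil and lymphocyte percentages are
derived from the log-normal NLR and a latent granulocyte+lymphocyte total
~N(90, 3) truncated to [60, 98]: sampling the percentages independently
cannot reproduce the NLR medians (ratio distortion), while the derived
split lands within noise of the printed percentage means (≈44.8/45.2
control, ≈49.3/40.7 case). SII = platelets × NLR follows exactly. Sex is
Bernoulli at the printed group proportions. Setting
`outcome_model_coefficients` regenerates group labels from a logistic
model on the pooled z-scored markers, for parameter-recovery tests. The
log-normal tails occasionally produce onset ages above 14 years, which
the gating stage then removes — a few records per simulated cohort.

**Mouse phenotypes.** 24 animals per genotype; group means/SDs: blood NLR
0.26 ± 0.02 (WT) vs 0.54 ± 0.02 (mutant), serum CRP 150.7 ± 16.4 vs
339.4 ± 18.4 ng/mL, serum IL-6 80.8 ± 41.5 vs 206.2 ± 57.9 pg/mL, and
hippocampal p-STAT3 1.0 ± 0.2 vs 2.2 ± 0.2 densitometry units (the
p-STAT3 scale is arbitrary; these values make all three couplings
feasible). `coupling_r` (defaults 0.96 NLR, 0.94 CRP, 0.74 IL-6) is the
**target pooled-genotype Pearson correlation**: the within-genotype
bivariate-normal correlation is solved in closed form from the configured
group moments so that the population pooled correlation equals the
target. Interpreting the coupling within-genotype instead would pin the
pooled correlation near 0.999 given these group separations, so the
pooled reading is the only one consistent with the calibration targets.
Infeasible targets (e.g. pooled 0 under a 14-SD separation) raise a clear
error. CRP/IL-6 negatives are avoided by re-drawing the conditional noise
(rejection), which leaves the p-STAT3 marginal untouched and biases the
low-mean WT IL-6 marginal upward by ~3%; the calibrated (mutant) moments
are ≥3.5 SDs from zero and effectively unaffected.

## What passing tests show — and don't

The simulations verify internal statistical correctness: seeded
reproducibility, type-I error and FDR control under planted nulls,
sensitivity on planted effects, parameter recovery and CI coverage, and
exact agreement with enumeration oracles for BH, hypergeometric tails and
AUC. They do not establish anything about real brain RNA-seq (no batch
effects, GC/length bias, or compositional artifacts), real hematology
(variables are sampled independently within group except where derived),
or real regulon curation. Problem sizes used throughout (2000 genes,
n = 3/group; 200 regulon triplets; 500 logistic replicates at n = 2000;
100–200 mouse seeds) were chosen as the smallest designs at which the
Monte-Carlo error is comfortably below each assertion's tolerance.

## Known limitations

* The Wald-normal reference at n = 3/group relies on the global dispersion
  floor for tail control; power for genes more variable than the median is
  correspondingly reduced.
* "Weighted r" and its t(n−2) p-value are heuristic at n = 6; treat them
  as descriptive, as the robust-correlation literature advises.
* The combined ROC panel is evaluated in-sample; no optimism correction is
  applied.
* The cohort generator draws variables independently within groups (apart
  from the NLR-derived percentages), so multivariable adjustment in the
  simulated cohort is less consequential than in real data.
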