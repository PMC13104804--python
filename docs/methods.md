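# Methods

## The problem and the model

Standard diagnostic machine learning on regional brain volumes selects the
features that best *separate* Alzheimer's disease (AD) from Parkinson's
disease (PD).  This package implements the opposite question: which regions
stay *indistinguishable* between the two diseases — candidate "structural
anchors" of a shared neurodegenerative core — and audits those candidates
with nonparametric statistics.

The scoring pipeline works on the disease-only manifold (AD + PD subjects;
healthy controls are excluded from discovery so the score is not
contaminated by the healthy-vs-disease axis):

1. Three classifier families — a random forest (500 trees, balanced class
   weights), gradient boosting (subsample 0.8, 300 rounds) and L2 logistic
   regression — are fitted to the binary AD/PD task on imputed, z-scored
   features.
2. Each feature receives an importance rank `r_{i,m}` per model
   (1 = most discriminative; impurity importance for the tree ensembles,
   absolute standardized coefficient for the linear model; ties get average
   ranks).  The Borda consensus is the mean rank
   `B_i = (1/M) Σ_m r_{i,m}` with `M = 3`; *high* `B_i` means
   discriminative neutrality.
3. Distributional consistency `ρ_i` is the Spearman correlation of the AD
   and PD value profiles of the feature, after sorting both samples and
   aligning them by quantile (the cohorts contain different subjects, so a
   pairing must be imposed; quantile alignment is the reading under which
   co-monotone samples give exactly ρ = 1).  When sample sizes differ, the
   larger sample is interpolated down to the smaller size.
4. Geometric proximity is the normalized mean difference
   `Δ_i = |mean_AD − mean_PD| / σ_CN`, with `σ_CN` the ddof-1 SD of the
   healthy-control cohort (the only place CN enters discovery).
5. The inversion score is `IIT_i = B_i · ρ_i / (1 + Δ_i)`.  The ten
   highest-scoring features are the anchor candidates; the ten lowest-`B_i`
   features are the bifurcation markers driving AD/PD separation.

The audit hierarchy then tests each region across the three cohorts:
Kruskal–Wallis H (tie-corrected, chi-square p), Dunn's post-hoc z-tests on
joint average ranks with Bonferroni correction over the three cohort pairs,
and a direct two-sided Mann–Whitney U between AD and PD.  A region with
Mann–Whitney `p ≥ α` (default 0.05, boundary inclusive) is a *master
anchor*; a high-scoring region with `p < α` is a *transition pillar*.
Cohen's d (pooled, (n−1)-weighted SD, reported unsigned) quantifies the
AD/PD magnitude gap.

## Feature construction

Input volumes are longitudinal (months 0, 12, 24 by default).  The
Cumulative Structural Integrity Index (CSII) is the per-cell arithmetic
mean of the available time points — `(V0 + V12 + V24)/3` when all three are
present.  It is a noise-reduction device, not a progression model.  Missing
time points fall back to the mean of the observed ones; a fully missing
cell propagates to median imputation.  Sex can be appended as a binary
feature for classification, but never enters anchor scoring, which is
restricted to neuroanatomical descriptors.

Preprocessing is leakage-safe by construction: median imputation and
z-scoring (population-SD convention, ddof = 0) are fit on training rows
only and applied elsewhere; inside cross-validation they live in a pipeline
refit per training fold.  A zero-variance training feature is scaled by 1
with a warning rather than crashing on degenerate synthetic input.

## Benchmarking protocol

The inductive path evaluates the three families on the 3-way (CN/PD/AD)
and binary (PD/AD) tasks under stratified 5-fold cross-validation repeated
over 10 fold seeds.  Hyperparameters are selected per training fold by an
inner 3-fold stratified grid search scored by ROC-AUC (macro one-vs-rest
for three classes).  Default grids are deliberately small: forest max depth
{None, 8} × min leaf {1, 5}; boosting learning rate {0.05, 0.1} × depth
{2, 3}; logistic C {0.01, 0.1, 1, 10}.  Reported metrics (accuracy,
F1-macro, ROC-AUC) and confusion matrices are means over all 50 fold
evaluations.  One seed drives fold assignment, inner CV and stochastic
model fitting, so a seed list fully reproduces a run.

## The synthetic cohort generator

No subject-level clinical data can ship with the package, so the generator
emulates the study conditions: three cohorts of 101 subjects over the 84
regions of the packaged atlas, whose CN/PD/AD mean volumes parameterize the
per-cohort distributions.  Subject latent volumes are zero-truncated
normals with SD = CV × cohort mean; the source table prints no SDs, so
dispersion is a parameter with default CV = 0.12, a plausible morphometric
coefficient of variation.  Each time point adds independent measurement
noise (default CV 0.05) around the constant latent volume — so CSII acts
purely as noise reduction, matching its design.  Missingness is completely
at random.  Sex is Bernoulli(0.5) independent of cohort, with an optional
multiplicative main effect (off by default).

Ground truth can be planted: *anchor regions* make AD reuse the PD
generating distribution exactly; *bifurcation regions* displace the AD mean
below the PD mean by a configured number of pooled-SD units (the AD side
reuses the PD SD so the realized Cohen's d equals the configured value).

What the generator does **not** emulate: progression slopes, site or
scanner effects, intracranial-volume confounding, covariance between
regions (regions are generated independently), or non-normal volume
distributions.  Passing recovery tests therefore demonstrate correctness
of the machinery under the stated generative model, not performance on
real cohort data.

## The recovery experiment and the calibration atlas

Planted-structure recovery is measured on 20 generator seeds at study
scale (84 regions, 101 subjects per cohort, CV 0.12, 5 planted anchors,
10 planted bifurcation regions at d = 1.5): the rates at which all five
anchors land in the top-10 score set, at least 8 of 10 bifurcation regions
land in the 10 lowest-Borda set, anchors are classified master anchors and
bifurcation regions transition pillars (the last two pooled over
region × seed classifications).

Recovery runs on a *calibration atlas* rather than the packaged volumetric
table.  The reason is structural: planting a bifurcation region *sets* its
AD/PD separation to d = 1.5, while 24 of the 84 packaged regions have
natural separation above 1.5 at CV 0.12 (lateral ventricles and entorhinal
cortex approach d ≈ 3.7).  Against that background, planted regions can
never dominate the lowest-Borda set, whatever the implementation does.  A
recovery experiment needs the controlled ordering anchors (0) < background
< planted effect, so the calibration atlas gives all background regions a
uniform intermediate separation (d ≈ 0.7) over a realistic volume range.
The packaged atlas keeps its role everywhere else (simulation defaults,
atrophy arithmetic, worked examples).

## Numerical choices

- **Mann–Whitney p**: exact U distribution when the pooled sample is
  tie-free, otherwise the normal approximation with tie and continuity
  corrections.  The continuity-free approximation errs by up to 0.11
  against exact enumeration at n ≤ 8, which is why it is not used.  Two
  identical samples give exactly p = 1.
- **Dunn's z**: joint average ranks, variance term
  `N(N+1)/12 − Σ(t³−t)/(12(N−1))`, two-sided normal p, Bonferroni × 3
  capped at 1.  Completely tied data short-circuit to z = 0, p = 1.
- **Kruskal–Wallis**: scipy's tie-corrected H with the chi-square
  approximation; all-identical input returns (0, 1) instead of an
  undefined statistic.
- **σ_CN = 0**: Δ is 0 if the AD/PD means agree, +∞ otherwise (score 0).
- **Negative ρ** passes through unclipped; such features can score
  negative and are never selected.
- **Borda scale**: raw mean rank in 1..p.  An optional flag rescales to
  [0, 1]; the raw scale is the default because the score's ordering, not
  its magnitude, drives selection.
- **Selection ties** break by ascending feature name, making runs
  reproducible across platforms.
- **Fold stratification** keeps per-fold cohort counts within one subject
  of the global proportions (303 subjects → folds of 60–61 with 20–21 per
  cohort).

## Problem sizes in the test and acceptance runs

The shipped tests and the acceptance script use scaled-down model settings
(forests of 40–60 trees, single-point or two-point grids) for the
cross-validation calibration checks, and the full study-scale
configuration (n = 101/cohort, 84 regions, 500-tree forests) for the
recovery experiment, which fits models once per seed rather than per fold.
Permutation oracles use 100,000 label permutations; the Mann–Whitney
oracle enumerates all C(10,5) labelings at n = 5 per group.

## Known limitations

- Printed atrophy percentages in the packaged atlas are not all
  arithmetically consistent with the printed means (only 12/84 PDA and
  11/84 ADA rows recompute to the printed value at two decimals); the
  package treats the means as primary and the percentage columns as
  reference output, and worked examples use self-consistent rows.
- The quantile-alignment ρ is close to 1 for continuous unimodal samples
  almost by construction; it acts mainly as a guard against degenerate or
  strongly discretized distributions rather than as a discriminating
  component.
- The paired region-level t-test utility pairs across regions; cohorts
  contain distinct subjects, so no subject-level pairing exists.  It is
  exposed as a utility, not used in the main pipeline.
- Absolute score magnitudes depend on p through the 1..p rank range and
  are not comparable across feature sets of different size.
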