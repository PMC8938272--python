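# Methods

This note documents the models, algorithms and design choices behind
`icibiome`, in the order data flows through the pipeline.

## Data model and IO

Species-level profiles are relative abundances (fractions summing to 1 per
sample) read from the merged-table TSV dialect of common taxonomic profilers:
first column `clade_name` with pipe-delimited taxonomy, one column per
sample. Percentages vs fractions are autodetected: if the median per-sample
column sum exceeds 1.5 the file is treated as percentages. Species rows are
those containing `s__` but no strain marker `t__`; unassigned/unclassified
rows are dropped before renormalization (configurable), and species-level
tables are re-closed after subsetting (renormalization is the default, with
a flag to disable, since profilers report sub-species mass elsewhere).
Gene-family tables use `K#####` identifiers and are not renormalized on
read. Clinical metadata is a TSV keyed by sample id with controlled
vocabularies; unknown categorical values become missing with a warning
rather than dropping the sample, and `performance_status` admits an explicit
`unknown` level.

## Compositional transforms

**CLR.** `x_ij = ln(p'_ij) − mean_j ln(p'_i·)` after zero replacement and
re-closure. Zero handling is the main free choice in CLR pipelines and the
upstream literature rarely states it; the default here replaces zeros by
half the smallest nonzero relative abundance in the table, with an explicit
pseudocount as the alternative. Results for very rare taxa depend on this
choice — flagged here deliberately. Each CLR row sums to zero and the
transform is scale invariant; the Aitchison distance is the Euclidean
distance between CLR rows.

**Count reconstruction.** Count-based models receive
`round(p_ij × total_reads_i)` with round-half-even for cross-platform
determinism. Samples under the 1,000-read library cutoff are flagged and
dropped by the count models.

**ML normalization.** Features with maximum abundance below the cutoff
(1e-4 species, 1e-6 gene families) are dropped; the rest are
`log10(p + pseudocount)` transformed (1e-5 / 1e-9) and z-scored per feature
(sd with denominator n−1). All parameters — retained features, cutoffs,
pseudocounts, per-feature means and sds — are frozen at training time and
applied unchanged to external cohorts: features missing externally are
imputed as zero abundance before the log, and external-only features are
ignored. This makes `transform` exact on the training table and well-defined
on any other cohort.

## Community statistics

**PERMANOVA.** The distance matrix is Gower-centered
(`G = J(−D²/2)J`), and explained sums of squares are partitioned
sequentially (Type I) over an ordered term list via hat-matrix increments;
pseudo-F per term uses the residual of the full model. p values come from
free permutation of sample identity: `p = (1 + #{F_perm ≥ F_obs})/(n_perm+1)`,
identity permutation included by the +1 convention, permutations drawn
without uniqueness enforcement. Term order is part of the model and is
logged. The default is 999 permutations with a config override to 10,000 —
both conventions are common and the cited usage is itself inconsistent, so
the cheaper default was kept with the override documented. A residual that
is zero to rounding (perfectly separated toy fixtures) makes F infinite for
the observed and partition-reproducing permutations alike; F is clamped to
infinity below `1e-12 × total SS` so the permutation comparison is exact
rather than noise-driven.

**Batch correction.** Empirical-Bayes location/scale adjustment of CLR
values (parametric ComBat: normal prior on batch locations, inverse-gamma on
scales, moment-matched), delegated to `scanpy.pp.combat` behind
`eb_batch_correct`. By default only the batch label enters the model; no
covariates are protected (whether to protect them is an open choice in the
upstream procedure; a protected design can be passed through scanpy's
covariate argument if needed). Singleton batches are rejected; a single
batch returns the input unchanged.

**Small-sample tests.** Fisher's exact test (two-sided, hypergeometric) and
Wilcoxon rank-sum tests delegate to scipy; the Wilcoxon path uses exact
enumeration when the pooled sample size is ≤ 20 and tie-free, else the
normal approximation with tie and continuity corrections.

## Differential-abundance ensemble

Effects are always method-native and pooled within one method only.
Features detected in fewer than 10% of a cohort's samples are recorded as
not estimable in that cohort (blank panel cells) rather than forced through
the models.

* **SMD** — Hedges' g on arcsine-square-root abundances:
  `g = J·(m_R − m_NR)/s_pooled`, `J = 1 − 3/(4N−9)`,
  `var = N/(n_R·n_NR) + g²/(2N)`; zero pooled variance flags the feature as
  undefined rather than reporting g = 0 with zero SE.
* **Bias-corrected log-linear model** on reconstructed counts:
  `ln(count+1) = d_i + X_i β_j + ε`. Sample offsets `d_i` (sampling
  fractions) and per-feature OLS coefficients are estimated by alternating
  updates until `max|Δd| < 1e-6` (at most 100 iterations; non-convergence is
  flagged in the output, never silent). The group coefficient is then
  bias-corrected by subtracting its across-feature median — a deterministic,
  robust simplification of the Gaussian-mixture E-M used by the original
  formulation of this estimator, justified when most features are null.
  Inference is a normal z-test with BH q values per cohort and a q < 0.2
  significance gate. The pseudocount is +1 on integer counts.
* **Logit-TSS linear model** — OLS of `logit(p)` on group (+ covariates)
  after total-sum scaling, zeros/ones squeezed by ε = 1e-6 (configurable);
  classical SEs, t-test p. Rank-deficient designs are rejected with the
  aliased columns named.
* **Wilcoxon** — two-tailed rank-sum p per feature; no effect/SE, so it
  feeds the panel's per-cohort cells and directions but is never pooled.

Effect direction is always the comparison of group mean relative abundances
(responder-up vs responder-down), independent of the model's coefficient
sign convention. Ensemble members based on negative-binomial or
zero-inflation machinery are accepted as plug-in TSVs (`plugin:<name>`)
but not reimplemented.

## Random-effects meta-analysis and the consensus panel

Per feature and method, cohort effects are pooled under
`θ_k ~ N(μ, v_k + τ²)`. τ² is estimated by REML Fisher scoring
(`τ² ← τ² + (θ'PPθ − tr P)/tr(PP)` with `P = W − W11'W/1'W1`), clamped at
zero, matching the standard REML meta-analysis estimator to ~1e-6 (verified
against an independent R implementation in the tests); the DerSimonian–Laird
closed form is available as an alternative. Inference on μ is a Wald z-test
with inverse-variance weights — not Knapp–Hartung, matching the cited
implementation's default. BH correction is applied within method across
features; the panel rule counts methods with *unadjusted* random-effects
p < 0.05 (as the consensus figure defines it), with q reported alongside.
Features estimable in at least 2 cohorts enter pooling (k is recorded);
with the three implemented methods the species default `min_methods = 3`
requires all of them, and the gene-family default of 6 requires plug-in
members, raising a clear error otherwise.

## Machine-learning framework

One *bundle* = repeats × folds lasso logistic models plus the frozen
normalization of the training cohort. Per outer fold, λ is selected by
5-fold inner CV on the training portion over a 30-point descending
log-spaced grid anchored at the largest λ keeping any coefficient nonzero
(via `l1_min_c`); candidates are refit on the full training fold in
descending inner-AUC order (ties prefer the sparser model) until the refit
retains ≥ 5 nonzero coefficients, else the densest feasible model is used
and logged. How to combine nested CV-based selection with the ≥5-coefficient
constraint is ambiguous in the upstream description; this is one consistent
reading, enforced on the refit training-fold model. Within-cohort AUC pools
held-out predictions per repeat and reports the median over repeats.
External cohorts are scored by the per-sample median predicted probability
over all models (median of probabilities, not decision scores; the logistic
link is monotone so per-model AUC is unaffected, and the median of
probabilities is what the upstream procedure states). LODO pools all
remaining cohorts with `merge_cohorts` (union of features, zeros for absent
ones) and runs the identical machinery. Stratified splits come from
scikit-learn's stratified K-fold with per-repeat seeds derived from the root
seed via `SeedSequence`, making every split, λ choice and AUC reproducible
bit-for-bit from one integer.

Release-scale settings are 100 repeats × 5 folds (500 models); the bundled
tests and the acceptance script run 10 repeats × 5 folds (50 models), which
leaves the median-AUC estimates stable on the synthetic studies while
keeping the suite's runtime practical.

## Synthetic multi-cohort generator

Per feature j: baseline log abundance `b_j ~ N(0, 2²)`, prevalence
`π_j ~ U(0.15, 0.95)`, within-cohort residual sd
`σ_j = 0.8·U(0.8, 1.2)`. Per cohort c: batch location
`δ_cj ~ N(0, 1.5²)` and scale factor `exp(N(0, 0.25²))` multiplying σ.
Sample i's log abundance is
`b_j + δ_cj + effect_j·R_i + Σ covariate shifts + σ noise`; presence is an
independent Bernoulli(π_j) draw, absent features are zero, and each sample
is closed to sum 1. Total reads are LogNormal(ln 1e7, 0.4). ORR responders
are drawn per cohort at rate 0.55 (the responder fraction of the bundled
clinical table); PFS12 derives from ORR by one-way responder→nonresponder
flips at probability 0.1 (patients progressing between months 6 and 12 —
the concordant fraction in the clinical table is ≈ 0.91). Clinical
covariates mirror the metadata schema (gender, age, BMI, performance
status, previous therapy, PPI/antibiotics/steroids, toxicity, colitis, ICI
regimen, four diet indices); a covariate spec can link any of them to
feature sets with a log-scale effect. Gene-family tables are the closure of
`species @ W` for a sparse nonnegative contribution matrix W (~3–7
contributing species per function) times log-normal noise, so planted
species signal propagates to linked functions.

Calibration. Two generator-level targets define the reference study
conditions: (i) the cohort term explains roughly ten times more PERMANOVA
variance than any clinical covariate (achieved at batch location sd 1.5);
(ii) a log-scale effect of 1.0 planted in 20 of 300 species at prevalence
U(0.85, 0.98) is weak at the whole-community level (response R² < 1%) yet
recoverable by the downstream consensus panel at ~85% with a few-percent
false-positive rate. Planted features' baselines are drawn `N(0, 1)` rather
than `N(0, 2)`: if a planted feature dominates the community, shifting it
imprints a closure artifact of opposite sign on every other feature, which
is a genuine compositional phenomenon but makes "false positives" a
property of the truth labels rather than of the methods. There are no
published quantitative responder effect sizes to target; these choices
reproduce the qualitative structure (variance ordering, weak signal,
imperfect cross-cohort reproducibility) rather than any printed magnitude.

What the generator does *not* emulate: read-level sequencing noise,
taxon–taxon correlation structure beyond closure, strain-level variation,
cohort-specific prevalence shifts (batch effects act on abundance, not
presence), non-random missingness of metadata, and signal heterogeneity
across cohorts (the planted effect is identical everywhere — one reason
cross-study transfer on synthetic data is easier than on real cohorts).
Passing tests therefore demonstrate correctness of the machinery under the
assumed generative structure, not expected performance on real data.

## Numerical choices and degenerate inputs

Round-half-even count reconstruction; z-scores with ddof=1; logit squeeze
ε=1e-6; CLR zero replacement as above; PERMANOVA infinite-F clamp as above;
REML τ² clamped to 0 below 1e-8 of the mean sampling variance; Wald CIs at
z = 1.96. All-zero samples, singleton batches, single-class label vectors,
constant model terms, rank-deficient designs, intercept-only count models,
and zero retained features all raise informative errors rather than
propagating NaNs. Every stochastic component accepts one root seed and
derives independent streams via `SeedSequence.spawn`.

## Known limitations

Permuted-label (null) cross-validation with this framework is slightly
*pessimistic*, not neutral: at cohort-scale sample sizes (n ≈ 60) the
≥5-nonzero-coefficient constraint forces each training-fold model to use the
fold's most label-correlated noise features, whose association inverts on
the held-out portion of a finite fixed sample — the well-documented
below-chance ("anti-learning") behavior of cross-validated selection at
small n. Median null CV AUC measures ≈ 0.43 rather than 0.50 on a
60-sample, 200-feature null fixture; the effect is not an information leak
(leaks bias upward), is unchanged by fold-averaged versus pooled-prediction
AUC and by narrower λ grids, and shrinks as n grows. Observed AUCs just
above 0.5 on real cohorts of this size are therefore conservative rather
than optimistic.

The bias-corrected log-linear model is a simplification of the full
published estimator (median bias correction, no structural-zero detection —
the upstream analysis also disabled it). The panel with only three
implemented pooled methods is stricter than an eight-member ensemble at the
same `min_methods = 3`. Synthetic transfer AUCs exceed what real cohorts
show because planted signals are homogeneous across cohorts and batch
location shifts do not perturb within-cohort ranking. PERMANOVA assumes
exchangeability under free permutation; no restricted permutation schemes
are provided. Dispersion tests, UniFrac distances, survival models and
Bayesian compositional models are out of scope.
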