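# Methods

## Overview

`mtorsig` builds a predictive biomarker of everolimus response in two fitted
models: an in vitro probit metagene signature (`SignatureModel`) and an
integrative patient-level random forest (`IntegrativeModel`), connected by
the signature gene set. This note documents the models, their assumptions,
the defaults, the synthetic-data conditions, and the numerical choices.

## Preprocessing

* **Low-information filter.** Genes whose across-sample variance falls at or
  below the 25th percentile of all gene variances, or whose mean expression
  falls at or below the 30th percentile of all gene means, are removed
  (union of the two rules, applied jointly on the unfiltered statistics).
  Percentiles use the linear-interpolation convention and the boundary is
  inclusive, which makes the 0-percentile case well defined (only exactly
  minimal genes can be removed). Whether the two filters should instead be
  applied sequentially is undecidable from the method's description; the
  joint rule is the package's choice.
* **Quantile normalization.** The reference distribution is the per-rank
  mean of the column-sorted values; each column is replaced by reference
  values at its within-column ranks, tied values receiving the mean of the
  tied reference positions. The reference is frozen into the fitted
  signature so held-out or external samples can be projected onto the
  training normalization without refitting — this is what keeps the
  cell-line LOOCV leakage-free.
* **Standardization.** Per gene: subtract the mean, divide by the sample
  standard deviation (n−1). Constant genes cannot be standardized and are
  dropped with a warning, so downstream correlation and entropy
  computations never see zero-variance predictors.
* **Probe/replicate aggregation** (microarray inputs): probes are averaged
  to genes first, then replicate columns to subjects — the order matters
  when probe counts differ between replicates.

## In vitro signature

Given filtered, quantile-normalized expression for treated/control samples:

1. **Gene selection.** Genes are ranked by Pearson correlation with the
   0/1 treatment label; the 50 most positively and 50 most negatively
   correlated genes form the signature (default size 100). The balanced
   split reflects that the signature represents both up- and down-regulated
   response genes; ties break lexicographically by gene id so selection is
   order-invariant.
2. **Metagenes.** The signature submatrix is centered per gene and
   decomposed by SVD; the first k = 2 left singular vectors are the
   metagene loadings and the per-sample scores are the projections (right
   singular vectors scaled by singular values). Sign convention: each
   loading column's largest-magnitude entry is made positive, for
   determinism across linear-algebra backends. A numerically rank-deficient
   submatrix yields zero trailing score columns rather than an error.
3. **Probit regression.** Treatment status is regressed on the metagene
   scores with a probit link under β ~ N(0, τ²I), τ² = 100 (diffuse proper
   prior keeping the updates conjugate), intercept included. The
   Albert–Chib Gibbs sampler alternates truncated-normal latent draws
   (inverse-CDF sampling with probabilities clipped to [1e−12, 1−1e−12])
   and conjugate normal coefficient draws. Defaults: 5,000 iterations,
   1,000 burn-in, seed 17; identical seeds give bitwise-identical chains.
   Predictions average Φ(x'β) over post-burn-in draws; 95% intervals are
   the 2.5/97.5 percentiles of the draw-level probabilities. Classification
   threshold is p = 0.5.

Cell-line LOOCV re-runs normalization, selection, metagene computation and
the probit fit per fold; the held-out sample is projected onto the fold's
frozen reference.

## FCBF

Expression is discretized per feature by a binary median split (ties go
low); entropies are plug-in estimates in bits with 0·log 0 := 0, and
SU(X,Y) = 2·I(X;Y)/(H(X)+H(Y)) (0 when both entropies vanish). Selection
keeps features with SU-to-class ≥ δ (default 0.25, the conventional
relevance threshold; the original analysis does not state its value or its
discretization, so both are config and documented as unverifiable), ranked
decreasingly with id tie-breaks, then prunes by predominance: walking the
list, a later feature q is removed when SU(p, q) ≥ SU(q, class) for the
current predominant feature p. `fcbf_select_reference` is a deliberately
unoptimized transcription of the same definition kept as an independent
oracle; the optimized path must agree with it exactly.

## Integrative classifier

* **Response labels.** Responder ⇔ relative Ki67 decrease
  100·(pre−post)/pre strictly greater than 10%. Whether the published rule
  meant relative or absolute percentage points is ambiguous; relative is
  the default and `relative=False` switches to absolute points.
* **Feature fusion.** Per training fold: FCBF genes ∪ signature genes
  present on the platform, deduplicated, in vitro genes first, provenance
  recorded.
* **Forest.** 500 trees; `mtry` (scikit-learn `max_features`) tuned over
  all integers 2..min(15, p) by default via repeated stratified k-fold CV
  (5 folds × 5 repeats) on the training fold only; ties prefer smaller
  `mtry`; the forest is refit on the whole training fold at the chosen
  value. Class probability is the tree-vote fraction.
* **Leakage control.** The held-out patient is excluded before
  discretization thresholds, FCBF, fusion, tuning and training. Training
  columns are put in a canonical (sorted-by-id) order and per-fold seeds
  are derived as SHA-256(global seed, held-out id) mod 2³¹, so out-of-fold
  results are invariant to the column order of the input matrix.
* **External scoring.** Cohorts are standardized per gene within the
  cohort; model genes missing from the cohort are imputed as standardized 0
  up to a 20% cap (beyond which scoring fails) — cross-platform transfer is
  inherent to the design, but the cap bounds silent degradation. Group
  comparison: one-way ANOVA with Tukey's HSD (studentized-range adjusted
  pairwise p-values), plus the per-group fraction of samples above the 0.75
  high-response cutoff. When group means coincide exactly, floating-point
  cancellation can make the F statistic fractionally negative; it is
  clamped at 0 and the p-value recomputed from the F distribution.

## Synthetic study conditions

The generators' defaults are the study conditions the pipeline is validated
under, not tuning knobs:

* **Cell lines:** 9 lines × 2 conditions, 5,000 genes, 200 responsive genes
  (half up, half down) at effect size δ = 1.5 log2 units; per-gene baseline
  N(6, 2), per-line effect N(0, 0.5) shared by both conditions of a line,
  residual noise N(0, 0.3). Noise scales are the package's choice of a
  realistic log-scale spread for a controlled in vitro design.
* **Patients:** 23 patients, 5,000 genes, 10 informative genes at effect
  size d = 2.0 (half of them drawn from the in vitro signature so the
  integration step sees true overlap), one redundant near-copy per
  informative gene (parent + N(0, 0.1)), response rate 0.5, noise N(0, 1).
  Ki67 pairs are generated label-consistently (responders: planted relative
  decrease 20–80%; non-responders: −10% to +10%), so labeling and
  modelling are decoupled in tests.
* **External cohort:** 3 groups × 50 samples whose informative-gene shifts
  scale with per-group means (0/1/2 by default), reusing the patient
  truth's genes and directions.

Simulation is Normal noise in log space with a single documented RNG
(NumPy `default_rng`); count-level realism, probe-level structure, batch
effects and platform-transfer noise beyond the missing-gene mechanism are
deliberately out of scope. Passing tests on these conditions demonstrate
the machinery (selection, leakage control, calibration of the workflow),
not clinical performance on real cohorts.

## Problem sizes used in validation runs

Full-scale `mtry` tuning (500-tree forests across a 14-value grid × 25
inner folds × 23 outer folds) is a cluster-scale computation; the package's
validation runs keep the final (per-fold and full-data) forests at 500
trees but tune with 100-tree forests over the grid (2, 4, 6, 8, 10, 12, 14),
which brackets the optimum reported for this design while keeping a full
patient LOOCV in minutes on one core. The anti-leakage null check (planted
effect 0) uses an even lighter tuning configuration, since leakage would
inflate out-of-fold accuracy regardless of tuning quality.

## Known limitations

* The probit sampler assumes the metagene design is well conditioned; a
  constant score column is rejected rather than regularized away.
* FCBF's binary median split discards within-half expression ordering;
  multi-bin MDL discretization is out of scope.
* The serialized signature stores full posterior draws in JSON; for very
  long chains an array container would be preferable.
* External-cohort scoring assumes the cohort is (or can be) standardized
  per gene within the cohort; no cross-platform renormalization beyond
  that is attempted.
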