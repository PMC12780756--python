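# Methods

`hetforest` implements the full heterogeneous-treatment-effect workflow used
in register-based epidemiology to ask *who* is most affected by a childhood
exposure — here, type 1 diabetes (T1D) diagnosed at school ages — across six
adult outcomes: death by age 30, antidepressant purchase, continuous
singlehood, basic-education-only, annualized unemployment months, and annual
income. Because the underlying total-population registers are confidential,
the package pairs the estimation machinery with a synthetic cohort generator
calibrated to the published descriptive margins of the design it emulates
(3048 cases, ~79,000 stratum-matched controls).

## The estimand and the causal forest

The estimand is the conditional average treatment effect (CATE)

    tau(x) = E[Y(1) - Y(0) | X = x],

the expected difference in adult potential outcomes given the childhood
covariates x. Estimation follows the generalized-random-forest construction
with local centering:

1. **Local centering.** Honest regression forests estimate the outcome
   surface m(x) = E[Y|X=x] and the propensity e(x) = E[W|X=x]; every
   person's fit is out-of-bag (only trees whose subsample excluded the
   person contribute). Residuals y~ = Y - m(X), w~ = W - e(X) remove the
   confounded parts of outcome and treatment before any effect is
   estimated. Propensity estimates are clipped to [0.01, 0.99]; the design
   propensity of a 1:26 matched cohort is ~3.7%, so the clip is inert for
   the bulk of the data and only guards degenerate leaves.

2. **Honest causal trees.** Each tree draws a half-sample without
   replacement and splits it into a structure half (J1) and an estimation
   half (J2). Node splits are chosen on J1 by gradient pseudo-outcomes:
   with the node solution tau_P = sum(w~ y~)/sum(w~^2) and A_P =
   mean(w~^2), each row carries rho_i = w~_i (y~_i - w~_i tau_P)/A_P, and
   the split maximizes (sum_L rho)^2/n_L + (sum_R rho)^2/n_R over all
   midpoints of consecutive sorted J1 values — the sample-size-aware
   between-child heterogeneity criterion. A split is admissible only if
   both children keep `min_node_size` rows in *both* honest halves. Ties
   break to the lowest covariate index, then the lowest threshold, making
   trees reproducible. Leaves store J2 members only; structure never sees
   J2 responses (honesty).

3. **Forest weights and prediction.** For a query x, every tree containing
   x in a leaf contributes weight 1/(B' |leaf|) to each J2 member of that
   leaf (B' = number of usable trees; training rows use only trees that
   excluded them). The CATE is the weighted residual-on-residual
   regression tau(x) = sum_i alpha_i(x) w~_i y~_i / sum_i alpha_i(x) w~_i^2.
   Queries with zero weighted treatment variance fall back to the
   forest-wide residual regression (logged).

4. **Average effects.** Per-person AIPW scores
   Gamma_i = tau_i + (W_i - e_i)/(e_i(1-e_i)) (Y_i - m_i - (W_i - e_i) tau_i)
   are doubly robust: their conditional mean is tau(x) if either nuisance is
   correct. The ATE is the mean score with se = sd/sqrt(n); the effect on
   the treated (ATT) uses propensity weights h_i = e_i on the same scores —
   the standard doubly robust ATT weighting, chosen here because the
   emulated study names AIPW and the treated-effect target without printing
   a formula, and validated by simulation (the constant-effect and
   double-robustness tests). CIs are normal 95% bands.

5. **Pilot/final screening.** With 38 candidate modifiers, a pilot forest
   on all covariates computes depth-decayed split-frequency importance
   (importance_v = sum_d d^-2 splits(v,d)/splits(d), d <= 4, normalized);
   covariates at or above the mean importance are retained and the final
   forest re-fits on that subset with identical hyperparameters. Split
   frequency favors continuous covariates (they offer many cut points), so
   a binary modifier can rank mid-field yet still pass the >= mean screen —
   the behavior observed for sex in the antidepressant analysis.

6. **Cross-fitted quartile ranks.** The sample is split into K = 10 random
   folds; each fold's CATEs are predicted by the full centering+pilot+final
   pipeline trained on the other nine folds, so nobody's outcome influences
   their own rank. Pooled predictions are cut at the empirical quartiles
   (rank 1 = "low effect", rank 4 = "high effect"); ties break by row order
   so group sizes differ by at most 3. The per-fold-quartile alternative is
   available via `pooled_cut=False`. Rank groups are profiled by covariate
   means and by standardized mean differences,
   SMD = (mean_4 - mean_1)/sqrt((s_1^2 + s_4^2)/2), positive when a
   covariate is more prevalent in the most vulnerable quartile.

Per-outcome analysis samples mirror the register design's conditioning:
mortality uses everyone; the other outcomes drop the deceased; the
prescription and income outcomes additionally drop the 1990 birth cohort
(register follow-up ends before their outcome window). This
conditional-on-survival reading carries the same selection caveat as the
design it emulates.

## Hyperparameters

| parameter | default | role |
|---|---|---|
| `n_trees` | 500 | forest size; large-cohort preset 200 |
| `subsample_fraction` | 0.5 | rows per tree, drawn without replacement |
| `honesty_fraction` | 0.5 | share of each subsample used for structure (J1) |
| `min_node_size` | 5 | per-child minimum in both honest halves; large-cohort preset 50 |
| `mtry` | ceil(sqrt(p)) | candidate covariates per split |
| `clip_epsilon` | 0.01 | propensity clipping bound |

Automatic cross-validated tuning is deliberately not implemented; the fixed
defaults above follow the standard generalized-random-forest construction
and every value is config-overridable. For full-size (~80k row) runs the
`LARGE_COHORT` preset (200 trees, min node 50) — and, inside the acceptance
suite, a 100-tree/min-node-100 configuration — keep a
single-CPU analysis of one outcome in the minutes range; the detection
margins involved (a 6-probability-point sex interaction at n ≈ 79k) are far
above what these forest sizes resolve, which the full-size acceptance test
verifies directly.

## The synthetic cohort generator

The generator emulates the *design*, not the disease biology:

* **Covariates.** 38 baseline covariates measured at age 6 (individual,
  parent, household, postcode level, plus region, remoteness, birth year).
  Cross-correlations are induced solely by a single latent family-SES
  factor Z ~ N(0,1) with per-covariate loadings; marginal means are
  preserved analytically (Gauss-Hermite intercepts for Bernoulli
  covariates, mean-preserving tilts for Poisson, exact quantile thresholds
  for ordinals). One latent factor is the minimal structure that supports
  an SES-modified effect; real register data have richer dependence.
  Missing fathers are imputed to reference values with a missing-parent
  indicator, mirroring the analysis convention of the emulated study.
* **Treatment.** Exactly `n_treated` cases are drawn by exponentially
  tilted sampling without replacement (Gumbel top-k), reproducing the
  published mild imbalances: more prior hospital visits, more household
  diabetes, slightly more boys and later cohorts among cases. The case
  count is fixed because the emulated design has a fixed case count;
  Bernoulli assignment would randomize it.
* **Outcomes.** Binary outcomes are logistic in the observed SES index,
  sex and cohort with an *additive on the probability scale* treatment
  effect tau(x); unemployment is a zero-inflated scaled Beta(0.9, 2.1) on
  [0, 12] months whose occupancy probability shifts so the effect is
  additive in expected months; income is log-normal with a multiplicative
  treatment shift, then rounded to €100 and top-coded at €150,000
  (the true disclosure cap is unpublished; 150k is a round, rarely-binding
  choice). Mortality is drawn first; survivors get the other outcomes.
* **Ground-truth heterogeneity.** By default the antidepressant effect
  carries +6 probability points for women and the partnership effect
  -2 points per SD of the observed family-SES index. These sizes are not
  published quantities; they are chosen so the published qualitative
  pattern (a largely female high-effect group; low-SES families
  over-represented among the unpartnered-vulnerable) is detectable by the
  quartile analysis at the design's sample size without being trivial.
* **Calibration.** Intercepts and mean effect sizes are solved
  numerically (Brent's method on analytic conditional means, including
  survival weighting, censoring and the income cap) against the published
  group means over the covariate distribution of an internally generated,
  fixed-seed calibration cohort run through the same exclusion and
  matching stages. Calibration error is therefore limited to covariate
  Monte-Carlo error of one design-size draw, an order of magnitude below
  per-run outcome sampling noise.
* **Exclusions.** Flags for pre-age-7 diagnosis, missing covariates, and
  death/emigration before 18 are generated at rates matching the published
  exclusion counts' proportions (0.25%, 0.81%, 0.21%, 1.15%); they exist
  so the matching stage's filters are exercised, not as a demographic
  model. A person excluded for several reasons is counted once, at the
  first rule in that order.

What passing the calibration tests shows: the generator reproduces the
published margins and supports the published qualitative heterogeneity
patterns. What it does not show: anything about real T1D etiology, register
linkage error, geographic structure beyond labels, or covariate dependence
beyond one factor.

## Matching

Controls are matched on (region, sex, birth year) by stratum-level pooled
sampling: a stratum with c cases contributes min(26 c, available) controls,
drawn uniformly without replacement from its own RNG stream keyed by
(seed, region, sex, birth year) — results are invariant to row order. The
emulated study says "up to 26 controls ... fewer if the stratum size was
smaller", which pooling reproduces; whether the original matched per case
or per stratum is not stated, and pooled sampling is equivalent in
distribution when controls are exchangeable within a stratum. The default
control pool (180,000) emulates drawing from a much larger source
population, so nearly every stratum saturates its cap and the matched
control count lands at ~79k.

## Numerical and reproducibility choices

* One master seed derives all streams (covariates, treatment, outcomes,
  matching, folds, trees) through fixed-purpose `SeedSequence` keys;
  identical seeds give bit-identical outputs.
* Candidate thresholds are midpoints of consecutive sorted J1 values,
  guarded against floating-point midpoint collapse (a midpoint that
  rounds onto the right value falls back to the left value); partition is
  by `x <= threshold`.
* Tree growth is exact (no threshold subsampling): a presort-based kernel
  keeps per-feature sorted index/value lists through stable partitions, so
  the exhaustive scan is linear per node. The split search is
  property-tested against a brute-force maximizer.
* Degenerate inputs: constant targets short-circuit; nodes without
  residual treatment variation become leaves; all-treated or all-control
  inputs raise; rows with no out-of-bag trees fall back to the training
  mean (regression) or raise (weights).
* Test-suite problem sizes are scaled-down versions of each property's
  natural size (e.g., 200 replications for CI calibration at n = 2000,
  one full-size seed for heterogeneity detection); each test states the
  size it uses.
* Under a constant-effect design the rank-quartile CIs are nominally
  calibrated, and there is no positive rank-4 excess. A small *negative*
  rank-4 minus rank-1 dependence (order 4% of the effect at n = 2000) is
  expected: the AIPW nuisances and the ranking forests share training
  data, which induces a slight conservative anticorrelation. It shrinks
  with sample size and never manufactures spurious heterogeneity.

## Known limitations

* Split-frequency importance is biased toward continuous covariates; the
  >= mean screen absorbs this, but importance *rankings* should not be
  over-read — the rank-group SMD profile is the primary heterogeneity
  readout.
* CATE variance estimation (bootstrap of little bags) is not implemented;
  uncertainty is reported only for aggregated (AIPW) effects, matching the
  emulated study's reporting.
* The mortality outcome conditions nothing, but all other outcomes are
  survivor-conditional; no principal-stratification correction is applied.
* No multiple-testing correction across outcomes (none is applied in the
  emulated analysis); no multi-arm or continuous treatments; no surrogate
  splits for missing covariates (the generator encodes missingness as an
  indicator instead).
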