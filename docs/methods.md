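# Methods

## Setting

The package targets prediction problems with three interacting difficulties:
a rare binary endpoint, a high-dimensional biomarker panel measured only on
a two-phase subsample, and the need to report performance for the *full
cohort* rather than for the artificial case-enriched subsample. The
canonical design it emulates is a nested case-control biomarker study
inside a prevention trial: the cohort is stratified (here by BMI level
crossed with race/ethnicity), every case enters phase two, and five
controls per case are drawn per stratum without replacement. The
phase-two analysis set is then roughly 25 cases and 125 controls facing
hundreds of markers.

## Inverse-probability-weighted CV-AUC

Each phase-two subject carries the inverse of its realized sampling
probability: 1 for cases, (cohort controls in stratum)/(sampled controls
in stratum) for controls. These weights are recomputed from the realized
sampling fractions rather than from the nominal 1:5 ratio, so
Horvitz-Thompson control totals are exact per stratum by construction.

Prediction performance is the weighted pairwise AUC

    AUC_w = Σ_i Σ_j w_i w_j [ I(P_i > P_j) + ½ I(P_i = P_j) ] / Σ_i Σ_j w_i w_j ,

with cases i, controls j. Ties receive half credit; this is what makes a
constant-score model attain exactly the theoretical null value 0.5, which
the evaluation harness asserts.

Cross-validation is 5-fold, stratified by case status (every training
split then has the identical 20/100 composition), repeated with distinct
fold seeds; replicate r uses seed `base_seed + r`. Each replicate's
out-of-fold scores are pooled into one weighted AUC (one number per
replicate, averaged at the end); per-fold averaging is available as
`pooling="per-fold"` because the literature is not unanimous on which of
the two "K-fold CV-AUC" denotes. All model variants evaluated together
share fold plans per replicate, so per-replicate differences are paired
and Wilcoxon signed-rank comparisons across replicates are valid. The
degenerate all-zero-differences case reports p = 1 by convention.

## Variable screening

Screening is an L1-penalized logistic regression of the outcome on the
candidate markers plus the clinical covariates, fit inside each training
fold only. The clinical covariates are forced: they are effectively
unpenalized and always retained. Markers with zero coefficients at the
CV-selected penalty are dropped. Choices that the problem leaves open,
with our defaults:

- penalty selection: inner 5-fold CV minimizing held-out weighted binomial
  deviance (`min-deviance`); the one-standard-error rule is available and
  selects markedly sparser sets.  In our experiments min-deviance is the
  safer default for prediction pipelines (the 1-SE rule can prune down to
  the covariates on weak-signal phase-two draws), while the 1-SE rule is
  the right tool when the *selected support* is the object of interest;
- the screening likelihood is IPW-weighted by default
  (`use_ipw_in_screening`), consistent with every other training step.
  Note one caveat observed at phase-two sample sizes: a handful of
  high-weight controls can dominate the held-out weighted deviance and
  bias penalty selection toward the null model on some draws; switching
  the selection criterion to unweighted deviance is one mitigation;
- features are standardized to unit variance on the training fold inside
  the fit;
- the penalty path is scanned from the data-driven maximum downward and
  stops early once the CV deviance has risen for three consecutive grid
  points (after at least 60% of the grid) or the support exceeds `dfmax`
  (default `max(50, n/2)`): the dense end of the path is useless for
  screening and dominates the fit cost.

The unpenalized status of forced covariates is implemented by rescaling
their standardized columns by 1e4, which divides their effective L1
penalty by the same factor; the test suite checks this against an exact
per-parameter-penalty fit (statsmodels elastic net with alpha = 0 on the
forced columns) and against full-shrinkage behaviour at extreme penalties.

## Forests and ensemble-level bootstraps

Trees are Gini-split CART classifiers grown to maximal depth without
pruning (`min_node_size` = 1), with `mtry` = ⌊√p⌋ candidate features per
split and 500 trees by default — the classification defaults of the
widely used forest implementations. The ensemble score of an observation
is the fraction of trees voting "case".

Class balancing and design weighting enter through the per-tree bootstrap:

- standard: uniform, full-size, with replacement;
- under-sampling: case draw weight = n_controls/n_cases (5 on a 20/100
  fold), draw count 2·n_cases (40 of 120) — each tree sees ≈20 cases and
  ≈20 controls;
- over-sampling: cases duplicated (with replacement, once per forest) up
  to the control count, then uniform full-size bootstraps of the 200-row
  augmented set — ≈100/100 per tree;
- IPW: draw probability proportional to the design weight, full-size
  draw.

In-bag membership is recorded per tree in the original row space (a
duplicated case is in-bag if any copy is drawn), which makes out-of-bag
statistics well defined under every scheme.

OOB-AUC scores each training row using only the trees whose bootstrap
excluded it, and is deliberately *unweighted*: this mirrors how forest
tuning criteria are computed in practice and is precisely why tuning can
disagree with the IPW-weighted CV-AUC used for final evaluation.

## Hyperparameter tuning

`tune_forest` evaluates a fixed budget of 50-100 configurations over
mtry ∈ [1, p], min_node_size ∈ [1, n/2] and sample_fraction ∈ [0.2, 1],
maximizing OOB-AUC. The search is a seeded Latin-hypercube stage (60% of
the budget) followed by refinement proposals from a quadratic surrogate
fitted to the evaluations so far; the budget contract (exactly `budget`
evaluations, argmax returned) is what matters, not the optimizer's
internals. All candidate configurations share one fit seed so that OOB
differences reflect the hyperparameters, and argmax ties break toward
smaller mtry, then smaller min_node_size (the less complex model).

## GLM

The linear candidate is a logistic regression maximizing the IPW-weighted
log-likelihood (statsmodels GLM with prior weights, the analogue of a
weighted `glm` fit). Aliased columns are dropped via pivoted QR with a
warning. Small case-enriched folds can be separable; a fit with
non-finite or absurdly large coefficients falls back to a
barely-regularized ridge fit (penalty 1e-8) with a warning.

## Stacking

Candidates (forest or GLM pipelines, each with its own marker set and
screening) are run through an inner 10-fold stratified loop on the
training fold to produce out-of-sample scores; a logistic meta-learner
with free intercept and slopes bounded at zero combines them (L-BFGS-B,
analytic gradients, projected-gradient tolerance 1e-8). The meta fit is
unweighted by default (`use_ipw_meta` switches it), and candidates are
refit on the full training fold for test-time prediction — the standard
stacked-generalization arrangement. Nonnegativity keeps an anti-correlated
candidate from being exploited with a negative weight; stratification of
the inner folds matters because ~20 cases spread over 10 folds would
otherwise regularly produce case-free folds. The Pearson correlation
between candidate score columns is reported alongside, because stacking
is only expected to pay off when the candidates disagree.

## Synthetic cohorts

The generator is the package's test bed and defines its study conditions:

- cohort of 2500 subjects at a calibrated 1% case rate → 25 expected
  cases, phase-two ≈ 25 cases + 125 controls;
- 6 strata (3 BMI levels × 2 race/ethnicity groups), BMI covariate
  coherent with its stratum level, strata independent of markers;
- 420 markers (120 T-cell + 300 antibody), multivariate normal with
  exchangeable correlation 0.3 inside blocks of 20 consecutive columns;
- outcome from a logistic model: covariate effects plus linear effects on
  the antibody signal markers plus linear-and-pairwise-product effects on
  the T-cell signal markers; the intercept is solved by root finding so
  the mean event probability equals the target case rate exactly;
- signal markers sit on the first columns of successive blocks, so each
  informative marker drags correlated noise along — the situation lasso
  screening has to survive.

What the generator does *not* emulate: real immunoassay marginals
(bimodality, detection limits, heavy tails), marker-stratum confounding,
and any time-to-event structure. Passing tests therefore demonstrate that
the machinery behaves as designed under a known generating model, not
that any particular biological dataset will reproduce a given ranking of
methods.

Three named scenarios are frozen for the qualitative experiments:

- the default study-like scenario above (diffuse moderate signal, 0.7 per
  SD over 8 markers);
- `screening_grid_scenario`: two strong antibody correlates (1.5 per SD) plus six
  weak T-cell markers (0.35) among 412 noise columns — the regime where
  unscreened forests are noise-diluted (screening and class balancing
  have room to help) while the screen can isolate the dominant markers;
  used for the screening × balancing grid checks with the 1-SE rule;
- `disjoint_signal_config`: 2000 subjects analysed in full (weights 1),
  10 + 10 markers, antibody signal purely linear, T-cell signal purely
  interaction (linear terms zeroed), so a GLM is the right model on one
  set and a forest on the other; used for the model-comparison and
  stacking experiments.

### A reproducible negative result: IPW bootstrap weighting under screening

On these Gaussian scenarios the forest variant whose bootstrap draws are
proportional to the IPW weights loses 0.02-0.06 mean CV-AUC relative to
the screened standard forest, consistently across effect sizes, weight
scales and seeds.  The mechanism is structural: control weights sum to
roughly the cohort control count, so a full-size weighted bootstrap of a
20-case/100-control fold contains about one expected case, and such
case-poor trees contribute mostly vote-fraction noise (the deficit
shrinks, but does not vanish, as the ensemble grows).  We verified with
the reference R forest implementation — identical data, fold plans and
screened feature sets — that it shows the same deficit, so this is a
property of the data-generating family, not of this implementation.
Analyses of real immunologic data have reported near-parity of these two
variants; reproducing that would require marker distributions with
features (discreteness, strong low-dimensional structure) that this
generator deliberately does not model.  The corresponding direction check
in the test suite is asserted at its nominal threshold and fails on this
clause, by design rather than oversight.

## Problem sizes in the shipped experiments

The repeated-CV experiments in the test suite and the worked examples run
at desk scale: 10-20 replicates rather than 100, 50-500 trees, and 5
inner stacking folds in the large-n scenario, chosen so a full run
completes on a laptop-class single core in minutes.  The statistics are
averages over replicates either way; the library defaults
(`n_replicates=100`, `n_trees=500`, `inner_folds=10`) match the
full-scale protocol.

## Numerical choices and edge cases

- Weighted AUC uses exact pairwise enumeration via broadcasting (the pair
  counts at these sample sizes are ≤ ~10^6); ties get half credit.
- `plan_bootstrap` draw counts are `round(sample_fraction × n)`; a draw
  count of zero is an error.
- A bootstrap may contain one class only; such trees vote their single
  class everywhere (handled, not an error). Training data with a single
  class are an error.
- Screening's penalty grid is geometric from the data-driven λ_max
  (null-model score maximum) down three decades, 25 points.
- Observations in-bag for every tree are dropped from OOB-AUC; if either
  class has no usable observation the statistic errors out with a count.
- `compare_replicates` requires identical replicate seed sequences —
  comparing unpaired runs is refused rather than silently unpaired.

## Known limitations

- No confidence intervals for CV-AUC at the population level; the
  bootstrap theory for cross-validated AUC under two-phase sampling is
  unsettled, so the package reports replicate variability only.
- The forest is a plain Python-over-scikit-learn tree loop; it is fast
  enough for phase-two-sized data but not a replacement for a compiled
  forest library at cohort scale.
- Calibration of predicted probabilities is out of scope; scores are
  used only for ranking (AUC) and as stacking inputs.
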