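# Methods

`oksmap` implements indirect (response) mapping from the Oxford Knee
Score (OKS) to the EQ-5D-5L: instead of regressing the utility index
directly on OKS, it predicts each of the five EQ-5D-5L domain levels
from the 12 OKS items with ordinal models, assembles the predicted
levels into 5-digit health-state profiles, and converts those to
utilities under country value sets.  Response mapping preserves the
descriptive system, so one fitted mapping serves every tariff.

## Instruments

The OKS has 12 items coded 0 (severe) to 4 (very mild); the total
(0-48, higher = better) is banded severe (0-19), moderate (20-29),
mild (30-39) and very mild (40-48).  The EQ-5D-5L describes health on
five domains — mobility (MO), self-care (SC), usual activities (UA),
pain/discomfort (PD), anxiety/depression (AD) — each at five ordered
levels (1 = no problems, 5 = extreme problems/unable to), giving
5^5 = 3,125 states from 11111 to 55555.

Value sets are supported in two dialects.  *Additive* tariffs carry a
full-health constant and per-domain level decrements,
`U(profile) = c - sum_d dec_d(level_d)`; *lookup* tariffs are complete
3,125-row profile-to-utility tables (needed for crosswalk tariffs and
tariffs with interaction terms, which the additive dialect cannot
express).  No country's published weights are bundled (they are
licensed); two illustrative toy tariffs ship for tests and examples,
and real tariffs load through `read_value_set` with the same schemas.
`data/synthetic_egypt_vt.csv` is a synthetic additive tariff anchored
only at the two published endpoints of the Egyptian tariff
(U(11111) = 1, U(55555) = -0.964); its interior decrements are
invented and must not be used for analysis.

## Synthetic cohorts

No patient-level data ships with the package, so a generator emulates
the joint OKS/EQ-5D-5L structure the mapping task presents: a single
dominant latent health factor, all-negative item-by-domain
correlations, and realistic marginal level frequencies.  The model is
a one-factor graded-response-style threshold model:

    x_i ~ N(0,1);   y_ij = a_j x_i + sd * e_ij;   item_ij = bin(y_ij)

with positive loadings for OKS items and negative loadings for EQ
domains.  Default thresholds are placed at normal quantiles of target
marginal frequencies: the published estimation-sample EQ level counts
for the five domains, and binomial(4, mean/4) marginals matched to the
published OKS item means.  Loadings (OKS 1.1-2.1, EQ -0.7 to -1.5,
unit noise) were calibrated once so that a large draw (n = 5000) shows
item-domain Spearman correlations of about -0.35 to -0.69 (all
negative) and a first OKS principal component explaining ~0.68 of item
variance — inside the bands the study population exhibits (roughly
-0.3 to -0.8, and two-thirds).  AD is given the weakest loading, so it
is the hardest domain to predict, as observed in practice.

Default sample sizes are the study's: 456 estimation, 115 external
validation, drawn from the same population model with different seeds.
Seeds are explicit fields of the spec; identical spec (including seed)
reproduces a cohort bit-for-bit.

What the generator does *not* emulate: covariates (age, sex, TKR
status), EQ-VAS, multidimensional residual structure (e.g., a distinct
mental-health factor behind AD), item-specific response styles, and
missingness.  Passing tests therefore show that the pipeline is
correct and behaves sensibly under the intended dependence structure —
not that its accuracy numbers transfer to any real cohort.

## Model families

Four ordinal families map a predictor matrix to one domain's level.

**Cumulative link model.**  `P(y <= k | x) = F(theta_k - eta_k(x))`
with links logit, probit, cauchit, cloglog and the one-sided logc
(`-ln(1-p)`, inverse clipped to 0 below z = 0, top cumulative pinned
at 1).  *Parallel* fits share one slope vector across thresholds
(proportional odds under logit); *non-parallel* fits give each
threshold its own slopes, which can produce crossing cumulative curves
— the likelihood floors category probabilities at 1e-10 and the fit
reports a `crossing_detected` flag; prediction clips the cumulative
curve non-decreasing.  Optimization is L-BFGS with analytic gradients
on a log-increment threshold parameterization, marginal-quantile
starts, and up to three jittered restarts on non-convergence (flagged,
never silent).  Standard errors, when requested, come from a
finite-difference Hessian in natural parameters.

**Penalized regression.**  The parallel cumulative model with a ridge
(`alpha = 0`: sum of squared slopes) or lasso (`alpha = 1`: sum of
absolute slopes) penalty on the slopes only.  A descending path of
~20 penalty magnitudes from just above `lambda_max` (the smallest
magnitude at which all lasso slopes are zero) is fitted with warm
starts — FISTA with proximal soft-thresholding for lasso, L-BFGS for
ridge — and the magnitude minimizing AIC or BIC is selected.  Degrees
of freedom: nonzero slopes (lasso) or the ridge effective dimension
`sum d_i^2/(d_i^2 + 2 lambda)` over singular values of the
standardized design, plus the K-1 thresholds; the ridge formula is a
linear-model approximation, adequate for ranking magnitudes.
Predictors are standardized internally; logc is excluded (one-sided).

**Ordinal CART.**  Levels receive scores 1..K; node impurity is the
generalized Gini index `sum_ij cost(i,j) p_i p_j` with cost
`|s_i - s_j|` (absolute) or `(s_i - s_j)^2` (quadratic).  A split must
improve the impurity risk by at least `cp` times the root impurity
risk (the relative-scale convention R's rpart uses; the run draws its
cp grid log-uniformly on [1e-4, 1e-1], which brackets values reported
for this kind of task).  Stopping: minsplit 20, minbucket 7, depth cap
30.  The grown tree is pruned by weakest-link cost-complexity pruning,
with an internal 5-fold cross-validation choosing the subtree with the
least misclassification *rate* (all misses weight 1) or
misclassification *cost* (misses weighted by the cost matrix).  Leaf
prediction is the leaf's modal level, ties toward the lower level, so
the cost matrix shapes the tree, not the labels; a cp too large to
allow any split yields the modal-level (baseline) predictor.  Whether
the cp gate should act on impurity improvement or on pruning-risk
improvement is genuinely ambiguous in this literature; here cp gates
impurity improvement and the pruning criterion is chosen by
`prune_rule`, which keeps the two notions orthogonal and both
exercisable.

**Ordinal forest.**  A random-forest variant that optimizes the
numeric scores assigned to the levels before growing the final
forest.  Each of `nsets` candidates is a partition of [0,1] into K
intervals (borders: 0, K-1 sorted uniforms, 1); class k's score is the
standard-normal quantile of its interval midpoint.  A small regression
forest of `ntreeperdiv` trees is grown per candidate on the scored
outcome; its out-of-bag predictions are classified by the
normal-quantile border partition and graded by accuracy; the best
candidate's scores train the final `ntreefinal`-tree forest.  Wide
intervals let skewed levels occupy more of the score axis, which is
what allows the forest to beat the modal baseline on domains such as
self-care.  The regression forests are scikit-learn
`RandomForestRegressor`s; the score-set search and level mapping are
the ordinal layer.

## Predictor sets

Each structure is tried with four predictor constructions: all 12
items; an RFE subset (random-forest importances computed once on the
full item set give the elimination order — re-ranking importances
inside small subsets is avoided because impurity importance inflates
noise items there — and repeated cross-validated accuracy over subset
sizes 1..12 picks the best, ties to the smaller subset); model-based
importance (absolute standardized slopes for the regression families
with an above-the-mean cut-off, impurity-decrease sums with an
above-zero cut-off for the tree families; an empty selection falls
back to all items with a warning); and PCA (items centered/scaled,
leading components to 90% cumulative variance).  Transforms fitted on
the estimation sample are reused verbatim on validation data.

## Tournament and evaluation

The full grid is 133 structures (10 cumulative, 16 penalized, 80
ocart, 27 oforest) x 4 predictor sets = 532 trials per domain.  Each
trial is graded by repeated stratified k-fold cross-validated accuracy
(default 5 folds x 3 repeats = 15 fold accuracies; the folds/repeats
split is configurable because both readings of a "5 x 3-fold"
protocol are defensible).  The winner per domain is the highest mean
accuracy, ties broken toward the simpler family (cumulative <
penalized < ocart < oforest), then fewer predictors, then grid order;
non-converged trials are excluded and logged.  The winner is refitted
on the whole estimation sample.

Evaluation reports baseline accuracy (share of the modal level), crude
accuracy with percentile-bootstrap 95% CIs, and — after assembling
predicted profiles — MAE and MSE of utilities per value set with
percentile-bootstrap CIs and a median-split MAE (patients at or above
vs below the median utility; the observed-utility median stratifies by
default, the predicted-utility median is an option, since either
reading of "median estimated utility" is defensible).  The bootstrap
resamples patients, keeping the five domains coupled; B = 2000 by
default.

## Problem sizes of the shipped runs

The package's own desk-scale configuration (`reduced_grid`) keeps
every family and predictor set but sizes the run for a single CPU: 5
random cp values (20 ocart structures), forest grid nsets {3,4,5} x
ntreeperdiv {8,10,12} x ntreefinal {30,40,50}, 3-fold x 1-repeat CV,
and lighter RFE (3-fold x 1, 25 trees).  That is 73 structures x 4
sets = 292 trials per domain, about two minutes per domain at
n = 456.  Cross-validation fold fits cap optimizer iterations
(`fast=True`); final refits use full settings.  The full grid with
5 x 3 CV is one flag away (`--full-grid`) and simply costs more time.

## Numerical choices

Probability floors 1e-12 in all likelihoods; crossing floor 1e-10.
Prediction ties break toward the lower (healthier) level everywhere.
Thresholds are kept ordered by a log-increment parameterization.  The
lasso path starts 5% above `lambda_max` so the all-zero solution is on
the path exactly.  Candidate tree splits are midpoints of adjacent
distinct predictor values.  All randomness flows from explicit seeds
through `numpy.random.SeedSequence`; a pipeline run fans one master
seed out per stage, and reruns are checksum-identical.

## Known limitations

Ridge degrees of freedom are approximate (see above).  The internal
CV used for tree pruning grows fold trees at the same cp but compares
subtrees on a shared candidate-alpha grid, a simplification of rpart's
per-fold alpha sequences.  The non-parallel cumulative model with
heavy-tailed links (cauchit) can fail to converge on small folds; such
trials are flagged and excluded rather than repaired.  The synthetic
cohorts are a single-factor world: real OKS/EQ-5D data have secondary
structure the generator does not attempt, so accuracy levels measured
here characterize the pipeline, not clinical performance.
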