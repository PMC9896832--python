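# oksmap

Indirect (response) mapping from the **Oxford Knee Score (OKS)** to the
**EQ-5D-5L**: predict the five EQ-5D-5L domain levels from the 12 OKS
items with ordinal models, assemble the predicted levels into 5-digit
health-state profiles, and convert them into utility indices under any
country value set.

## Who this is for

Health-economic analyses of knee osteoarthritis and knee arthroplasty
need utilities (for QALYs), but many cohorts collected only the
knee-specific OKS.  Response mapping recovers EQ-5D-5L utilities from
OKS responses.  Because the mapping predicts the *descriptive system*
(the domain levels) rather than one country's utility index, a single
fitted mapping serves all tariffs.

## The method

For each EQ-5D-5L domain (mobility, self-care, usual activities,
pain/discomfort, anxiety/depression), a cross-validated tournament
selects among four ordinal model families:

* **cumulative link models** `P(y ≤ k | x) = F(θ_k − x'β)`, parallel or
  threshold-specific slopes, with logit / probit / cauchit / cloglog /
  logc links (10 structures);
* **penalized cumulative regression** — ridge (α = 0) or lasso (α = 1)
  on the slopes, penalty magnitude selected by AIC or BIC along a
  warm-started path (16 structures);
* **ordinal CART** — classification trees splitting on the generalized
  Gini index `Σ_ij cost(i,j) p_i p_j` with absolute or quadratic
  level-distance costs, a complexity-parameter gate (20 random cp
  values), and cross-validated misclassification-rate or -cost pruning
  (80 structures);
* **ordinal forests** — random forests with an optimized monotone score
  set for the ordered levels, searched over `nsets` candidates with
  small forests of `ntreeperdiv` trees and finalized with `ntreefinal`
  trees (27 structures).

Each of the 133 structures is crossed with four predictor sets (all 12
items, an RFE subset, model-based important items, and principal
components reaching 90% of item variance), giving **532 trials per
domain**.  The accuracy-best trial is refitted on the full estimation
sample; evaluation reports baseline vs crude accuracy with bootstrap
CIs, and per-value-set MAE / MSE of utilities with a median-split MAE.

Because no patient-level data ships with the package, a calibrated
synthetic cohort generator (single latent health factor, thresholds
matched to published marginal frequencies, estimation n = 456 /
validation n = 115) exercises the pipeline end to end; see
`docs/methods.md` for the model and its limitations.

## Worked example

```bash
oksmap full --out demo_run --seed 1
```

runs simulate → tournament → evaluate with the desk-scale grid and
prints the per-domain winners:

```
MO: cumulative|parallel=True|link=logit [model_based] cv_acc=0.566
SC: cumulative|parallel=True|link=probit [pca] cv_acc=0.673
UA: cumulative|parallel=True|link=cauchit [pca] cv_acc=0.524
PD: penalized|link=logit|alpha=ridge|criterion=bic [all] cv_acc=0.539
AD: ocart|cp=0.000592923|split_cost=quadratic|prune_rule=misclassification_cost [pca] cv_acc=0.404
```

Each line is one domain's tournament winner: the model structure, the
predictor set in brackets, and its cross-validated accuracy on the
n = 456 synthetic estimation sample.  Self-care — the domain with the
strongest modal level — is predicted best; anxiety/depression, the
weakest-signal domain, worst, with every winner above its no-model
baseline (the modal-level share: 0.29, 0.63, 0.29, 0.33 and 0.27
here).  `demo_run/` then contains the cohorts, the full leaderboard,
the serialized winners, and evaluation tables:

```
$ oksmap evaluate --out demo_run --seed 1
MO estimation: baseline=0.294 crude=0.559 (0.514, 0.605)
...
ToyLand: MAE=0.117 MSE=0.023 MAE above/below median=0.060/0.175
```

The last line converts actual and predicted profiles of the n = 115
validation sample to utilities under the bundled toy tariff: mean
absolute error 0.117, smaller among the healthier half of patients.
Real country value sets are plain CSV files (additive
`domain,level,decrement` or lookup `profile_code,utility`) passed via
`--value-sets DIR`.

The same pipeline is available as a library
(`oksmap.pipeline.run_full`, `oksmap.selection.run_tournament`, …),
and `oksmap template` writes a commented YAML run configuration.

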