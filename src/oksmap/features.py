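"""Predictor-set construction from the 12 OKS items.

Every model structure is tried with four predictor sets:

* ``all`` — the 12 OKS items as-is;
* ``rfe`` — the subset selected by recursive feature elimination:
  random-forest importances give an elimination order, and repeated
  cross-validated accuracy over the subset sizes 1..12 picks the best
  subset (5 x 5-fold by default);
* ``model_based`` — items ranked by the model family's native
  importance measure (absolute standardized slopes for the regression
  families, impurity-decrease sums for the tree families), retaining
  items with importance above the mean (cumulative) or above zero
  (penalized and trees); an empty selection falls back to ``all`` with
  a warning;
* ``pca`` — the items centered and scaled, rotated onto principal
  components, keeping the smallest number of leading components whose
  cumulative explained variance reaches 90%.

A ``PredictorSet`` carries its fitted transform, so validation-sample
predictors are built with estimation-sample centers, scales and
rotations (no leakage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .cumulative import fit_cumulative_core
from .instruments import OKS_N_ITEMS
from .ocart import fit_ocart_core
from .oforest import fit_oforest_core
from .penalized import fit_penalized_core

__all__ = [
    "PredictorSet",
    "PREDICTOR_SET_IDS",
    "all_predictors",
    "rfe_rank",
    "model_based_importance",
    "pca_preprocess",
    "build_predictor_sets",
]

PREDICTOR_SET_IDS = ("all", "rfe", "model_based", "pca")

ITEM_NAMES = [f"oks_q{j + 1:02d}" for j in range(OKS_N_ITEMS)]

PCA_VARIANCE_TARGET = 0.90


@dataclass
class PredictorSet:
    """A fitted predictor construction, reusable on new data."""

    id: str
    columns: list  # selected item names, or component labels for pca
    item_indices: np.ndarray | None = None  # into the 12 items (selection sets)
    ranking: list | None = None  # item names, most important first
    center: np.ndarray | None = None  # pca only
    scale: np.ndarray | None = None
    rotation: np.ndarray | None = None  # (12, k) loadings
    explained_variance_ratio: np.ndarray | None = None

    def apply(self, X) -> np.ndarray:
        """Build this set's design matrix from a raw n x 12 item matrix,
        using the transform fitted on the estimation sample."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != OKS_N_ITEMS:
            raise ValueError(f"expected {OKS_N_ITEMS} OKS item columns, got {X.shape[1]}")
        if self.id == "pca":
            return ((X - self.center) / self.scale) @ self.rotation
        return X[:, self.item_indices]

    @property
    def n_columns(self) -> int:
        return len(self.columns)


def all_predictors() -> PredictorSet:
    return PredictorSet(id="all", columns=list(ITEM_NAMES), item_indices=np.arange(OKS_N_ITEMS))


def _check_y(y) -> np.ndarray:
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is degenerate (single level)")
    return y


def _rf_elimination_order(X, y, n_trees, seed) -> list[int]:
    """Item ranking for backward elimination: random-forest importance of
    the full 12-item fit, most important first.  Ranking once on the full
    model (rather than re-ranking inside each subset) avoids the
    impurity-importance inflation noise items show in small subsets."""
    rf = RandomForestClassifier(n_estimators=max(2 * n_trees, 100), random_state=seed, n_jobs=1)
    rf.fit(X, y)
    return list(np.argsort(-rf.feature_importances_, kind="stable"))


def rfe_rank(X, y, folds: int = 5, repeats: int = 5, seed: int = 0, n_trees: int = 100) -> PredictorSet:
    """Recursive feature elimination for one EQ domain.

    Returns the accuracy-best subset over sizes 1..12 and the full
    ranking; ties between sizes go to the smaller subset.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = _check_y(y)
    if len(y) < 50:
        raise ValueError("RFE needs at least 50 observations")
    ranking = _rf_elimination_order(X, y, n_trees, seed)

    n_sizes = X.shape[1]
    size_acc = np.zeros(n_sizes)
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + 1000 + r)
        # stratification needs every class >= folds; else fall back to plain folds
        try:
            splits = list(skf.split(X, y))
        except ValueError:
            rng = np.random.default_rng(seed + 1000 + r)
            fold_of = rng.permutation(len(y)) % folds
            splits = [(np.flatnonzero(fold_of != f), np.flatnonzero(fold_of == f)) for f in range(folds)]
        for fi, (tr, te) in enumerate(splits):
            if len(np.unique(y[tr])) < 2:
                continue
            for size in range(1, n_sizes + 1):
                cols = ranking[:size]
                rf = RandomForestClassifier(
                    n_estimators=n_trees, random_state=seed + 7 * r + fi, n_jobs=1
                )
                rf.fit(X[tr][:, cols], y[tr])
                size_acc[size - 1] += np.mean(rf.predict(X[te][:, cols]) == y[te])
    best_size = 1 + int(np.argmax(size_acc))  # first maximum -> smallest subset on ties
    idx = np.array(sorted(ranking[:best_size]))
    return PredictorSet(
        id="rfe",
        columns=[ITEM_NAMES[i] for i in idx],
        item_indices=idx,
        ranking=[ITEM_NAMES[i] for i in ranking],
    )


def model_based_importance(family: str, X, y, seed: int = 0) -> PredictorSet:
    """Family-native item importances and the retained subset."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = _check_y(y)
    if family == "cumulative":
        fit = fit_cumulative_core(X, y, parallel=True, link="logit", seed=seed)
        if not fit.converged:
            raise RuntimeError("base cumulative model did not converge")
        imp = np.abs(fit.beta) * X.std(axis=0)
        keep = imp > imp.mean()
    elif family == "penalized":
        fit = fit_penalized_core(X, y, alpha="lasso", criterion="aic", link="logit", seed=seed)
        imp = np.abs(fit.beta_std)
        keep = imp > 0
    elif family == "ocart":
        fit = fit_ocart_core(X, y, cp=0.001, split_cost="absolute",
                             prune_rule="misclassification_rate", seed=seed)
        imp = fit.feature_importances(X.shape[1])
        keep = imp > 0
    elif family == "oforest":
        fit = fit_oforest_core(X, y, nsets=10, ntreeperdiv=50, ntreefinal=100, seed=seed)
        imp = fit.feature_importances()
        keep = imp > 0
    else:
        raise ValueError(f"unknown family {family!r}")
    if not keep.any():
        warnings.warn(
            f"model-based importance for family {family!r} retained no item; "
            "falling back to all 12 predictors"
        )
        return PredictorSet(
            id="model_based", columns=list(ITEM_NAMES), item_indices=np.arange(OKS_N_ITEMS),
            ranking=[ITEM_NAMES[i] for i in np.argsort(-imp)],
        )
    idx = np.flatnonzero(keep)
    return PredictorSet(
        id="model_based",
        columns=[ITEM_NAMES[i] for i in idx],
        item_indices=idx,
        ranking=[ITEM_NAMES[i] for i in np.argsort(-imp)],
    )


def pca_preprocess(X) -> PredictorSet:
    """Center/scale the 12 items and keep the leading principal components
    reaching 90% cumulative explained variance."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] <= X.shape[1]:
        raise ValueError("PCA needs more rows than the 12 items")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [ITEM_NAMES[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant item column(s) {bad}; PCA scaling undefined")
    mu = X.mean(axis=0)
    Z = (X - mu) / sd
    corr = np.corrcoef(Z.T)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    ratio = evals / evals.sum()
    k = 1 + int(np.argmax(np.cumsum(ratio) >= PCA_VARIANCE_TARGET))
    return PredictorSet(
        id="pca",
        columns=[f"PC{i + 1}" for i in range(k)],
        center=mu,
        scale=sd,
        rotation=evecs[:, :k],
        explained_variance_ratio=ratio[:k],
    )


def build_predictor_sets(
    family: str, X, y, seed: int = 0,
    rfe_folds: int = 5, rfe_repeats: int = 5, rfe_trees: int = 100,
    include=PREDICTOR_SET_IDS,
) -> dict:
    """All requested predictor sets for one domain and one model family."""
    out = {}
    if "all" in include:
        out["all"] = all_predictors()
    if "rfe" in include:
        out["rfe"] = rfe_rank(X, y, folds=rfe_folds, repeats=rfe_repeats, seed=seed, n_trees=rfe_trees)
    if "model_based" in include:
        out["model_based"] = model_based_importance(family, X, y, seed=seed)
    if "pca" in include:
        out["pca"] = pca_preprocess(X)
    return out
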