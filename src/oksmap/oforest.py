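"""Ordinal forest: random forest with score-set optimization.

A random-forest variant for ordered outcomes.  Instead of fixing the
numeric scores assigned to the K ordered levels, the method searches
over candidate monotone score sets.  A candidate is induced by a
partition of [0, 1] into K class intervals: the K+1 borders are 0 and
1 (anchored) plus K-1 sorted uniform variates.  Class k's score is the
standard-normal quantile of its interval midpoint — strictly
increasing in k — so the partition widths control how much of the
latent score axis each ordered level occupies (a wide first interval,
for instance, lets a heavily modal level dominate predictions).

For every candidate a small regression forest of ``ntreeperdiv`` trees
is grown on the scored outcome; its out-of-bag score predictions are
classified back to levels by the normal-quantile border partition and
graded by ordinal accuracy.  The best candidate's score set is used to
grow the final forest of ``ntreefinal`` trees, and prediction
classifies the score-space forest aggregate with the same borders.

The underlying regression forests are scikit-learn
``RandomForestRegressor`` instances; the score-set search, the
level/score mapping, and the out-of-bag ordinal grading are what make
the forest ordinal.
"""

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

__all__ = ["OforestFit", "fit_oforest_core"]


def _draw_borders(K: int, rng: np.random.Generator) -> np.ndarray:
    """One candidate partition of [0, 1]: K+1 strictly increasing borders
    anchored at 0 and 1; redrawn in the (measure-zero) event of ties."""
    for _ in range(100):
        interior = np.sort(rng.uniform(0.0, 1.0, size=K - 1))
        b = np.concatenate([[0.0], interior, [1.0]])
        if np.all(np.diff(b) > 0):
            return b
    raise RuntimeError("could not draw a strictly monotone border set")


def _scores_from_borders(borders: np.ndarray) -> np.ndarray:
    """Class scores: standard-normal quantiles of the interval midpoints
    (strictly increasing because the midpoints are)."""
    mids = 0.5 * (borders[:-1] + borders[1:])
    return stats.norm.ppf(mids)


def _cutpoints(borders: np.ndarray) -> np.ndarray:
    """Score-axis classification cutpoints between adjacent levels."""
    return stats.norm.ppf(borders[1:-1])


def _oob_mask(rf: RandomForestRegressor, n: int) -> np.ndarray:
    """Rows with at least one out-of-bag tree.  Small forests can leave a
    few rows with no OOB estimate; those are excluded from the candidate
    grading.  Falls back to grading all rows if the bootstrap bookkeeping
    helpers are unavailable."""
    try:
        from sklearn.ensemble._forest import (
            _generate_unsampled_indices,
            _get_n_samples_bootstrap,
        )
    except ImportError:  # pragma: no cover - depends on sklearn internals
        return np.ones(n, dtype=bool)
    import inspect

    needs_weight = "sample_weight" in inspect.signature(_get_n_samples_bootstrap).parameters
    extra = (None,) if needs_weight else ()
    nb = _get_n_samples_bootstrap(n, rf.max_samples, *extra)
    count = np.zeros(n, dtype=int)
    for est in rf.estimators_:
        count[_generate_unsampled_indices(est.random_state, n, nb, *extra)] += 1
    return count > 0


@dataclass
class OforestFit:
    """The final ordinal forest with its optimized score set."""

    forest: RandomForestRegressor
    level_labels: np.ndarray
    borders: np.ndarray  # optimized (K+1,) partition of [0, 1]
    score_set: np.ndarray  # (K,) class scores implied by the borders
    oob_accuracy: float  # OOB ordinal accuracy of the winning small forest
    candidate_accuracies: np.ndarray

    def predict(self, X) -> np.ndarray:
        raw = self.forest.predict(np.atleast_2d(np.asarray(X, dtype=float)))
        codes = np.searchsorted(_cutpoints(self.borders), raw)
        return self.level_labels[codes]

    def feature_importances(self) -> np.ndarray:
        return self.forest.feature_importances_


def fit_oforest_core(
    X,
    y,
    nsets: int = 50,
    ntreeperdiv: int = 50,
    ntreefinal: int = 200,
    seed: int = 0,
) -> OforestFit:
    """Search ``nsets`` score sets with small forests, keep the best by
    out-of-bag ordinal accuracy, and grow the final forest with it.

    Deterministic for identical seed, data and hyperparameters; ties in
    candidate accuracy go to the first candidate drawn.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels, codes = np.unique(np.asarray(y), return_inverse=True)
    K = len(labels)
    if K < 2:
        raise ValueError("outcome has a single level; cannot fit a forest")
    rng = np.random.default_rng(seed)
    forest_seeds = rng.integers(0, 2**31 - 1, size=nsets + 1)

    accs = np.empty(nsets)
    candidates = []
    for c in range(nsets):
        borders = _draw_borders(K, rng)
        candidates.append(borders)
        scores = _scores_from_borders(borders)
        rf = RandomForestRegressor(
            n_estimators=ntreeperdiv,
            oob_score=True,
            bootstrap=True,
            random_state=int(forest_seeds[c]),
            n_jobs=1,
        )
        with warnings.catch_warnings():
            # rows never out-of-bag are masked below; sklearn's warning
            # about them is expected for very small candidate forests
            warnings.simplefilter("ignore", UserWarning)
            rf.fit(X, scores[codes])
        seen = _oob_mask(rf, len(codes))
        if not seen.any():
            accs[c] = 0.0
            continue
        pred_codes = np.searchsorted(_cutpoints(borders), rf.oob_prediction_[seen])
        accs[c] = float(np.mean(pred_codes == codes[seen]))

    best = int(np.argmax(accs))  # first maximum on ties
    best_borders = candidates[best]
    best_scores = _scores_from_borders(best_borders)
    final = RandomForestRegressor(
        n_estimators=ntreefinal,
        bootstrap=True,
        random_state=int(forest_seeds[-1]),
        n_jobs=1,
    )
    final.fit(X, best_scores[codes])
    return OforestFit(
        forest=final, level_labels=labels, borders=best_borders,
        score_set=best_scores, oob_accuracy=float(accs[best]),
        candidate_accuracies=accs,
    )
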