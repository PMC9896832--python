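"""Cross-validated model-selection tournament and winner refitting.

For each of the five EQ-5D-5L domains, every model structure (133 at
full scale) is crossed with the four predictor sets, giving 532
trials.  Each trial is graded by repeated k-fold cross-validated
accuracy on the estimation sample — 5 folds repeated 3 times by
default, so 15 fold accuracies per trial, with outcome-stratified fold
assignment where level counts permit.  The structure with the highest
mean cross-validated accuracy wins its domain and is refitted on the
whole estimation sample.

Ties are broken deterministically: higher mean accuracy, then the
simpler family (cumulative < penalized < ocart < oforest), then fewer
predictor columns, then grid order.  Trials whose fits do not converge
are excluded from the ranking and logged with reasons, never silently
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import PREDICTOR_SET_IDS, PredictorSet, build_predictor_sets
from .instruments import DOMAINS
from .models import (
    FAMILIES,
    N_CP,
    OFOREST_NSETS,
    OFOREST_NTREEFINAL,
    OFOREST_NTREEPERDIV,
    FittedOrdinalModel,
    OrdinalModelSpec,
    enumerate_structures,
    fit_model,
)

__all__ = [
    "GridOptions",
    "reduced_grid_options",
    "TrialResult",
    "SelectionReport",
    "enumerate_grid",
    "cross_validate",
    "select_and_refit",
    "run_tournament",
]

_FAMILY_ORDER = {f: i for i, f in enumerate(FAMILIES)}


@dataclass(frozen=True)
class GridOptions:
    """Grid and cross-validation sizing for one tournament run."""

    folds: int = 5
    repeats: int = 3
    n_cp: int = N_CP
    oforest_nsets: tuple = OFOREST_NSETS
    oforest_ntreeperdiv: tuple = OFOREST_NTREEPERDIV
    oforest_ntreefinal: tuple = OFOREST_NTREEFINAL
    rfe_folds: int = 5
    rfe_repeats: int = 5
    rfe_trees: int = 100
    include_sets: tuple = PREDICTOR_SET_IDS
    include_families: tuple = FAMILIES
    domains: tuple = DOMAINS


def reduced_grid_options() -> GridOptions:
    """A desk-scale grid: every family and predictor set is kept, the
    random cp grid is cut to 5 values, the forest sizes are scaled down,
    and cross-validation runs one repeat of 3 folds."""
    return GridOptions(
        folds=3,
        repeats=1,
        n_cp=5,
        oforest_nsets=(3, 4, 5),
        oforest_ntreeperdiv=(8, 10, 12),
        oforest_ntreefinal=(30, 40, 50),
        rfe_folds=3,
        rfe_repeats=1,
        rfe_trees=25,
    )


def enumerate_grid(seed: int = 0, options: GridOptions | None = None) -> list[tuple[OrdinalModelSpec, str]]:
    """All (structure, predictor-set) trials in deterministic order; 532 at
    the default grid (133 structures x 4 sets)."""
    options = options or GridOptions()
    specs = [
        s
        for s in enumerate_structures(
            seed=seed,
            n_cp=options.n_cp,
            oforest_nsets=options.oforest_nsets,
            oforest_ntreeperdiv=options.oforest_ntreeperdiv,
            oforest_ntreefinal=options.oforest_ntreefinal,
        )
        if s.family in options.include_families
    ]
    return [(spec, set_id) for spec in specs for set_id in options.include_sets]


def _fold_assignment(y: np.ndarray, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Outcome-stratified fold labels where level counts permit, else a
    random permutation; returns one fold label per row."""
    n = len(y)
    fold_of = np.empty(n, dtype=int)
    offset = 0
    for level in np.unique(y):
        rows = np.flatnonzero(y == level)
        rng.shuffle(rows)
        # round-robin with a rotating offset spreads scarce levels evenly
        fold_of[rows] = (np.arange(len(rows)) + offset) % folds
        offset += len(rows)
    return fold_of


@dataclass
class TrialResult:
    """Cross-validation outcome of one (structure, predictor set) trial."""

    domain: str
    spec: OrdinalModelSpec
    predictor_set_id: str
    fold_accuracies: list
    converged: bool = True
    note: str = ""
    folds_merged: bool = False

    @property
    def cv_accuracy_mean(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def cv_accuracy_sd(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1)) if len(self.fold_accuracies) > 1 else 0.0

    @property
    def cv_cv(self) -> float:
        m = self.cv_accuracy_mean
        return self.cv_accuracy_sd / m if m > 0 else np.inf


def cross_validate(
    spec: OrdinalModelSpec,
    X,
    y,
    folds: int = 5,
    repeats: int = 3,
    seed: int = 0,
    domain: str = "",
    predictor_set_id: str = "all",
    fold_assignments: list | None = None,
) -> TrialResult:
    """Repeated k-fold accuracy of one structure on a ready design matrix.

    ``fold_assignments`` (one label vector per repeat) lets a tournament
    share identical folds across all its trials.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if fold_assignments is None:
        rng = np.random.default_rng(seed)
        fold_assignments = [_fold_assignment(y, folds, rng) for _ in range(repeats)]
    accuracies = []
    converged = True
    merged = False
    notes = []
    for r, fold_of in enumerate(fold_assignments):
        for f in range(folds):
            tr = fold_of != f
            te = ~tr
            if len(np.unique(y[tr])) < 2:
                # degenerate training part: merge this fold into the next
                merged = True
                continue
            try:
                model = fit_model(spec, X[tr], y[tr], seed=seed + 97 * r + f,
                                  predictor_set_id=predictor_set_id, fast=True)
            except Exception as exc:  # flagged, not silent
                converged = False
                notes.append(f"repeat {r} fold {f}: {exc}")
                continue
            if not model.converged:
                converged = False
                notes.append(f"repeat {r} fold {f}: non-convergence flagged")
            accuracies.append(float(np.mean(model.predict(X[te]) == y[te])))
    if not accuracies:
        converged = False
        notes.append("no fold produced a fit")
        accuracies = [0.0]
    return TrialResult(
        domain=domain, spec=spec, predictor_set_id=predictor_set_id,
        fold_accuracies=accuracies, converged=converged,
        note="; ".join(notes), folds_merged=merged,
    )


def _rank_key(t: TrialResult, grid_index: int):
    return (
        -t.cv_accuracy_mean,
        _FAMILY_ORDER[t.spec.family],
        t.n_predictors if hasattr(t, "n_predictors") else 0,
        grid_index,
    )


@dataclass
class SelectionReport:
    """Per-domain trial rankings, winners, and refitted winner models."""

    trials: dict  # domain -> list[TrialResult], ranked best first
    winners: dict  # domain -> TrialResult
    models: dict  # domain -> FittedOrdinalModel (refit on full estimation data)
    predictor_sets: dict  # domain -> {set_id or (family, 'model_based') -> PredictorSet}

    def leaderboard(self) -> pd.DataFrame:
        rows = []
        for domain, trs in self.trials.items():
            for rank, t in enumerate(trs, start=1):
                rows.append(
                    {
                        "domain": domain,
                        "rank": rank,
                        "family": t.spec.family,
                        "structure": t.spec.label(),
                        "predictor_set": t.predictor_set_id,
                        "cv_accuracy_mean": t.cv_accuracy_mean,
                        "cv_accuracy_sd": t.cv_accuracy_sd,
                        "cv_cv": t.cv_cv,
                        "n_folds": len(t.fold_accuracies),
                        "converged": t.converged,
                        "note": t.note,
                    }
                )
        return pd.DataFrame(rows)


def _sets_for(domain_sets: dict, family: str, set_id: str) -> PredictorSet:
    if set_id == "model_based":
        return domain_sets[("model_based", family)]
    return domain_sets[set_id]


def run_tournament(
    oks_items,
    eq_levels,
    seed: int = 0,
    options: GridOptions | None = None,
    progress=None,
) -> SelectionReport:
    """The full tournament on one estimation cohort.

    ``oks_items`` is n x 12 (0-4 coding), ``eq_levels`` n x 5 (1-5,
    MO/SC/UA/PD/AD order).  Deterministic for identical seed and data.
    """
    options = options or GridOptions()
    oks_items = np.asarray(oks_items)
    eq_levels = np.asarray(eq_levels)
    grid = enumerate_grid(seed=seed, options=options)

    all_trials: dict = {}
    winners: dict = {}
    models: dict = {}
    sets_out: dict = {}
    for d_idx, domain in enumerate(DOMAINS):
        if domain not in options.domains:
            continue
        y = eq_levels[:, d_idx]
        dseed = int(np.random.SeedSequence([seed, d_idx]).generate_state(1)[0] % (2**31 - 1))
        # predictor sets: all / rfe / pca shared across families,
        # model_based per family
        domain_sets: dict = {}
        shared = build_predictor_sets(
            "cumulative", oks_items, y, seed=dseed,
            rfe_folds=options.rfe_folds, rfe_repeats=options.rfe_repeats,
            rfe_trees=options.rfe_trees,
            include=[s for s in options.include_sets if s != "model_based"],
        )
        domain_sets.update(shared)
        if "model_based" in options.include_sets:
            for family in options.include_families:
                domain_sets[("model_based", family)] = build_predictor_sets(
                    family, oks_items, y, seed=dseed, include=("model_based",)
                )["model_based"]
        designs = {
            key: ps.apply(oks_items) for key, ps in domain_sets.items()
        }

        rng = np.random.default_rng(dseed)
        fold_assignments = [
            _fold_assignment(y, options.folds, rng) for _ in range(options.repeats)
        ]

        results = []
        for g_idx, (spec, set_id) in enumerate(grid):
            ps = _sets_for(domain_sets, spec.family, set_id)
            key = ("model_based", spec.family) if set_id == "model_based" else set_id
            X = designs[key]
            tseed = int(np.random.SeedSequence([seed, d_idx, g_idx]).generate_state(1)[0] % (2**31 - 1))
            res = cross_validate(
                spec, X, y, folds=options.folds, repeats=options.repeats,
                seed=tseed, domain=domain, predictor_set_id=set_id,
                fold_assignments=fold_assignments,
            )
            res.n_predictors = ps.n_columns
            res.grid_index = g_idx
            results.append(res)
            if progress is not None:
                progress(domain, g_idx, len(grid), res)

        ranked = sorted(
            [t for t in results if t.converged],
            key=lambda t: (-t.cv_accuracy_mean, _FAMILY_ORDER[t.spec.family],
                           t.n_predictors, t.grid_index),
        )
        if not ranked:
            raise RuntimeError(f"no converged trial for domain {domain}")
        failed = [t for t in results if not t.converged]
        all_trials[domain] = ranked + failed
        winner = ranked[0]
        winners[domain] = winner
        ps = _sets_for(domain_sets, winner.spec.family, winner.predictor_set_id)
        key = ("model_based", winner.spec.family) if winner.predictor_set_id == "model_based" else winner.predictor_set_id
        refit_seed = int(np.random.SeedSequence([seed, d_idx, 999983]).generate_state(1)[0] % (2**31 - 1))
        models[domain] = fit_model(
            winner.spec, designs[key], y, seed=refit_seed,
            predictor_set_id=winner.predictor_set_id,
        )
        sets_out[domain] = domain_sets
    return SelectionReport(trials=all_trials, winners=winners, models=models,
                           predictor_sets=sets_out)


def select_and_refit(results: list, oks_items, y, domain_sets: dict, seed: int = 0):
    """Argmax-by-accuracy winner selection over explicit trial results,
    then a refit of the winner on all estimation rows.  Returns
    (winner TrialResult, refitted model)."""
    converged = [t for t in results if t.converged]
    if not converged:
        raise RuntimeError("all trials non-converged; nothing to select")
    for i, t in enumerate(results):
        if not hasattr(t, "grid_index"):
            t.grid_index = i
        if not hasattr(t, "n_predictors"):
            ps = _sets_for(domain_sets, t.spec.family, t.predictor_set_id)
            t.n_predictors = ps.n_columns
    winner = sorted(
        converged,
        key=lambda t: (-t.cv_accuracy_mean, _FAMILY_ORDER[t.spec.family],
                       t.n_predictors, t.grid_index),
    )[0]
    ps = _sets_for(domain_sets, winner.spec.family, winner.predictor_set_id)
    model = fit_model(winner.spec, ps.apply(oks_items), y, seed=seed,
                      predictor_set_id=winner.predictor_set_id)
    return winner, model
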