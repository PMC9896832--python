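"""Model structures: the hyperparameter grid cells and fitted realizations.

Four ordinal model families map OKS-derived predictors to one EQ-5D-5L
domain level:

* ``cumulative`` — cumulative link model; hyperparameters: parallel
  (True/False) x link (logit, probit, cauchit, cloglog, logc) = 10
  structures;
* ``penalized`` — penalized parallel cumulative regression;
  alpha (ridge/lasso) x criterion (AIC/BIC) x link (logc excluded)
  = 16 structures;
* ``ocart`` — cost-sensitive ordinal classification tree; 20 randomly
  drawn complexity parameters x split cost (absolute/quadratic) x
  prune rule (misclassification rate/cost) = 80 structures;
* ``oforest`` — ordinal forest; nsets (50/100/150) x ntreeperdiv
  (50/100/150) x ntreefinal (200/400/600) = 27 structures.

That is 133 structures in total; crossed with the four predictor sets
they give the 532 trials of the model-selection tournament.

The 20 ocart complexity parameters are drawn log-uniformly on
[1e-4, 1e-1] from the run seed (the grid is random by design; any
particular run's values are reproducible from its seed).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import joblib
import numpy as np

from .cumulative import fit_cumulative_core
from .links import LINK_NAMES, PENALIZED_LINK_NAMES
from .ocart import fit_ocart_core
from .oforest import fit_oforest_core
from .penalized import fit_penalized_core

__all__ = [
    "FAMILIES",
    "OrdinalModelSpec",
    "FittedOrdinalModel",
    "enumerate_structures",
    "draw_cp_values",
    "fit_model",
    "predict_levels",
    "save_model",
    "load_model",
]

FAMILIES = ("cumulative", "penalized", "ocart", "oforest")

OFOREST_NSETS = (50, 100, 150)
OFOREST_NTREEPERDIV = (50, 100, 150)
OFOREST_NTREEFINAL = (200, 400, 600)

CP_RANGE = (1e-4, 1e-1)
N_CP = 20


@dataclass(frozen=True)
class OrdinalModelSpec:
    """One cell of the hyperparameter grid.  Fields irrelevant to the
    chosen family must be left at None."""

    family: str
    parallel: bool | None = None
    link: str | None = None
    alpha: str | None = None
    criterion: str | None = None
    cp: float | None = None
    split_cost: str | None = None
    prune_rule: str | None = None
    nsets: int | None = None
    ntreeperdiv: int | None = None
    ntreefinal: int | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        required = {
            "cumulative": ("parallel", "link"),
            "penalized": ("alpha", "criterion", "link"),
            "ocart": ("cp", "split_cost", "prune_rule"),
            "oforest": ("nsets", "ntreeperdiv", "ntreefinal"),
        }[self.family]
        allowed = set(required) | {"family"}
        for name, value in asdict(self).items():
            if name in allowed:
                if value is None:
                    raise ValueError(f"{self.family} spec requires {name}")
            elif value is not None:
                raise ValueError(f"field {name} is not used by family {self.family}")
        if self.family == "cumulative" and self.link not in LINK_NAMES:
            raise ValueError(f"cumulative link must be one of {LINK_NAMES}")
        if self.family == "penalized" and self.link not in PENALIZED_LINK_NAMES:
            raise ValueError(f"penalized link must be one of {PENALIZED_LINK_NAMES}")
        if self.family == "ocart" and self.cp < 0:
            raise ValueError("cp must be >= 0")

    def label(self) -> str:
        parts = [self.family]
        for name, value in asdict(self).items():
            if name != "family" and value is not None:
                v = f"{value:.6g}" if isinstance(value, float) else str(value)
                parts.append(f"{name}={v}")
        return "|".join(parts)


def draw_cp_values(seed: int, n_cp: int = N_CP, lo: float = CP_RANGE[0], hi: float = CP_RANGE[1]) -> np.ndarray:
    """The run's ocart complexity parameters: log-uniform on [lo, hi]."""
    rng = np.random.default_rng(seed)
    return np.sort(np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_cp)))


def enumerate_structures(
    seed: int = 0,
    n_cp: int = N_CP,
    oforest_nsets=OFOREST_NSETS,
    oforest_ntreeperdiv=OFOREST_NTREEPERDIV,
    oforest_ntreefinal=OFOREST_NTREEFINAL,
) -> list[OrdinalModelSpec]:
    """All model structures, in deterministic order (133 at defaults)."""
    specs: list[OrdinalModelSpec] = []
    for parallel in (True, False):
        for link in LINK_NAMES:
            specs.append(OrdinalModelSpec("cumulative", parallel=parallel, link=link))
    for alpha in ("ridge", "lasso"):
        for criterion in ("aic", "bic"):
            for link in PENALIZED_LINK_NAMES:
                specs.append(OrdinalModelSpec("penalized", alpha=alpha, criterion=criterion, link=link))
    for cp in draw_cp_values(seed, n_cp):
        for split_cost in ("absolute", "quadratic"):
            for prune_rule in ("misclassification_rate", "misclassification_cost"):
                specs.append(
                    OrdinalModelSpec("ocart", cp=float(cp), split_cost=split_cost, prune_rule=prune_rule)
                )
    for nsets in oforest_nsets:
        for ntreeperdiv in oforest_ntreeperdiv:
            for ntreefinal in oforest_ntreefinal:
                specs.append(
                    OrdinalModelSpec(
                        "oforest", nsets=int(nsets), ntreeperdiv=int(ntreeperdiv), ntreefinal=int(ntreefinal)
                    )
                )
    return specs


@dataclass
class FittedOrdinalModel:
    """A trained realization of one grid cell on one predictor set."""

    spec: OrdinalModelSpec
    payload: object  # family-specific fit object
    level_labels: np.ndarray
    n_features: int
    predictor_set_id: str = "all"
    converged: bool = True
    feature_names: list | None = None

    def _check_X(self, X) -> np.ndarray:
        if hasattr(X, "columns") and self.feature_names is not None:
            missing = [c for c in self.feature_names if c not in X.columns]
            if missing:
                raise ValueError(f"input is missing model columns: {missing}")
            X = X[self.feature_names].to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"model was fitted with {self.n_features} predictors, got {X.shape[1]}"
            )
        return X

    def predict(self, X) -> np.ndarray:
        return self.payload.predict(self._check_X(X))

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self.payload, "predict_proba"):
            raise AttributeError(f"family {self.spec.family} does not provide probabilities")
        return self.payload.predict_proba(self._check_X(X))


def fit_model(spec: OrdinalModelSpec, X, y, seed: int = 0,
              predictor_set_id: str = "all", feature_names=None,
              fast: bool = False) -> FittedOrdinalModel:
    """Fit one model structure; deterministic for identical seed and data.

    ``fast=True`` caps optimizer iterations and restarts (used inside
    cross-validation folds; final refits use the full settings).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if spec.family == "cumulative":
        payload = fit_cumulative_core(
            X, y, parallel=spec.parallel, link=spec.link, seed=seed,
            maxiter=150 if fast else 500, max_restarts=1 if fast else 3,
        )
        converged = payload.converged
    elif spec.family == "penalized":
        payload = fit_penalized_core(
            X, y, alpha=spec.alpha, criterion=spec.criterion, link=spec.link, seed=seed,
            n_lambda=10 if fast else 20, max_iter=150 if fast else 400,
        )
        converged = payload.converged
    elif spec.family == "ocart":
        payload = fit_ocart_core(
            X, y, cp=spec.cp, split_cost=spec.split_cost, prune_rule=spec.prune_rule, seed=seed
        )
        converged = True
    else:
        payload = fit_oforest_core(
            X, y, nsets=spec.nsets, ntreeperdiv=spec.ntreeperdiv,
            ntreefinal=spec.ntreefinal, seed=seed,
        )
        converged = True
    return FittedOrdinalModel(
        spec=spec, payload=payload, level_labels=payload.level_labels,
        n_features=X.shape[1], predictor_set_id=predictor_set_id,
        converged=converged, feature_names=list(feature_names) if feature_names is not None else None,
    )


def predict_levels(model: FittedOrdinalModel, X) -> np.ndarray:
    """One predicted level per row, always within the training level set;
    probabilistic families take the most probable level with ties broken
    toward the lower (healthier) level."""
    return model.predict(X)


def save_model(model: FittedOrdinalModel, path) -> None:
    """Persist a fitted model (joblib archive: spec, parameters, level
    labels and preprocessing reference) for bit-exact reload."""
    joblib.dump(model, Path(path))


def load_model(path) -> FittedOrdinalModel:
    return joblib.load(Path(path))
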