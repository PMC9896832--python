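"""Synthetic paired OKS / EQ-5D-5L cohort generator.

Knee-osteoarthritis cohorts show a dominant single latent health factor:
the first principal component of the 12 OKS items explains roughly
two-thirds of their variance, and every OKS item correlates negatively
with every EQ-5D-5L domain level (higher OKS item = better health,
higher EQ level = worse).  The generator reproduces that structure with
a one-factor graded-response-style threshold model:

    latent health   x_i ~ N(0, 1)                 (one draw per patient)
    item propensity y_ij = a_j * x_i + sd * e_ij  (e_ij ~ N(0,1) indep.)
    observed item   = ordinal bin of y_ij under item j's thresholds

OKS loadings ``a_j`` are positive and EQ loadings negative, so all
OKS-item x EQ-domain correlations come out negative.  Default
thresholds are set at normal quantiles of target marginal frequencies
(see :data:`EQ_LEVEL_COUNTS_ESTIMATION` and :data:`OKS_ITEM_MEANS`),
so simulated marginals approximate the study population the mapping
method was developed on.  Default sample sizes are 456 (estimation)
and 115 (external validation).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np
import pandas as pd
from scipy import stats

from .instruments import DOMAINS, OKS_N_ITEMS

__all__ = [
    "CohortSpec",
    "SimulatedCohort",
    "generate_cohort",
    "default_study_spec",
    "write_cohort",
    "read_cohort",
    "EQ_LEVEL_COUNTS_ESTIMATION",
    "OKS_ITEM_MEANS",
]

COHORT_COLUMNS = [f"oks_q{j + 1:02d}" for j in range(OKS_N_ITEMS)] + [
    f"eq_{d.lower()}" for d in DOMAINS
]

#: Published estimation-sample (n = 456) EQ-5D-5L level counts, used to
#: place the default domain thresholds (and to recompute baseline
#: accuracies: the baseline is the modal level's share).
EQ_LEVEL_COUNTS_ESTIMATION = {
    "MO": (121, 111, 103, 94, 27),
    "SC": (271, 61, 62, 38, 24),
    "UA": (112, 116, 113, 68, 47),
    "PD": (38, 140, 140, 77, 61),
    "AD": (118, 114, 138, 48, 38),
}

#: Published estimation-sample OKS item means (0-4 coding), one per item,
#: used to place the default item thresholds via a binomial(4, mean/4)
#: marginal shape.
OKS_ITEM_MEANS = (1.11, 3.06, 2.39, 2.70, 2.16, 2.38, 2.11, 2.16, 2.12, 2.44, 2.66, 1.98)

# Loadings calibrated once so that, with unit noise, the simulated
# cohort shows (i) all-negative OKS x EQ Spearman correlations spanning
# roughly -0.3 to -0.8 and (ii) a first principal component of the 12
# standardized items explaining ~0.66 of their variance.
_OKS_LOADINGS = (1.1, 2.0, 1.9, 2.1, 1.6, 1.8, 1.3, 1.5, 1.7, 1.8, 2.0, 1.4)
_EQ_LOADINGS = (-1.5, -1.2, -1.5, -1.4, -0.7)


def _check_thresholds(thresholds: np.ndarray, what: str, n_expected: int) -> np.ndarray:
    arr = np.asarray(thresholds, dtype=float)
    if arr.shape != (n_expected, 4):
        raise ValueError(f"{what} thresholds must have shape ({n_expected}, 4), got {arr.shape}")
    if not np.all(np.diff(arr, axis=1) > 0):
        raise ValueError(f"{what} thresholds must be strictly increasing within each row")
    return arr


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterization of one synthetic cohort draw."""

    n_patients: int
    latent_loadings_oks: tuple = _OKS_LOADINGS
    latent_loadings_eq: tuple = _EQ_LOADINGS
    noise_sd: float = 1.0
    oks_thresholds: tuple = None  # (12, 4); default derived from OKS_ITEM_MEANS
    eq_thresholds: tuple = None  # (5, 4); default derived from EQ_LEVEL_COUNTS_ESTIMATION
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0 (0 = deterministic items given the latent)")
        a = np.asarray(self.latent_loadings_oks, dtype=float)
        b = np.asarray(self.latent_loadings_eq, dtype=float)
        if a.shape != (OKS_N_ITEMS,) or b.shape != (len(DOMAINS),):
            raise ValueError("need 12 OKS loadings and 5 EQ loadings")
        if not (np.all(a > 0) and np.all(b < 0)) and not (np.all(a < 0) and np.all(b > 0)):
            raise ValueError(
                "OKS and EQ loadings must have opposite signs so that "
                "OKS-item x EQ-domain correlations are negative"
            )
        object.__setattr__(self, "latent_loadings_oks", tuple(a))
        object.__setattr__(self, "latent_loadings_eq", tuple(b))
        oks_t = (
            _default_oks_thresholds(a, self.noise_sd)
            if self.oks_thresholds is None
            else _check_thresholds(np.asarray(self.oks_thresholds), "OKS", OKS_N_ITEMS)
        )
        eq_t = (
            _default_eq_thresholds(b, self.noise_sd)
            if self.eq_thresholds is None
            else _check_thresholds(np.asarray(self.eq_thresholds), "EQ", len(DOMAINS))
        )
        object.__setattr__(self, "oks_thresholds", tuple(map(tuple, oks_t)))
        object.__setattr__(self, "eq_thresholds", tuple(map(tuple, eq_t)))


def _marginal_sd(loading: float, noise_sd: float) -> float:
    # the item propensity a*x + sd*e is N(0, sqrt(a^2 + sd^2))
    return float(np.hypot(loading, noise_sd))


def _thresholds_from_probs(probs: np.ndarray, scale: float) -> np.ndarray:
    """Normal-quantile thresholds reproducing category probabilities ``probs``."""
    cum = np.cumsum(probs)[:-1]
    cum = np.clip(cum, 1e-6, 1 - 1e-6)
    return stats.norm.ppf(cum) * scale


def _default_oks_thresholds(loadings: np.ndarray, noise_sd: float) -> np.ndarray:
    rows = []
    for mean, a in zip(OKS_ITEM_MEANS, loadings):
        p = stats.binom.pmf(np.arange(5), 4, mean / 4.0)
        rows.append(_thresholds_from_probs(p, _marginal_sd(a, noise_sd)))
    return np.array(rows)


def _default_eq_thresholds(loadings: np.ndarray, noise_sd: float) -> np.ndarray:
    rows = []
    for d, b in zip(DOMAINS, loadings):
        counts = np.asarray(EQ_LEVEL_COUNTS_ESTIMATION[d], dtype=float)
        rows.append(_thresholds_from_probs(counts / counts.sum(), _marginal_sd(b, noise_sd)))
    return np.array(rows)


@dataclass(frozen=True)
class SimulatedCohort:
    """A generated cohort: ordinal observations plus the hidden latent factor."""

    oks_items: np.ndarray  # (n, 12) ints in 0..4
    eq_levels: np.ndarray  # (n, 5) ints in 1..5
    latent_health: np.ndarray  # (n,) reals, retained for diagnostics

    def __post_init__(self):
        n = len(self.latent_health)
        if self.oks_items.shape != (n, OKS_N_ITEMS) or self.eq_levels.shape != (n, len(DOMAINS)):
            raise ValueError("row counts must agree across cohort fields")
        if self.oks_items.min() < 0 or self.oks_items.max() > 4:
            raise ValueError("OKS entries must lie in 0..4")
        if self.eq_levels.min() < 1 or self.eq_levels.max() > 5:
            raise ValueError("EQ entries must lie in 1..5")

    @property
    def n(self) -> int:
        return len(self.latent_health)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            np.hstack([self.oks_items, self.eq_levels]), columns=COHORT_COLUMNS
        )
        return df.astype(int)


def generate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Draw one cohort under ``spec``; identical spec (incl. seed) gives an
    identical cohort."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    x = rng.standard_normal(n)
    oks = np.empty((n, OKS_N_ITEMS), dtype=int)
    noise = rng.standard_normal((n, OKS_N_ITEMS + len(DOMAINS))) * spec.noise_sd
    oks_t = np.asarray(spec.oks_thresholds)
    for j, a in enumerate(spec.latent_loadings_oks):
        y = a * x + noise[:, j]
        oks[:, j] = np.searchsorted(oks_t[j], y)
    eq = np.empty((n, len(DOMAINS)), dtype=int)
    eq_t = np.asarray(spec.eq_thresholds)
    for d, b in enumerate(spec.latent_loadings_eq):
        y = b * x + noise[:, OKS_N_ITEMS + d]
        eq[:, d] = np.searchsorted(eq_t[d], y) + 1
    return SimulatedCohort(oks_items=oks, eq_levels=eq, latent_health=x)


def default_study_spec(role: str, seed: int | None = None) -> CohortSpec:
    """Calibrated default spec for the study's two samples.

    ``estimation`` gives n = 456 and ``validation`` n = 115; the two
    share the same population model (loadings, thresholds, noise) and
    differ only in sample size and seed.
    """
    if role == "estimation":
        return CohortSpec(n_patients=456, seed=456 if seed is None else seed)
    if role == "validation":
        return CohortSpec(n_patients=115, seed=115 if seed is None else seed)
    raise ValueError(f"unknown role {role!r}; expected 'estimation' or 'validation'")


def write_cohort(cohort: SimulatedCohort, path) -> None:
    cohort.to_frame().to_csv(path, index=False)


def read_cohort(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a cohort table (synthetic or real) with the standard header;
    returns ``(oks_items, eq_levels)``."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} missing columns: {missing}")
    oks = df[COHORT_COLUMNS[:OKS_N_ITEMS]].to_numpy(dtype=int)
    eq = df[COHORT_COLUMNS[OKS_N_ITEMS:]].to_numpy(dtype=int)
    if oks.min() < 0 or oks.max() > 4:
        raise ValueError("OKS items must lie in 0..4")
    if eq.min() < 1 or eq.max() > 5:
        raise ValueError("EQ levels must lie in 1..5")
    return oks, eq


def scaled_spec(spec: CohortSpec, loading_scale: float) -> CohortSpec:
    """Rescale every loading magnitude by ``loading_scale`` (diagnostic
    helper for coupling-strength checks); thresholds are re-derived."""
    a = tuple(v * loading_scale for v in spec.latent_loadings_oks)
    b = tuple(v * loading_scale for v in spec.latent_loadings_eq)
    return replace(spec, latent_loadings_oks=a, latent_loadings_eq=b,
                   oks_thresholds=None, eq_thresholds=None)
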