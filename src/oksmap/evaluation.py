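"""Accuracy and utility-error evaluation of the refitted winners.

Two accuracy notions per domain: *baseline* accuracy (the share of the
most common observed level — what predicting the mode with no model
achieves) and *crude* accuracy (the share of correct level
predictions).  Confidence intervals are percentile bootstrap over
patients.

Predicted domain levels are assembled into 5-digit EQ-5D-5L profiles
and converted to utilities under one or more value sets; errors are
summarized as MAE and MSE with percentile-bootstrap 95% CIs, plus MAE
within the strata above and below the median utility (observed
utilities stratify by default; the predicted-utility median is an
option).  Bootstrap resampling is over patients so the five domains
stay coupled within a resample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import DOMAINS, EQProfile, ValueSet, utilities

__all__ = [
    "AccuracyReport",
    "UtilityErrorReport",
    "baseline_accuracy",
    "crude_accuracy",
    "assemble_profiles",
    "utility_errors",
    "multi_valueset_summary",
    "conceptual_overlap",
]


def baseline_accuracy(y) -> float:
    """Proportion of the most common level (accuracy of the no-model
    modal prediction)."""
    y = np.asarray(y)
    if len(y) == 0:
        raise ValueError("empty outcome vector")
    _, counts = np.unique(y, return_counts=True)
    return float(counts.max() / len(y))


def _percentile_ci(values: np.ndarray, stat, B: int, rng: np.random.Generator, level=0.95):
    n = len(values)
    idx = rng.integers(0, n, size=(B, n))
    boot = np.array([stat(values[row]) for row in idx])
    lo, hi = np.percentile(boot, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    return float(lo), float(hi)


@dataclass
class AccuracyReport:
    domain: str
    sample: str  # 'estimation' | 'validation'
    baseline: float
    crude: float
    ci_low: float
    ci_high: float
    n: int


def crude_accuracy(
    pred, actual, domain: str = "", sample: str = "estimation",
    boot_B: int = 2000, seed: int = 0,
) -> AccuracyReport:
    """Proportion of exact level matches, with a percentile-bootstrap 95%
    CI over patients."""
    pred = np.asarray(pred)
    actual = np.asarray(actual)
    if len(pred) != len(actual):
        raise ValueError(f"length mismatch: {len(pred)} predictions vs {len(actual)} observations")
    hits = (pred == actual).astype(float)
    point = float(hits.mean())
    rng = np.random.default_rng(seed)
    lo, hi = _percentile_ci(hits, np.mean, boot_B, rng)
    lo, hi = min(lo, point), max(hi, point)
    return AccuracyReport(
        domain=domain, sample=sample, baseline=baseline_accuracy(actual),
        crude=point, ci_low=lo, ci_high=hi, n=len(actual),
    )


def assemble_profiles(domain_predictions) -> list[EQProfile]:
    """Combine five aligned level vectors (MO/SC/UA/PD/AD order) into
    per-patient EQ-5D-5L profiles."""
    vectors = [np.asarray(v) for v in domain_predictions]
    if len(vectors) != 5:
        raise ValueError("need exactly five domain level vectors")
    lengths = {len(v) for v in vectors}
    if len(lengths) != 1:
        raise ValueError(f"domain vectors are misaligned: lengths {sorted(lengths)}")
    return [EQProfile(tuple(int(v[i]) for v in vectors)) for i in range(lengths.pop())]


@dataclass
class UtilityErrorReport:
    value_set_id: str
    tariff_type: str
    mae: float
    mae_ci: tuple
    mse: float
    mse_ci: tuple
    mae_above_median: float
    mae_above_ci: tuple
    mae_below_median: float
    mae_below_ci: tuple
    n: int
    n_above: int
    n_below: int


def utility_errors(
    actual_profiles, predicted_profiles, vs: ValueSet,
    boot_B: int = 2000, seed: int = 0, stratify_by: str = "observed",
) -> UtilityErrorReport:
    """MAE and MSE between observed and predicted utilities under ``vs``,
    with percentile-bootstrap 95% CIs and a median-split MAE.

    The median split stratifies patients at the median of the observed
    utilities by default (``stratify_by='predicted'`` uses the
    predicted-utility median instead); the >= median stratum is the
    'above' group.
    """
    actual_profiles = list(actual_profiles)
    predicted_profiles = list(predicted_profiles)
    if len(actual_profiles) == 0:
        raise ValueError("empty profile vectors")
    if len(actual_profiles) != len(predicted_profiles):
        raise ValueError("actual and predicted profile vectors are misaligned")
    u_act = utilities(actual_profiles, vs)
    u_pred = utilities(predicted_profiles, vs)
    err = u_act - u_pred
    abs_err = np.abs(err)
    sq_err = err**2

    rng = np.random.default_rng(seed)
    mae = float(abs_err.mean())
    mse = float(sq_err.mean())
    mae_ci = _percentile_ci(abs_err, np.mean, boot_B, rng)
    mse_ci = _percentile_ci(sq_err, np.mean, boot_B, rng)

    strat = u_act if stratify_by == "observed" else u_pred
    med = float(np.median(strat))
    above = strat >= med
    below = ~above
    def _stratum(mask):
        if not mask.any():
            return float("nan"), (float("nan"), float("nan")), 0
        vals = abs_err[mask]
        return float(vals.mean()), _percentile_ci(vals, np.mean, boot_B, rng), int(mask.sum())

    mae_above, mae_above_ci, n_above = _stratum(above)
    mae_below, mae_below_ci, n_below = _stratum(below)
    return UtilityErrorReport(
        value_set_id=vs.country, tariff_type=vs.tariff_type,
        mae=mae, mae_ci=mae_ci, mse=mse, mse_ci=mse_ci,
        mae_above_median=mae_above, mae_above_ci=mae_above_ci,
        mae_below_median=mae_below, mae_below_ci=mae_below_ci,
        n=len(actual_profiles), n_above=n_above, n_below=n_below,
    )


def multi_valueset_summary(reports: list) -> pd.DataFrame:
    """Cross-value-set aggregation (mean, sd, min, max) of MAE and MSE,
    as the bottom rows of a per-country error table are built."""
    if not reports:
        raise ValueError("need at least one utility-error report")
    mae = np.array([r.mae for r in reports])
    mse = np.array([r.mse for r in reports])
    above = np.array([r.mae_above_median for r in reports])
    below = np.array([r.mae_below_median for r in reports])

    def agg(v):
        return {
            "mean": float(np.mean(v)),
            "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
            "min": float(np.min(v)),
            "max": float(np.max(v)),
        }

    return pd.DataFrame(
        {
            "mae": agg(mae),
            "mae_above_median": agg(above),
            "mae_below_median": agg(below),
            "mse": agg(mse),
        }
    )


def error_table(reports: list) -> pd.DataFrame:
    """Per-value-set error rows (one per tariff) with CI columns."""
    rows = []
    for r in reports:
        rows.append(
            {
                "country": r.value_set_id,
                "tariff_type": r.tariff_type,
                "mae": r.mae,
                "mae_ci_low": r.mae_ci[0],
                "mae_ci_high": r.mae_ci[1],
                "mae_above_median": r.mae_above_median,
                "mae_below_median": r.mae_below_median,
                "mse": r.mse,
                "mse_ci_low": r.mse_ci[0],
                "mse_ci_high": r.mse_ci[1],
                "n": r.n,
            }
        )
    return pd.DataFrame(rows)


def accuracy_table(reports: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "domain": r.domain,
                "sample": r.sample,
                "baseline": r.baseline,
                "crude": r.crude,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "n": r.n,
            }
            for r in reports
        ]
    )


def conceptual_overlap(oks_items, eq_levels, utility_values):
    """Conceptual-overlap diagnostics between the two instruments.

    Returns ``(spearman, ols)``: the 12 x 5 Spearman matrix between OKS
    items and EQ domain levels (NaN where a column is constant), and an
    exploratory OLS of utility on the total OKS score (slope,
    intercept, r_squared).
    """
    oks_items = np.asarray(oks_items)
    eq_levels = np.asarray(eq_levels)
    utility_values = np.asarray(utility_values, dtype=float)
    if not (len(oks_items) == len(eq_levels) == len(utility_values)):
        raise ValueError("inputs are misaligned")
    n_items = oks_items.shape[1]
    rho = np.full((n_items, eq_levels.shape[1]), np.nan)
    for j in range(n_items):
        if np.ptp(oks_items[:, j]) == 0:
            continue  # constant column: correlation undefined, left missing
        for d in range(eq_levels.shape[1]):
            if np.ptp(eq_levels[:, d]) == 0:
                continue
            rho[j, d] = stats.spearmanr(oks_items[:, j], eq_levels[:, d]).statistic
    spearman = pd.DataFrame(
        rho,
        index=[f"oks_q{j + 1:02d}" for j in range(n_items)],
        columns=list(DOMAINS),
    )
    totals = oks_items.sum(axis=1).astype(float)
    if np.ptp(totals) == 0:
        # degenerate regressor: slope undefined, reported missing
        ols = {"slope": np.nan, "intercept": np.nan, "r_squared": np.nan}
    else:
        res = stats.linregress(totals, utility_values)
        ols = {
            "slope": float(res.slope),
            "intercept": float(res.intercept),
            "r_squared": float(res.rvalue**2),
        }
    return spearman, ols
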