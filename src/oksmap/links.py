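"""Link functions for cumulative (ordinal) regression.

A link maps a cumulative probability ``p`` in (0, 1) onto an unbounded
real scale where a linear predictor can act.  Five links are supported:

========  ==========================================  =================
name      forward g(p)                                inverse F(z)
========  ==========================================  =================
logit     log(p / (1 - p))                            1 / (1 + e^{-z})
probit    Phi^{-1}(p)  (standard-normal quantile)     Phi(z)
cauchit   tan(pi * (p - 0.5))                         standard Cauchy CDF
cloglog   log(-log(1 - p))                            1 - exp(-exp(z))
logc      -log(1 - p)                                 1 - exp(-z), z >= 0
========  ==========================================  =================

``logc`` is one-sided: its forward map is defined on [0, 1) and its
inverse returns valid probabilities only for z >= 0.  It is used only
for the unpenalized cumulative family, with the top cumulative
probability pinned at 1 and negative linear predictors clipped to
probability 0 (floored inside the likelihood).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["LINK_NAMES", "PENALIZED_LINK_NAMES", "link_forward", "link_inverse", "link_density"]

LINK_NAMES = ("logit", "probit", "cauchit", "cloglog", "logc")
# logc is excluded from the penalized family's grid.
PENALIZED_LINK_NAMES = ("logit", "probit", "cauchit", "cloglog")


def _check_name(name: str) -> None:
    if name not in LINK_NAMES:
        raise ValueError(f"unknown link {name!r}; expected one of {LINK_NAMES}")


def link_forward(name: str, p):
    """Map cumulative probability ``p`` to the unbounded linear scale.

    Raises ``ValueError`` for probabilities outside the link's domain:
    (0, 1) for the two-sided links, [0, 1) for ``logc``.
    """
    _check_name(name)
    p = np.asarray(p, dtype=float)
    lo_ok = p >= 0.0 if name == "logc" else p > 0.0
    if not np.all(lo_ok & (p < 1.0)):
        raise ValueError(f"probability outside the domain of link {name!r}")
    if name == "logit":
        return np.log(p / (1.0 - p))
    if name == "probit":
        if np.any(p <= 0.0):
            raise ValueError("probit requires p in (0, 1)")
        return stats.norm.ppf(p)
    if name == "cauchit":
        return np.tan(np.pi * (p - 0.5))
    if name == "cloglog":
        return np.log(-np.log(1.0 - p))
    # logc
    return -np.log(1.0 - p)


def link_inverse(name: str, z):
    """Inverse link: unbounded scale back to cumulative probability.

    For ``logc`` the inverse is clipped to 0 below z = 0 (one-sided link).
    """
    _check_name(name)
    z = np.asarray(z, dtype=float)
    if name == "logit":
        return stats.logistic.cdf(z)
    if name == "probit":
        return stats.norm.cdf(z)
    if name == "cauchit":
        return stats.cauchy.cdf(z)
    if name == "cloglog":
        # 1 - exp(-exp(z)), stable for large |z|
        return -np.expm1(-np.exp(np.clip(z, -700.0, 700.0)))
    # logc: p = 1 - exp(-z) for z >= 0, else 0
    return np.where(z > 0.0, -np.expm1(-np.clip(z, 0.0, 700.0)), 0.0)


def link_density(name: str, z):
    """d/dz of the inverse link (the latent density), used in gradients."""
    _check_name(name)
    z = np.asarray(z, dtype=float)
    if name == "logit":
        return stats.logistic.pdf(z)
    if name == "probit":
        return stats.norm.pdf(z)
    if name == "cauchit":
        return stats.cauchy.pdf(z)
    if name == "cloglog":
        zc = np.clip(z, -700.0, 30.0)
        return np.exp(zc - np.exp(zc))
    # logc: density exp(-z) on z >= 0, 0 elsewhere
    return np.where(z > 0.0, np.exp(-np.clip(z, 0.0, 700.0)), 0.0)
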