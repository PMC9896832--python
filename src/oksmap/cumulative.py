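"""Cumulative (link) ordinal regression, parallel and non-parallel.

The cumulative model treats an ordinal outcome with levels
1 < 2 < ... < K as the binning of a latent continuous variable and
models the cumulative probabilities

    P(y <= k | x) = F(theta_k - eta_k(x)),    k = 1..K-1,

where ``F`` is the inverse of one of five link functions (see
:mod:`oksmap.links`) and the linear predictor is shared across
thresholds under the *parallel* assumption (``eta_k = x'beta``;
proportional odds when the link is logit) or threshold-specific
otherwise (``eta_k = x'beta_k``).

Non-parallel fits can produce crossing cumulative curves, i.e. negative
implied category probabilities.  The likelihood floors category
probabilities at ``CROSSING_EPS`` and the fit reports a
``crossing_detected`` flag whenever any training-point category
probability had to be floored at the optimum; downstream prediction
clips the cumulative curve to be non-decreasing.

Fitting is quasi-Newton (L-BFGS-B) on the negative log-likelihood with
analytic gradients; thresholds are kept ordered through a
log-increment parameterization.  On non-convergence the optimizer is
restarted from up to three jittered starts and the fit is flagged, not
silently accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .links import link_density, link_forward, link_inverse

__all__ = ["CumulativeFit", "fit_cumulative_core", "nll_parallel"]

CROSSING_EPS = 1e-10
_PROB_FLOOR = 1e-12


def _encode_levels(y) -> tuple[np.ndarray, np.ndarray]:
    labels, codes = np.unique(np.asarray(y), return_inverse=True)
    if len(labels) < 2:
        raise ValueError("outcome has a single level; cannot fit an ordinal model")
    return labels, codes


_MAX_LOG_INCREMENT = 30.0  # keeps exp() finite in degenerate fits


def _theta_from_params(t: np.ndarray) -> np.ndarray:
    """Ordered thresholds from (theta_1, log-increments)."""
    if len(t) == 1:
        return t.copy()
    inc = np.exp(np.clip(t[1:], -_MAX_LOG_INCREMENT, _MAX_LOG_INCREMENT))
    return t[0] + np.concatenate([[0.0], np.cumsum(inc)])


def _params_from_theta(theta: np.ndarray) -> np.ndarray:
    if len(theta) == 1:
        return theta.copy()
    d = np.diff(theta)
    return np.concatenate([[theta[0]], np.log(np.maximum(d, 1e-6))])


def _chain_theta_grad(g_theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Pull a gradient w.r.t. thresholds back to (theta_1, log-increments)."""
    out = np.empty_like(t)
    out[0] = g_theta.sum()
    if len(t) > 1:
        # theta_m depends on delta_j for all m >= j (1-based increments)
        tail = np.cumsum(g_theta[::-1])[::-1]
        inc = np.exp(np.clip(t[1:], -_MAX_LOG_INCREMENT, _MAX_LOG_INCREMENT))
        out[1:] = inc * tail[1:]
    return out


def _nll_and_grad(params, X, codes, K, link, parallel):
    """Negative log-likelihood, its gradient, and the count of floored
    (crossing) category probabilities."""
    n, p = X.shape
    m = K - 1
    t = params[:m]
    theta = _theta_from_params(t)
    if parallel:
        beta = params[m:]
        eta = X @ beta  # (n,)
        zu = np.where(codes < m, theta[np.minimum(codes, m - 1)] - eta, np.inf)
        zl = np.where(codes > 0, theta[np.maximum(codes - 1, 0)] - eta, -np.inf)
    else:
        B = params[m:].reshape(m, p)
        eta_u = np.einsum("np,np->n", X, B[np.minimum(codes, m - 1)])
        eta_l = np.einsum("np,np->n", X, B[np.maximum(codes - 1, 0)])
        zu = np.where(codes < m, theta[np.minimum(codes, m - 1)] - eta_u, np.inf)
        zl = np.where(codes > 0, theta[np.maximum(codes - 1, 0)] - eta_l, -np.inf)

    Fu = np.where(np.isposinf(zu), 1.0, link_inverse(link, zu))
    Fl = np.where(np.isneginf(zl), 0.0, link_inverse(link, zl))
    pi_raw = Fu - Fl
    n_crossing = int(np.sum(pi_raw < CROSSING_EPS))
    pi = np.maximum(pi_raw, CROSSING_EPS)
    nll = -np.sum(np.log(np.maximum(pi, _PROB_FLOOR)))

    # gradient; flat where the probability was floored (barrier clip)
    active = pi_raw >= CROSSING_EPS
    fu = np.where(np.isposinf(zu), 0.0, link_density(link, zu))
    fl = np.where(np.isneginf(zl), 0.0, link_density(link, zl))
    w_u = np.where(active, -fu / pi, 0.0)  # dNLL/dz_upper
    w_l = np.where(active, fl / pi, 0.0)  # dNLL/dz_lower

    g_theta = np.zeros(m)
    has_u = codes < m
    has_l = codes > 0
    np.add.at(g_theta, codes[has_u], w_u[has_u])
    np.add.at(g_theta, codes[has_l] - 1, w_l[has_l])
    g_t = _chain_theta_grad(g_theta, t)

    if parallel:
        g_beta = -(X * (w_u + w_l)[:, None]).sum(axis=0)
        grad = np.concatenate([g_t, g_beta])
    else:
        g_B = np.zeros((m, p))
        Xu = X[has_u] * w_u[has_u, None]
        np.add.at(g_B, codes[has_u], -Xu)
        Xl = X[has_l] * w_l[has_l, None]
        np.add.at(g_B, codes[has_l] - 1, -Xl)
        grad = np.concatenate([g_t, g_B.ravel()])
    return nll, grad, n_crossing


def nll_parallel(theta: np.ndarray, beta: np.ndarray, X, codes, K, link) -> float:
    """Negative log-likelihood of a parallel cumulative model at explicit
    natural parameters (used by oracles and penalized fitting)."""
    params = np.concatenate([_params_from_theta(np.asarray(theta, float)),
                             np.asarray(beta, float)])
    nll, _, _ = _nll_and_grad(params, np.asarray(X, float), codes, K, link, True)
    return float(nll)


@dataclass
class CumulativeFit:
    """A fitted cumulative model in natural parameters."""

    link: str
    parallel: bool
    level_labels: np.ndarray
    theta: np.ndarray  # (K-1,) ordered thresholds
    beta: np.ndarray  # (p,) if parallel else (K-1, p)
    nll: float
    converged: bool
    crossing_detected: bool = False
    n_obs: int = 0
    se_beta: np.ndarray | None = None
    se_theta: np.ndarray | None = None

    @property
    def n_levels(self) -> int:
        return len(self.level_labels)

    def cumulative_probs(self, X) -> np.ndarray:
        """P(y <= k | x) for k = 1..K-1, clipped non-decreasing across k."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        m = self.n_levels - 1
        if self.parallel:
            z = self.theta[None, :] - (X @ self.beta)[:, None]
        else:
            z = self.theta[None, :] - X @ self.beta.T
        cum = link_inverse(self.link, z)
        return np.maximum.accumulate(cum, axis=1)

    def predict_proba(self, X) -> np.ndarray:
        cum = self.cumulative_probs(X)
        full = np.hstack([np.zeros((len(cum), 1)), cum, np.ones((len(cum), 1))])
        return np.diff(full, axis=1)

    def predict(self, X) -> np.ndarray:
        """Most probable level per row; ties broken toward the lower level."""
        proba = self.predict_proba(X)
        return self.level_labels[np.argmax(proba, axis=1)]


def _start_params(codes, K, link, p, parallel, rng=None):
    freq = np.bincount(codes, minlength=K).astype(float)
    cum = np.cumsum(freq)[:-1] / freq.sum()
    cum = np.clip(cum, 1e-3, 1 - 1e-3)
    theta0 = np.sort(np.asarray(link_forward(link, cum), dtype=float))
    theta0 += np.arange(K - 1) * 1e-3  # de-tie
    t0 = _params_from_theta(theta0)
    nb = p if parallel else (K - 1) * p
    params = np.concatenate([t0, np.zeros(nb)])
    if rng is not None:
        params = params + rng.normal(scale=0.2, size=len(params))
    return params


def fit_cumulative_core(
    X,
    y,
    parallel: bool = True,
    link: str = "logit",
    compute_se: bool = False,
    max_restarts: int = 3,
    maxiter: int = 500,
    seed: int = 0,
) -> CumulativeFit:
    """Maximum-likelihood fit of the cumulative model.

    Predictors must be finite; the outcome must show at least two
    levels.  Separation or non-convergence is reported through the
    ``converged`` flag (after up to ``max_restarts`` jittered restarts),
    never silently.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(X)):
        raise ValueError("predictors must be finite")
    labels, codes = _encode_levels(y)
    K = len(labels)
    n, p = X.shape

    def objective(params):
        nll, grad, _ = _nll_and_grad(params, X, codes, K, link, parallel)
        return nll, grad

    rng = np.random.default_rng(seed)
    best = None
    converged = False
    for attempt in range(max_restarts + 1):
        x0 = _start_params(codes, K, link, p, parallel, rng if attempt else None)
        res = optimize.minimize(
            objective, x0, jac=True, method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        if res.success or np.max(np.abs(res.jac)) < 1e-3:
            converged = True
            best = res if res.fun <= best.fun + 1e-9 else best
            break

    m = K - 1
    theta = _theta_from_params(best.x[:m])
    beta = best.x[m:] if parallel else best.x[m:].reshape(m, p)
    _, _, n_crossing = _nll_and_grad(best.x, X, codes, K, link, parallel)
    fit = CumulativeFit(
        link=link, parallel=parallel, level_labels=labels, theta=theta, beta=beta,
        nll=float(best.fun), converged=bool(converged),
        crossing_detected=bool(n_crossing > 0), n_obs=n,
    )
    if compute_se and parallel:
        fit.se_theta, fit.se_beta = _parallel_se(best.x, X, codes, K, link)
    return fit


def _parallel_se(params, X, codes, K, link):
    """Delta-method standard errors from a finite-difference Hessian of the
    NLL in natural parameters (theta, beta)."""
    m = K - 1
    theta = _theta_from_params(params[:m])
    natural = np.concatenate([theta, params[m:]])

    def nll_nat(q):
        qq = np.concatenate([_params_from_theta(q[:m]), q[m:]])
        val, _, _ = _nll_and_grad(qq, X, codes, K, link, True)
        return val

    d = len(natural)
    h = 1e-4 * np.maximum(np.abs(natural), 1.0)
    H = np.empty((d, d))
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = h[i]
            ej = np.zeros(d); ej[j] = h[j]
            fpp = nll_nat(natural + ei + ej)
            fpm = nll_nat(natural + ei - ej)
            fmp = nll_nat(natural - ei + ej)
            fmm = nll_nat(natural - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(d, np.nan)
    return se[:m], se[m:]
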