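"""Maximum-likelihood negative binomial fit to the degree distribution.

Daily contact counts are strongly over-dispersed, so the degree distribution
is modelled as negative binomial in the ecological (mu, k) parameterization:
mean ``mu`` and dispersion ``k`` with variance ``mu + mu^2/k`` — small ``k``
means heavy over-dispersion, ``k -> inf`` recovers the Poisson.  The fit is
by direct maximisation of the log-likelihood in log-parameters (both
parameters are positive); standard errors come from the observed information
at the optimum.

Censored observations (degree truncated at the reporting cap) are treated as
exact values by default; ``censor_limit`` switches on a proper right-censored
likelihood term for sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

_K_MAX = 1e6


@dataclass
class NBFit:
    mu: float
    k: float
    loglik: float
    se_mu: float
    se_k: float
    converged: bool
    n: int
    censor_limit: Optional[int] = None

    def pmf(self, x) -> np.ndarray:
        return stats.nbinom.pmf(x, self.k, self.k / (self.k + self.mu))


def nb_loglik(degrees: np.ndarray, mu: float, k: float,
              censor_limit: Optional[int] = None) -> float:
    """Log-likelihood of NB(mu, k) for observed degrees.

    With ``censor_limit`` set, observations equal to the limit contribute
    the right-tail mass P(X >= limit) instead of a point mass.
    """
    p = k / (k + mu)
    if censor_limit is None:
        return float(stats.nbinom.logpmf(degrees, k, p).sum())
    cens = degrees >= censor_limit
    ll = stats.nbinom.logpmf(degrees[~cens], k, p).sum()
    if cens.any():
        ll += cens.sum() * stats.nbinom.logsf(censor_limit - 1, k, p)
    return float(ll)


def _moment_init(degrees: np.ndarray) -> tuple[float, float]:
    m = degrees.mean()
    v = degrees.var(ddof=1)
    if v > m > 0:
        return float(m), float(m * m / (v - m))
    return float(max(m, 1e-3)), 10.0


def fit_negative_binomial(
    degrees: Sequence[int],
    init: Optional[tuple[float, float]] = None,
    tol: float = 1e-10,
    censor_limit: Optional[int] = None,
) -> NBFit:
    """Fit NB(mu, k) by maximum likelihood.

    Parameters
    ----------
    degrees
        Non-negative integer counts, at least 10 of them.
    init
        Optional (mu, k) starting point; defaults to moment estimates.
    tol
        Optimizer tolerance on the negative log-likelihood.
    censor_limit
        If given, values at/above this limit are treated as right-censored.

    Under-dispersed samples (variance <= mean) produce a warning and a fit
    pinned at the dispersion upper bound; constant input raises, since the
    likelihood is then unbounded in k.
    """
    x = np.asarray(degrees, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 observations")
    if np.any(x < 0) or np.any(x != np.floor(x)):
        raise ValueError("degrees must be non-negative integers")
    x = x.astype(np.int64)
    m, v = x.mean(), x.var(ddof=1)
    if v == 0:
        raise ValueError("constant input: dispersion is unidentifiable")

    underdispersed = v <= m
    if underdispersed:
        warnings.warn(
            "variance <= mean: data are not over-dispersed; "
            f"dispersion reported at its upper bound {_K_MAX:g}",
            stacklevel=2,
        )

    mu0, k0 = init if init is not None else _moment_init(x)

    def nll(theta: np.ndarray) -> float:
        mu, k = np.exp(theta)
        if not np.isfinite(mu) or not np.isfinite(k):
            return np.inf
        return -nb_loglik(x, mu, min(k, _K_MAX), censor_limit)

    best = None
    starts = [np.log([mu0, k0])]
    # grid fallback over dispersion if the first start fails to converge
    starts += [np.log([mu0, 10.0 ** g]) for g in (-1.0, 0.0, 1.0, 2.0)]
    for theta0 in starts:
        res = optimize.minimize(nll, theta0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": tol,
                                         "maxiter": 5000})
        if best is None or res.fun < best.fun:
            best = res
        if best.success and theta0 is not starts[0]:
            break

    mu_hat, k_hat = np.exp(best.x)
    if underdispersed or k_hat > _K_MAX:
        k_hat = _K_MAX
        mu_hat = float(x.mean())

    hess = _hessian(lambda p: -nb_loglik(x, p[0], p[1], censor_limit),
                    np.array([mu_hat, min(k_hat, _K_MAX)]))
    se_mu = se_k = float("nan")
    try:
        cov = np.linalg.inv(hess)
        if cov[0, 0] > 0:
            se_mu = float(np.sqrt(cov[0, 0]))
        if cov[1, 1] > 0:
            se_k = float(np.sqrt(cov[1, 1]))
    except np.linalg.LinAlgError:
        pass

    return NBFit(
        mu=float(mu_hat),
        k=float(k_hat),
        loglik=float(-best.fun),
        se_mu=se_mu,
        se_k=se_k,
        converged=bool(best.success) and not underdispersed,
        n=int(x.size),
        censor_limit=censor_limit,
    )


def _hessian(f, x0: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian with relative steps."""
    n = x0.size
    h = rel_step * np.maximum(np.abs(x0), 1.0)
    H = np.empty((n, n))
    f0 = f(x0)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x0 + ei) - 2 * f0 + f(x0 - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x0 + ei + ej) - f(x0 + ei - ej)
                    - f(x0 - ei + ej) + f(x0 - ei - ej)
                ) / (4 * h[i] * h[j])
    return H


def degree_histogram(
    degrees: Sequence[int], fit: NBFit, max_degree: Optional[int] = None
) -> pd.DataFrame:
    """Observed relative frequencies and fitted NB mass on a shared support.

    Returns a DataFrame with columns ``degree``, ``observed`` (relative
    frequency, summing to 1 when the support covers the data) and ``fitted``
    (NB pmf, summing to <= 1 over the plotted range).
    """
    x = np.asarray(degrees, dtype=np.int64)
    hi = int(max_degree if max_degree is not None else x.max())
    support = np.arange(hi + 1)
    counts = np.bincount(x[x <= hi], minlength=hi + 1)
    return pd.DataFrame(
        {
            "degree": support,
            "observed": counts / x.size,
            "fitted": fit.pmf(support),
        }
    )
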