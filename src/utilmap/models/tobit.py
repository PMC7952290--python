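"""Maximum-likelihood Tobit regression with upper censoring.

Health utilities pile up at the full-health ceiling of 1; the Tobit model
treats observed utility as y = min(y*, 1) with latent y* ~ N(x'b, s^2).
The log-likelihood is

    sum_{uncensored} [ log phi((y - x'b)/s) - log s ]
  + sum_{censored}   log(1 - Phi((1 - x'b)/s))

maximised over (b, log s) by quasi-Newton (BFGS) with the analytic score.

Prediction uses the censored expectation

    E[min(y*, 1)] = x'b * Phi(a) - s * phi(a) + 1 - Phi(a),   a = (1 - x'b)/s

which is strictly below 1 for any finite (b, s); the cruder min(x'b, 1) is
available as an alternative.
"""

from __future__ import annotations

import warnings
from typing import Optional, Tuple

import numpy as np
from scipy import optimize, special
from scipy.stats import norm

from ..exceptions import ConvergenceWarning, DegenerateDataError

TOBIT_MAX_ITER = 200
TOBIT_TOL = 1e-8
_CENSOR_EPS = 1e-12


def _mills_log(z):
    """phi(z)/Phi(z) computed in log space for numerical stability."""
    return np.exp(norm.logpdf(z) - special.log_ndtr(z))


class TobitModel:
    """Upper-censored normal regression, censoring point ``censor``."""

    def __init__(self, y, X, censor: float = 1.0):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.censor = float(censor)
        self.cens = self.y >= self.censor - _CENSOR_EPS
        if self.cens.all():
            raise DegenerateDataError("all observations are censored at the ceiling")
        self.n, self.k = self.X.shape

    # parameter vector: [beta (k), log sigma]
    def loglike_obs(self, params) -> np.ndarray:
        beta, logsig = params[:-1], params[-1]
        sigma = np.exp(logsig)
        mu = self.X @ beta
        out = np.empty(self.n)
        r = (self.y[~self.cens] - mu[~self.cens]) / sigma
        out[~self.cens] = norm.logpdf(r) - logsig
        z = (mu[self.cens] - self.censor) / sigma
        out[self.cens] = special.log_ndtr(z)
        return out

    def loglike(self, params) -> float:
        return float(np.sum(self.loglike_obs(params)))

    def score_obs(self, params) -> np.ndarray:
        """Per-observation gradient of the log-likelihood, (n, k+1)."""
        beta, logsig = params[:-1], params[-1]
        sigma = np.exp(logsig)
        mu = self.X @ beta
        g = np.empty((self.n, self.k + 1))
        # uncensored
        r = (self.y - mu) / sigma
        g[~self.cens, : self.k] = self.X[~self.cens] * (r[~self.cens] / sigma)[:, None]
        g[~self.cens, self.k] = r[~self.cens] ** 2 - 1.0
        # censored: d/dbeta log Phi(z) with z = (mu - c)/sigma
        z = (mu[self.cens] - self.censor) / sigma
        lam = _mills_log(z)
        g[self.cens, : self.k] = self.X[self.cens] * (lam / sigma)[:, None]
        g[self.cens, self.k] = -lam * z
        return g

    def fit(self, maxiter: int = TOBIT_MAX_ITER, tol: float = TOBIT_TOL):
        """BFGS maximisation; returns (params, converged, iterations).

        Internally the design columns are max-abs rescaled (an exact
        reparameterisation) so indicator and age columns condition the
        optimiser comparably; returned coefficients are on the original
        scale.
        """
        from .base import column_scales

        scales = column_scales(self.X)
        scaled = TobitModel.__new__(TobitModel)
        scaled.y, scaled.X, scaled.censor = self.y, self.X / scales, self.censor
        scaled.cens, scaled.n, scaled.k = self.cens, self.n, self.k

        beta0, *_ = np.linalg.lstsq(scaled.X, self.y, rcond=None)
        resid = self.y - scaled.X @ beta0
        sigma0 = max(np.std(resid), 1e-3)
        x0 = np.concatenate([beta0, [np.log(sigma0)]])

        def neg(params):
            return -scaled.loglike(params)

        def grad(params):
            return -scaled.score_obs(params).sum(axis=0)

        res = optimize.minimize(
            neg, x0, jac=grad, method="BFGS",
            options={"maxiter": maxiter, "gtol": tol},
        )
        res.x[:-1] /= scales
        gnorm = np.max(np.abs(grad(np.concatenate(
            [res.x[:-1] * scales, res.x[-1:]]))))
        converged = bool(res.success) or gnorm < 1e-4 * max(1.0, abs(res.fun))
        if not converged:
            warnings.warn(
                f"Tobit did not converge within {maxiter} iterations "
                f"({res.message}); keeping the last iterate",
                ConvergenceWarning,
                stacklevel=2,
            )
        return res.x, converged, int(res.nit)

    def hessian(self, params, eps: float = 1e-5) -> np.ndarray:
        """Central-difference Hessian of the log-likelihood via the score."""
        p = len(params)
        H = np.empty((p, p))
        for j in range(p):
            step = np.zeros(p)
            step[j] = eps * max(1.0, abs(params[j]))
            gp = self.score_obs(params + step).sum(axis=0)
            gm = self.score_obs(params - step).sum(axis=0)
            H[:, j] = (gp - gm) / (2 * step[j])
        return (H + H.T) / 2.0


def tobit_expected(mu, sigma: float, censor: float = 1.0) -> np.ndarray:
    """E[min(y*, censor)] for y* ~ N(mu, sigma^2); strictly < censor.

    Computed as censor - [(censor - mu) * Phi(a) + sigma * phi(a)] with
    a = (censor - mu)/sigma; the bracketed shortfall is positive for all
    finite (mu, sigma) by the Mills-ratio inequality, so the expectation
    stays below the ceiling (up to float saturation for mu far above it).
    """
    mu = np.asarray(mu, dtype=float)
    a = (censor - mu) / sigma
    shortfall = (censor - mu) * norm.cdf(a) + sigma * norm.pdf(a)
    return censor - shortfall
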