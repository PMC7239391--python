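"""Hierarchical Poisson-lognormal model: likelihood layers, priors, posterior.

The model for registration counts is

    C_i ~ Poisson(theta_i * E_i)
    theta_i ~ Lognormal(mu_i, sigma^2),   mu = X beta
    beta_j ~ Normal(0, 1e4),  sigma^2 ~ Inverse-Gamma(1, 0.001)

with E_i the person-years exposure of cell i.  The lognormal layer absorbs
overdispersion relative to a plain Poisson GLM.  All latent-rate computation
is done on the log-theta scale; theta itself only appears at interfaces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .design_matrix import DesignMatrix
from .registry_data import RegistrationTable

__all__ = [
    "ModelParameters",
    "BETA_PRIOR_VAR",
    "SIGMA2_PRIOR_SHAPE",
    "SIGMA2_PRIOR_SCALE",
    "poisson_loglik",
    "lognormal_layer_loglik",
    "log_prior",
    "log_posterior",
    "map_beta_degenerate",
]

#: Vague prior scales: beta_j ~ N(0, 1e4); sigma^2 ~ Inverse-Gamma(shape 1,
#: scale 0.001), i.e. the precision 1/sigma^2 is Gamma(1, rate 0.001).
BETA_PRIOR_VAR = 1.0e4
SIGMA2_PRIOR_SHAPE = 1.0
SIGMA2_PRIOR_SCALE = 0.001

#: Floor applied to log pmf when a zero mean meets a positive count.
_NEG_GUARD = -1.0e12


@dataclass
class ModelParameters:
    """Full parameter state: coefficients, layer variance, latent log rates."""

    beta: np.ndarray
    sigma2: float
    log_theta: np.ndarray

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.log_theta = np.asarray(self.log_theta, dtype=float)
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")


def poisson_loglik(count, exposure, theta) -> float:
    """Summed log Poisson pmf of counts with mean theta * exposure.

    Degenerate mean 0 with a positive count gets a large negative finite
    value instead of -inf so optimisers and MH ratios stay well defined.
    """
    C = np.asarray(count, dtype=float)
    E = np.asarray(exposure, dtype=float)
    th = np.asarray(theta, dtype=float)
    if np.any(th <= 0):
        raise ValueError("theta must be positive")
    lam = th * E
    with np.errstate(divide="ignore"):
        ll = C * np.log(lam) - lam - special.gammaln(C + 1.0)
    ll = np.where(np.isfinite(ll), ll, _NEG_GUARD)
    return float(np.sum(ll))


def poisson_loglik_log_rate(count, exposure, log_theta) -> np.ndarray:
    """Per-cell log Poisson pmf parameterised by log theta (no overflow for
    moderate log rates; used by the samplers)."""
    C = np.asarray(count, dtype=float)
    E = np.asarray(exposure, dtype=float)
    u = np.asarray(log_theta, dtype=float)
    lam = np.exp(u + np.log(E))
    return C * (u + np.log(E)) - lam - special.gammaln(C + 1.0)


def lognormal_layer_loglik(log_theta, mu, sigma2: float) -> float:
    """Gaussian log density of log theta around mu with variance sigma2.

    This is the lognormal layer expressed on the log scale (the Jacobian
    theta^-1 belongs to the density in theta, not in log theta).
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    u = np.asarray(log_theta, dtype=float)
    m = np.asarray(mu, dtype=float)
    resid = u - m
    n = u.size
    return float(
        -0.5 * n * np.log(2.0 * np.pi * sigma2) - 0.5 * np.sum(resid**2) / sigma2
    )


def inverse_gamma_logpdf(x: float, shape: float, scale: float) -> float:
    """log density of Inverse-Gamma(shape, scale): x^-(shape+1) exp(-scale/x)."""
    if x <= 0:
        return -np.inf
    return float(
        shape * np.log(scale) - special.gammaln(shape) - (shape + 1.0) * np.log(x) - scale / x
    )


def log_prior(beta, sigma2: float) -> float:
    """Vague prior: independent N(0, 1e4) on each coefficient and
    Inverse-Gamma(1, 0.001) on the layer variance; -inf for sigma2 <= 0."""
    if sigma2 <= 0:
        return -np.inf
    b = np.asarray(beta, dtype=float)
    lp_beta = float(
        -0.5 * b.size * np.log(2.0 * np.pi * BETA_PRIOR_VAR)
        - 0.5 * np.sum(b**2) / BETA_PRIOR_VAR
    )
    return lp_beta + inverse_gamma_logpdf(sigma2, SIGMA2_PRIOR_SHAPE, SIGMA2_PRIOR_SCALE)


def log_posterior(
    params: ModelParameters, design: DesignMatrix, table: RegistrationTable
) -> float:
    """Unnormalised log posterior of (beta, sigma2, log theta)."""
    if params.beta.size != design.n_params:
        raise ValueError(
            f"beta length {params.beta.size} != design columns {design.n_params}"
        )
    if params.log_theta.size != design.n_cells or len(table) != design.n_cells:
        raise ValueError("log_theta / table / design dimensions inconsistent")
    mu = design.X @ params.beta
    lp = float(
        np.sum(poisson_loglik_log_rate(table.counts, table.exposures, params.log_theta))
    )
    lp += lognormal_layer_loglik(params.log_theta, mu, params.sigma2)
    lp += log_prior(params.beta, params.sigma2)
    return lp


def map_beta_degenerate(design: DesignMatrix, table: RegistrationTable) -> np.ndarray:
    """MAP coefficients in the sigma2 -> 0 limit.

    With the layer collapsed (log theta pinned to mu) the model is a Poisson
    GLM with log link and offset log E; the N(0, 1e4) ridge keeps the Hessian
    positive definite.  Newton iterations on the penalised log likelihood.
    """
    X = design.X
    C = table.counts.astype(float)
    logE = np.log(table.exposures)
    beta = np.linalg.lstsq(X, np.log((C + 0.5) / table.exposures), rcond=None)[0]

    def negloglik_grad_hess(b):
        eta = X @ b + logE
        lam = np.exp(eta)
        nll = -(C @ eta - lam.sum()) + 0.5 * b @ b / BETA_PRIOR_VAR
        grad = -X.T @ (C - lam) + b / BETA_PRIOR_VAR
        H = (X * lam[:, None]).T @ X + np.eye(b.size) / BETA_PRIOR_VAR
        return nll, grad, H

    for _ in range(100):
        nll, g, H = negloglik_grad_hess(beta)
        step = np.linalg.solve(H, g)
        # damped Newton: halve until the objective does not increase
        t = 1.0
        for _ in range(30):
            cand = beta - t * step
            if negloglik_grad_hess(cand)[0] <= nll + 1e-12:
                break
            t /= 2.0
        beta = cand
        if np.max(np.abs(t * step)) < 1e-10:
            break
    else:  # pragma: no cover - Newton converges quickly on these problems
        raise RuntimeError("MAP Newton iteration did not converge")
    return beta
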