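"""Metropolis-within-Gibbs sampler for the Poisson-lognormal hierarchy.

Update scheme per sweep:

* beta   — exact draw from its Gaussian full conditional (Bayesian linear
           regression of log theta on X with the N(0, 1e4 I) prior);
* sigma2 — exact draw from Inverse-Gamma(1 + n/2, 0.001 + RSS/2);
* log theta — one adaptive random-walk Metropolis update per cell; the
           conditionals factorise over cells, so all cells are proposed and
           accepted/rejected in a single vectorised step.

Step sizes adapt towards a 0.44 acceptance rate during burn-in only, so the
retained draws come from a fixed transition kernel.  Model comparison uses
the deviance information criterion with the latent rates integrated out of
the Poisson likelihood by Gauss-Hermite quadrature (so the deviance is a
function of beta and sigma2, the parameters the selection acts on); the
theta-conditional deviance version is reported alongside.  Bayes factors
are supported through a Laplace approximation of the marginal likelihood at
the posterior mode.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, special

from .design_matrix import DesignMatrix
from .plm_model import (
    BETA_PRIOR_VAR,
    SIGMA2_PRIOR_SCALE,
    SIGMA2_PRIOR_SHAPE,
    log_prior,
    poisson_loglik_log_rate,
)
from .registry_data import RegistrationTable

__all__ = [
    "SamplerConfig",
    "PosteriorDraws",
    "DICResult",
    "SelectionStep",
    "SelectionTrace",
    "update_beta",
    "update_sigma2",
    "update_log_theta",
    "run_chain",
    "dic",
    "marginal_poisson_loglik",
    "log_marginal_likelihood_laplace",
    "forward_select",
    "save_draws",
    "load_draws",
]


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC run settings.  The seed is mandatory: runs are reproducible by
    construction and the seed is recorded in the output."""

    seed: int
    n_chains: int = 2
    n_iterations: int = 4000
    burn_in: int = 2000
    thinning: int = 2
    adapt_window: int = 50
    target_accept: float = 0.44
    init_step: float = 0.3

    def __post_init__(self):
        if not (0 <= self.burn_in < self.n_iterations):
            raise ValueError("require 0 <= burn_in < n_iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")

    @property
    def n_retained_per_chain(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thinning


@dataclass
class PosteriorDraws:
    """Retained MCMC draws, stacked over chains, plus diagnostics."""

    beta: np.ndarray        # (n_draws, P)
    sigma2: np.ndarray      # (n_draws,)
    log_theta: np.ndarray   # (n_draws, n_cells)
    chain_id: np.ndarray    # (n_draws,)
    columns: list[str]
    accept_rate: np.ndarray  # per-cell mean acceptance after burn-in
    ess: dict[str, float]
    rhat: dict[str, float]
    config: SamplerConfig

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def beta_mean(self) -> np.ndarray:
        return self.beta.mean(axis=0)

    def sigma2_mean(self) -> float:
        return float(self.sigma2.mean())

    def log_theta_mean(self) -> np.ndarray:
        return self.log_theta.mean(axis=0)

    def _per_chain(self, x: np.ndarray) -> np.ndarray:
        chains = np.unique(self.chain_id)
        return np.stack([x[self.chain_id == c] for c in chains])


# ----------------------------------------------------------------------
# full-conditional updates
# ----------------------------------------------------------------------

def update_beta(
    log_theta: np.ndarray,
    X: np.ndarray,
    sigma2: float,
    rng: np.random.Generator,
    XtX: np.ndarray | None = None,
) -> np.ndarray:
    """Exact draw from the Gaussian full conditional of beta.

    Precision A = X'X / sigma2 + I / 1e4, mean A^-1 X' log_theta / sigma2.
    """
    P = X.shape[1]
    if XtX is None:
        XtX = X.T @ X
    A = XtX / sigma2 + np.eye(P) / BETA_PRIOR_VAR
    b = X.T @ log_theta / sigma2
    try:
        L = np.linalg.cholesky(A)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular posterior precision for beta: rescale covariates or "
            "reduce the model specification"
        ) from exc
    mean = np.linalg.solve(A, b)  # via cholesky would be fine too
    z = rng.standard_normal(P)
    return mean + np.linalg.solve(L.T, z)


def update_sigma2(
    log_theta: np.ndarray, mu: np.ndarray, rng: np.random.Generator
) -> float:
    """Exact Inverse-Gamma draw for the lognormal layer variance."""
    resid = log_theta - mu
    shape = SIGMA2_PRIOR_SHAPE + resid.size / 2.0
    scale = SIGMA2_PRIOR_SCALE + 0.5 * float(resid @ resid)
    return float(scale / rng.gamma(shape, 1.0))


def update_log_theta(
    log_theta: np.ndarray,
    mu: np.ndarray,
    sigma2: float,
    counts: np.ndarray,
    log_exposures: np.ndarray,
    steps: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One vectorised random-walk Metropolis update per cell.

    The target factorises over cells: p(u_i) prop Poisson(C_i | e^{u_i} E_i)
    * Normal(u_i | mu_i, sigma2), so each cell is an independent scalar MH
    step.  Returns (new log_theta, per-cell acceptance indicator).
    """
    u = log_theta
    prop = u + steps * rng.standard_normal(u.size)
    eta_old = u + log_exposures
    eta_new = prop + log_exposures
    # Poisson log-likelihood difference plus Gaussian layer difference
    delta = (
        counts * (eta_new - eta_old)
        - (np.exp(eta_new) - np.exp(eta_old))
        - ((prop - mu) ** 2 - (u - mu) ** 2) / (2.0 * sigma2)
    )
    accept = np.log(rng.random(u.size)) < delta
    out = np.where(accept, prop, u)
    return out, accept.astype(float)


def _initial_state(
    design: DesignMatrix, table: RegistrationTable, rng: np.random.Generator
) -> tuple[np.ndarray, float, np.ndarray]:
    """Moment-style initialisation: regress log((C+0.5)/E) on X; latent log
    rates start at the observed values; sigma2 at 0.1.  Zero counts are
    handled by the +0.5 continuity correction."""
    y = np.log((table.counts + 0.5) / table.exposures)
    beta = np.linalg.lstsq(design.X, y, rcond=None)[0]
    beta = beta + 0.01 * rng.standard_normal(beta.size)
    return beta, 0.1, y.copy()


def run_chain(
    table: RegistrationTable, design: DesignMatrix, config: SamplerConfig
) -> PosteriorDraws:
    """Run the Metropolis-within-Gibbs sampler.

    Deterministic given ``config.seed``; chains use independent seeds spawned
    from it.  Split-Rhat and bulk ESS are computed for every beta coefficient
    and sigma2; a warning is emitted when any Rhat exceeds 1.05.
    """
    X = design.X
    XtX = X.T @ X
    counts = table.counts.astype(float)
    logE = np.log(table.exposures)
    n = len(table)

    keep = config.n_retained_per_chain
    all_beta = np.empty((config.n_chains, keep, design.n_params))
    all_sigma2 = np.empty((config.n_chains, keep))
    all_theta = np.empty((config.n_chains, keep, n))
    accept_sum = np.zeros(n)
    accept_n = 0

    root = np.random.SeedSequence(config.seed)
    for c, ss in enumerate(root.spawn(config.n_chains)):
        rng = np.random.default_rng(ss)
        beta, sigma2, log_theta = _initial_state(design, table, rng)
        mu = X @ beta
        if not np.isfinite(
            np.sum(poisson_loglik_log_rate(counts, table.exposures, log_theta))
            + log_prior(beta, sigma2)
        ):
            raise RuntimeError("non-finite log posterior at the initial state")
        steps = np.full(n, config.init_step)
        k = 0
        for it in range(config.n_iterations):
            log_theta, acc = update_log_theta(
                log_theta, mu, sigma2, counts, logE, steps, rng
            )
            if it < config.burn_in:
                # Robbins-Monro adaptation towards the target acceptance rate
                gamma = (1.0 + it / config.adapt_window) ** -0.6
                steps = steps * np.exp(gamma * (acc - config.target_accept))
                np.clip(steps, 1e-4, 10.0, out=steps)
            else:
                accept_sum += acc
                accept_n += 1
            beta = update_beta(log_theta, X, sigma2, rng, XtX)
            mu = X @ beta
            sigma2 = update_sigma2(log_theta, mu, rng)
            if it >= config.burn_in and (it - config.burn_in) % config.thinning == 0:
                if k < keep:
                    all_beta[c, k] = beta
                    all_sigma2[c, k] = sigma2
                    all_theta[c, k] = log_theta
                    k += 1

    ess, rhat = _diagnostics(all_beta, all_sigma2, design.columns)
    bad = {k: v for k, v in rhat.items() if v > 1.05}
    if bad:
        warnings.warn(f"split-Rhat above 1.05 for {sorted(bad)}", stacklevel=2)

    chain_id = np.repeat(np.arange(config.n_chains), keep)
    return PosteriorDraws(
        beta=all_beta.reshape(-1, design.n_params),
        sigma2=all_sigma2.reshape(-1),
        log_theta=all_theta.reshape(-1, n),
        chain_id=chain_id,
        columns=list(design.columns),
        accept_rate=accept_sum / max(accept_n, 1),
        ess=ess,
        rhat=rhat,
        config=config,
    )


def _diagnostics(
    beta: np.ndarray, sigma2: np.ndarray, columns: Sequence[str]
) -> tuple[dict[str, float], dict[str, float]]:
    """Bulk ESS and split-Rhat per scalar parameter via ArviZ."""
    import arviz as az

    if beta.shape[0] == 1:
        # single chain: split it in half so split-Rhat is still defined
        half = beta.shape[1] // 2
        beta = np.stack([beta[0, :half], beta[0, half : 2 * half]])
        sigma2 = np.stack([sigma2[0, :half], sigma2[0, half : 2 * half]])
    data = {c: beta[:, :, j] for j, c in enumerate(columns)}
    data["sigma2"] = sigma2
    idata = az.convert_to_dataset(data)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ess_ds = az.ess(idata)
        rhat_ds = az.rhat(idata)
    ess = {k: float(ess_ds[k].values) for k in data}
    rhat = {k: float(rhat_ds[k].values) for k in data}
    return ess, rhat


# ----------------------------------------------------------------------
# DIC and marginal likelihood
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class DICResult:
    """DIC with the latent rates marginalised by quadrature (``marginal``,
    the model-selection quantity) and the theta-conditional variant
    (``conditional``), plus the mean deviances behind them."""

    marginal: float
    conditional: float
    mean_marginal_loglik: float
    plugin_marginal_loglik: float

    def __float__(self) -> float:  # pragma: no cover - convenience
        return self.marginal


def marginal_poisson_loglik(
    counts: np.ndarray,
    exposures: np.ndarray,
    mu: np.ndarray,
    sigma2: float,
    n_nodes: int = 21,
) -> float:
    """log f(D | beta, sigma2): the Poisson likelihood with log theta
    integrated against Normal(mu, sigma2), cell by cell.

    Uses adaptive Gauss-Hermite quadrature: each cell's node grid is
    centred at the mode of its integrand with the Laplace width.  A grid
    centred naively at mu with width sigma would under-resolve the Poisson
    factor in high-count cells (likelihood width ~ C^-1/2 << sigma), which
    biases model comparisons by several deviance units.
    """
    C = np.asarray(counts, dtype=float)
    E = np.asarray(exposures, dtype=float)
    mu = np.asarray(mu, dtype=float)

    # Newton iterations for the per-cell mode of
    # h(u) = C u - E e^u - (u - mu)^2 / (2 sigma2)   (+ const)
    u = np.where(C > 0, np.log((C + 0.5) / E), mu)
    for _ in range(50):
        eu = E * np.exp(u)
        grad = C - eu - (u - mu) / sigma2
        hess = -eu - 1.0 / sigma2
        step = grad / hess
        u = u - np.clip(step, -2.0, 2.0)
        if np.max(np.abs(step)) < 1e-10:
            break
    s = 1.0 / np.sqrt(E * np.exp(u) + 1.0 / sigma2)  # Laplace width

    x, w = np.polynomial.hermite_e.hermegauss(n_nodes)  # probabilists'
    nodes = u[:, None] + s[:, None] * x[None, :]
    h = (
        poisson_loglik_log_rate(C[:, None], E[:, None], nodes)
        - (nodes - mu[:, None]) ** 2 / (2.0 * sigma2)
        - 0.5 * np.log(2.0 * np.pi * sigma2)
    )
    logw = np.log(w) + 0.5 * x**2
    per_cell = np.log(s) + special.logsumexp(h + logw[None, :], axis=1)
    return float(np.sum(per_cell))


def dic(
    draws: PosteriorDraws,
    table: RegistrationTable,
    design: DesignMatrix,
    max_draws: int = 200,
    n_nodes: int = 21,
) -> DICResult:
    """DIC = -4 E[log f(D|beta)] + 2 log f(D|beta_hat).

    ``f`` is the Poisson likelihood with the latent rates integrated out, so
    the deviance is a function of (beta, sigma2); the expectation runs over
    retained draws (at most ``max_draws``, evenly thinned) and the plug-in
    uses posterior means.  The theta-conditional variant evaluates the
    Poisson likelihood at the theta draws instead.
    """
    if draws.n_draws < 100:
        raise ValueError("need at least 100 retained draws for DIC")
    counts = table.counts.astype(float)
    E = table.exposures
    idx = np.unique(np.linspace(0, draws.n_draws - 1, max_draws).astype(int))
    mlls = np.array(
        [
            marginal_poisson_loglik(
                counts, E, design.X @ draws.beta[i], draws.sigma2[i], n_nodes
            )
            for i in idx
        ]
    )
    plugin = marginal_poisson_loglik(
        counts, E, design.X @ draws.beta_mean(), draws.sigma2_mean(), n_nodes
    )
    marginal = -4.0 * float(mlls.mean()) + 2.0 * plugin

    clls = np.array(
        [
            float(np.sum(poisson_loglik_log_rate(counts, E, draws.log_theta[i])))
            for i in idx
        ]
    )
    cplug = float(
        np.sum(poisson_loglik_log_rate(counts, E, draws.log_theta_mean()))
    )
    conditional = -4.0 * float(clls.mean()) + 2.0 * cplug
    return DICResult(
        marginal=marginal,
        conditional=conditional,
        mean_marginal_loglik=float(mlls.mean()),
        plugin_marginal_loglik=plugin,
    )


def log_marginal_likelihood_laplace(
    table: RegistrationTable,
    design: DesignMatrix,
    n_nodes: int = 21,
    start: np.ndarray | None = None,
) -> float:
    """Laplace approximation of log P(D | model).

    Maximises the theta-marginalised log posterior over phi = (beta,
    log sigma2) and applies log P(D) ~= g(phi_hat) + d/2 log(2 pi)
    - 1/2 log |-H|, with H the finite-difference Hessian of g at the mode.
    """
    counts = table.counts.astype(float)
    E = table.exposures
    X = design.X
    P = design.n_params

    def g(phi: np.ndarray) -> float:
        beta, log_s2 = phi[:P], phi[P]
        s2 = float(np.exp(log_s2))
        lp = log_prior(beta, s2) + log_s2  # + Jacobian d sigma2 / d log sigma2
        return marginal_poisson_loglik(counts, E, X @ beta, s2, n_nodes) + lp

    if start is None:
        y = np.log((counts + 0.5) / E)
        start = np.append(np.linalg.lstsq(X, y, rcond=None)[0], np.log(0.05))
    res = optimize.minimize(
        lambda p: -g(p), start, method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-10},
    )
    phi = res.x
    d = phi.size
    H = _numeric_hessian(g, phi)
    sign, logdet = np.linalg.slogdet(-H)
    if sign <= 0:
        # mode Hessian not negative definite (flat direction); fall back to
        # a ridge-regularised determinant
        H = H - 1e-6 * np.eye(d)
        sign, logdet = np.linalg.slogdet(-H)
    return float(g(phi) + 0.5 * d * np.log(2.0 * np.pi) - 0.5 * logdet)


def _numeric_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    d = x.size
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h**2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h**2)
    return H


# ----------------------------------------------------------------------
# forward model selection
# ----------------------------------------------------------------------

@dataclass
class SelectionStep:
    term: str
    dic: float
    accepted: bool
    log_bayes_factor: float | None = None


@dataclass
class SelectionTrace:
    """Ordered record of the greedy forward-selection path."""

    steps: list[SelectionStep] = field(default_factory=list)
    selected: list[str] = field(default_factory=list)
    dic_path: list[float] = field(default_factory=list)

    def validate(self) -> None:
        """Accepted steps strictly decrease DIC or carry Bayes factor > 3."""
        current = np.inf if not self.dic_path else self.dic_path[0]
        for s in self.steps:
            if s.accepted:
                ok = s.dic < current or (
                    s.log_bayes_factor is not None and s.log_bayes_factor > np.log(3.0)
                )
                if not ok:
                    raise AssertionError(f"invalid acceptance of {s.term}")
                current = min(current, s.dic)


def _subdesign(design: DesignMatrix, labels: Sequence[str]) -> DesignMatrix:
    idx = [design.columns.index(c) for c in labels]
    return DesignMatrix(
        X=design.X[:, idx],
        columns=list(labels),
        scalers=design.scalers,
        contrasts=design.contrasts,
        spec=design.spec,
    )


def forward_select(
    terms: Mapping[str, Sequence[str]],
    table: RegistrationTable,
    design: DesignMatrix,
    config: SamplerConfig,
    dependencies: Mapping[str, Sequence[str]] | None = None,
    use_bayes_factor: bool = False,
    dic_draws: int = 500,
    min_dic_decrease: float = 5.0,
) -> SelectionTrace:
    """Greedy forward inclusion of term groups by DIC decrease.

    ``terms`` maps a term name to the design-column labels it contributes
    (e.g. ``{"age": ["age^1", "age^2"], "age:year": ["age^1:year^1"]}``);
    ``dependencies`` restricts interactions to be eligible only once their
    main effects are in.  Each candidate model is fitted with the full
    sampler and scored by the theta-marginalised DIC; when
    ``use_bayes_factor`` is set, a candidate that fails the DIC test is
    still accepted if its Laplace Bayes factor against the current model
    exceeds 3.  The full trace of evaluations is returned.

    A candidate must lower the DIC by at least ``min_dic_decrease`` (default
    5, the conventional smallest difference worth a mention): a chance-
    aligned null term typically moves DIC by only a couple of units, which
    a strict any-decrease rule would mistake for support.
    """
    dependencies = dependencies or {}
    active = ["intercept"]
    remaining = [t for t in terms]
    trace = SelectionTrace()

    def fit_dic(labels: Sequence[str]) -> float:
        sub = _subdesign(design, labels)
        draws = run_chain(table, sub, config)
        return dic(draws, table, sub, max_draws=dic_draws).marginal

    current_dic = fit_dic(active)
    trace.dic_path.append(current_dic)
    current_lml = (
        log_marginal_likelihood_laplace(table, _subdesign(design, active))
        if use_bayes_factor
        else None
    )

    improved = True
    while improved and remaining:
        improved = False
        eligible = [
            t
            for t in remaining
            if all(dep in trace.selected for dep in dependencies.get(t, ()))
        ]
        best: tuple[float, str, float | None] | None = None
        for t in eligible:
            labels = active + list(terms[t])
            cand_dic = fit_dic(labels)
            log_bf = None
            if use_bayes_factor and current_lml is not None:
                cand_lml = log_marginal_likelihood_laplace(
                    table, _subdesign(design, labels)
                )
                log_bf = cand_lml - current_lml
            accepted_candidate = cand_dic < current_dic - min_dic_decrease or (
                log_bf is not None and log_bf > np.log(3.0)
            )
            trace.steps.append(
                SelectionStep(term=t, dic=cand_dic, accepted=False, log_bayes_factor=log_bf)
            )
            if accepted_candidate and (best is None or cand_dic < best[0]):
                best = (cand_dic, t, log_bf)
        if best is not None:
            cand_dic, t, log_bf = best
            for s in reversed(trace.steps):
                if s.term == t and s.dic == cand_dic:
                    s.accepted = True
                    break
            active += list(terms[t])
            trace.selected.append(t)
            remaining.remove(t)
            if use_bayes_factor and log_bf is not None and current_lml is not None:
                current_lml = current_lml + log_bf
            current_dic = min(current_dic, cand_dic)
            trace.dic_path.append(cand_dic)
            improved = True
    return trace


# ----------------------------------------------------------------------
# persistence
# ----------------------------------------------------------------------

def save_draws(draws: PosteriorDraws, path: str | Path, include_theta: bool = True) -> None:
    """Persist draws as a JSON header line followed by CSV columns.

    Columns: chain, sigma2, one per beta coefficient, and (optionally) one
    per latent cell log rate (theta_0 ... theta_{n-1}).
    """
    path = Path(path)
    header = {
        "seed": draws.config.seed,
        "n_chains": draws.config.n_chains,
        "n_iterations": draws.config.n_iterations,
        "burn_in": draws.config.burn_in,
        "thinning": draws.config.thinning,
        "columns": draws.columns,
        "n_cells": int(draws.log_theta.shape[1]),
        "include_theta": include_theta,
    }
    with open(path, "w") as fh:
        fh.write("#" + json.dumps(header) + "\n")
        names = ["chain", "sigma2"] + draws.columns
        mats = [draws.chain_id[:, None], draws.sigma2[:, None], draws.beta]
        if include_theta:
            names += [f"theta_{i}" for i in range(draws.log_theta.shape[1])]
            mats.append(draws.log_theta)
        fh.write(",".join(names) + "\n")
        np.savetxt(fh, np.hstack(mats), delimiter=",", fmt="%.10g")


def load_draws(path: str | Path) -> PosteriorDraws:
    """Inverse of :func:`save_draws` (diagnostics are not re-derived)."""
    path = Path(path)
    with open(path) as fh:
        header = json.loads(fh.readline().lstrip("#"))
        data = np.loadtxt(fh, delimiter=",", skiprows=1, ndmin=2)
    P = len(header["columns"])
    n = header["n_cells"]
    chain = data[:, 0].astype(int)
    sigma2 = data[:, 1]
    beta = data[:, 2 : 2 + P]
    if header.get("include_theta", True):
        log_theta = data[:, 2 + P : 2 + P + n]
    else:
        log_theta = np.empty((data.shape[0], 0))
    config = SamplerConfig(
        seed=header["seed"],
        n_chains=header["n_chains"],
        n_iterations=header["n_iterations"],
        burn_in=header["burn_in"],
        thinning=header["thinning"],
    )
    return PosteriorDraws(
        beta=beta,
        sigma2=sigma2,
        log_theta=log_theta,
        chain_id=chain,
        columns=list(header["columns"]),
        accept_rate=np.array([]),
        ess={},
        rhat={},
        config=config,
    )
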