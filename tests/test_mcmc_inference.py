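"""Sampler correctness: conjugate updates vs closed forms, Metropolis
marginal vs quadrature, determinism, DIC behaviour, forward selection."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import canmorb as cm
from canmorb.mcmc_inference import (
    marginal_poisson_loglik,
    log_marginal_likelihood_laplace,
    update_beta,
    update_log_theta,
    update_sigma2,
)
from canmorb.registry_data import RegistrationTable

from conftest import make_small_table


# ----------------------------------------------------------------- beta

def test_update_beta_single_column_closed_form():
    """Posterior precision X'X/s2 + 1/1e4, mean via the normal equations."""
    rng = np.random.default_rng(0)
    X = np.linspace(-1, 1, 50)[:, None]
    u = 2.0 * X[:, 0] + rng.normal(0, 0.3, 50)
    s2 = 0.09
    A = float(X[:, 0] @ X[:, 0]) / s2 + 1e-4
    mean = float(X[:, 0] @ u) / s2 / A
    draws = np.array(
        [update_beta(u, X, s2, np.random.default_rng(s))[0] for s in range(4000)]
    )
    assert draws.mean() == pytest.approx(mean, abs=4 * np.sqrt(1 / A / 4000) + 1e-9)
    assert draws.var() == pytest.approx(1 / A, rel=0.15)


def test_update_beta_flat_prior_limit_is_ols():
    """With small s2 the ridge 1/1e4 is negligible: conditional mean -> OLS."""
    rng = np.random.default_rng(1)
    X = np.column_stack([np.ones(200), rng.normal(size=200)])
    u = X @ np.array([-6.0, 0.8]) + rng.normal(0, 0.1, 200)
    s2 = 1e-6
    draws = np.array(
        [update_beta(u, X, s2, np.random.default_rng(s)) for s in range(50)]
    )
    ols = np.linalg.lstsq(X, u, rcond=None)[0]
    np.testing.assert_allclose(draws.mean(axis=0), ols, rtol=1e-3)


# --------------------------------------------------------------- sigma2

def test_update_sigma2_zero_residuals_gives_prior_scale():
    """log theta == mu: posterior is IG(1 + n/2, 0.001)."""
    mu = np.full(10, -6.0)
    draws = np.array(
        [update_sigma2(mu, mu, np.random.default_rng(s)) for s in range(4000)]
    )
    # IG(6, 0.001) has mean 0.001/5
    assert draws.mean() == pytest.approx(0.001 / 5, rel=0.1)
    assert (draws > 0).all()


def test_update_sigma2_known_residual_sum():
    """n=4, RSS=2: IG(3, 1.001) with mean 1.001/2."""
    mu = np.zeros(4)
    u = np.array([1.0, -1.0, 0.0, 0.0]) * np.sqrt(1.0)  # RSS = 2
    draws = np.array(
        [update_sigma2(u, mu, np.random.default_rng(s)) for s in range(6000)]
    )
    assert draws.mean() == pytest.approx(1.001 / 2, rel=0.08)
    # full distribution against the closed form
    ks = stats.kstest(draws, stats.invgamma(a=3.0, scale=1.001).cdf).statistic
    assert ks < 0.03


def test_update_sigma2_concentrates_with_n():
    rng = np.random.default_rng(4)
    true = 0.3
    for n in (200, 5000):
        mu = np.zeros(n)
        u = rng.normal(0, np.sqrt(true), n)
        draws = np.array(
            [update_sigma2(u, mu, np.random.default_rng(s)) for s in range(300)]
        )
        assert draws.mean() == pytest.approx(true, rel=0.3 if n == 200 else 0.08)


# ------------------------------------------------------------ log theta

def test_log_theta_zero_count_cells_move_down():
    """At C=0 the Poisson factor is decreasing in theta, so the conditional
    mode sits below mu and accepted moves drift downward on average."""
    n = 2000
    mu = np.full(n, np.log(20.0 / 1e4))
    u = mu.copy()
    rng = np.random.default_rng(0)
    counts = np.zeros(n)
    logE = np.full(n, np.log(1e4))
    for _ in range(200):
        u, _ = update_log_theta(u, mu, 0.25, counts, logE, np.full(n, 0.3), rng)
    assert u.mean() < mu.mean() - 0.5


def test_log_theta_zero_step_flags_stuck_chain():
    n = 5
    mu = np.zeros(n)
    u = np.full(n, -1.0)
    rng = np.random.default_rng(0)
    new, acc = update_log_theta(
        u, mu, 1.0, np.ones(n), np.zeros(n), np.zeros(n), rng
    )
    assert (new == u).all() and (acc == 1.0).all()


def quadrature_conditional_cdf(counts, E, mu, s2):
    """Normalised CDF of p(u) prop Poisson(C|e^u E) N(u|mu, s2) on a grid."""
    us = np.linspace(mu - 8, mu + 8, 20001)
    logf = counts * (us + np.log(E)) - np.exp(us + np.log(E)) - (
        (us - mu) ** 2
    ) / (2 * s2)
    f = np.exp(logf - logf.max())
    cdf = np.cumsum(f)
    cdf /= cdf[-1]
    return us, cdf


def test_single_cell_metropolis_marginal_matches_quadrature():
    """Long-run MH histogram for one cell vs the quadrature CDF: KS < 0.05."""
    C, E, mu, s2 = 7.0, 5.0e3, np.log(1.0e-3), 0.3
    rng = np.random.default_rng(9)
    u = np.array([mu])
    kept = []
    step = np.array([0.8])
    for it in range(60_000):
        u, _ = update_log_theta(
            u, np.array([mu]), s2, np.array([C]), np.array([np.log(E)]), step, rng
        )
        if it >= 5000 and it % 5 == 0:
            kept.append(u[0])
    kept = np.array(kept)
    us, cdf = quadrature_conditional_cdf(C, E, mu, s2)
    emp_at = np.searchsorted(us, np.sort(kept))
    theory = cdf[np.clip(emp_at, 0, len(us) - 1)]
    ks = np.max(np.abs(theory - np.arange(1, len(kept) + 1) / len(kept)))
    assert ks < 0.05


# ------------------------------------------------------------ run_chain

def test_run_chain_deterministic_given_seed(small_table):
    design = cm.build_design(cm.default_spec("lung"), small_table)
    cfg = cm.SamplerConfig(seed=5, n_chains=2, n_iterations=300, burn_in=100)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        d1 = cm.run_chain(small_table, design, cfg)
        d2 = cm.run_chain(small_table, design, cfg)
    np.testing.assert_array_equal(d1.beta, d2.beta)
    np.testing.assert_array_equal(d1.sigma2, d2.sigma2)
    np.testing.assert_array_equal(d1.log_theta, d2.log_theta)


def test_intercept_only_recovers_pooled_rate():
    rng = np.random.default_rng(2)
    rows = []
    for k in range(60):
        rows.append(
            {
                "age_band": ["45-49", "60-64", "85+"][k % 3],
                "year": 2000 + k // 3,
                "gender": "male",
                "region": "London",
                "count": int(rng.poisson(50)),
                "exposure": 1e5,
            }
        )
    table = RegistrationTable(pd.DataFrame(rows), cancer_type="lung", validate=False)
    design = cm.DesignMatrix(
        X=np.ones((60, 1)), columns=["intercept"], scalers={}, contrasts={},
        spec=cm.ModelSpec(cancer_type="lung"),
    )
    cfg = cm.SamplerConfig(seed=11, n_chains=2, n_iterations=1500, burn_in=500)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        draws = cm.run_chain(table, design, cfg)
    pooled = table.counts.sum() / table.exposures.sum()
    post_rate = np.exp(draws.log_theta.mean())
    assert post_rate == pytest.approx(pooled, rel=0.03)


def test_sampler_config_validation():
    with pytest.raises(ValueError):
        cm.SamplerConfig(seed=1, n_iterations=100, burn_in=100)
    with pytest.raises(ValueError):
        cm.SamplerConfig(seed=1, thinning=0)


# ------------------------------------------------------------------ DIC

def _degenerate_draws(table, design, beta, sigma2, n=120):
    u = design.X @ beta
    return cm.PosteriorDraws(
        beta=np.tile(beta, (n, 1)),
        sigma2=np.full(n, sigma2),
        log_theta=np.tile(u, (n, 1)),
        chain_id=np.zeros(n, dtype=int),
        columns=list(design.columns),
        accept_rate=np.array([]),
        ess={},
        rhat={},
        config=cm.SamplerConfig(seed=0, n_iterations=n + 1, burn_in=0, thinning=1),
    )


def test_dic_collapses_for_degenerate_posterior(small_table):
    design = cm.build_design(cm.default_spec("lung"), small_table)
    beta = np.zeros(design.n_params)
    beta[0] = np.log(
        small_table.counts.sum() / small_table.exposures.sum()
    )
    draws = _degenerate_draws(small_table, design, beta, 0.05)
    res = cm.dic(draws, small_table, design)
    mll = marginal_poisson_loglik(
        small_table.counts.astype(float),
        small_table.exposures,
        design.X @ beta,
        0.05,
    )
    assert res.marginal == pytest.approx(-2.0 * mll)


def test_dic_requires_enough_draws(small_table):
    design = cm.build_design(cm.default_spec("lung"), small_table)
    draws = _degenerate_draws(small_table, design, np.zeros(design.n_params), 0.05, n=50)
    with pytest.raises(ValueError, match="100"):
        cm.dic(draws, small_table, design)


def test_marginal_loglik_quadrature_vs_dense_integration():
    """Adaptive Gauss-Hermite vs brute trapezoid, low and high counts."""
    for C, E, mu, s2 in [
        (0.0, 1e5, -7.0, 0.02),
        (3.0, 1e3, -5.8, 0.05),
        (900.0, 2e5, np.log(900 / 2e5), 0.02),
    ]:
        us = np.linspace(mu - 6, mu + 6, 200001)
        vals = stats.poisson.logpmf(C, np.exp(us) * E) + stats.norm.logpdf(
            us, mu, np.sqrt(s2)
        )
        m = vals.max()
        brute = m + np.log(np.trapezoid(np.exp(vals - m), us))
        ours = marginal_poisson_loglik(
            np.array([C]), np.array([E]), np.array([mu]), s2
        )
        assert ours == pytest.approx(brute, abs=1e-8)


def test_dic_prefers_true_age_effect():
    """Nested model comparison on data generated with a real age effect."""
    wins = 0
    for rep in range(5):
        truth = cm.GeneratorTruth(
            spec=cm.ModelSpec(cancer_type="lung", max_age_power=1, max_year_power=1),
            beta={"intercept": -6.2, "age^1": 0.6, "year^1": 0.0},
            sigma2=0.02,
            seed=1000 + rep,
            years=tuple(range(2008, 2017)),
        )
        table, design, _ = cm.simulate_registrations(truth)
        cfg = cm.SamplerConfig(
            seed=50 + rep, n_chains=1, n_iterations=900, burn_in=300, thinning=1
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = cm.dic(cm.run_chain(table, design, cfg), table, design).marginal
            sub_idx = [design.columns.index(c) for c in ("intercept", "year^1")]
            sub = cm.DesignMatrix(
                X=design.X[:, sub_idx],
                columns=["intercept", "year^1"],
                scalers=design.scalers,
                contrasts=design.contrasts,
                spec=design.spec,
            )
            reduced = cm.dic(cm.run_chain(table, sub, cfg), table, sub).marginal
        wins += full < reduced
    assert wins == 5


# ---------------------------------------------------- forward selection

def test_forward_select_no_candidates_gives_intercept_only(small_table):
    design = cm.build_design(
        cm.ModelSpec(cancer_type="lung", max_age_power=1), small_table
    )
    cfg = cm.SamplerConfig(seed=2, n_chains=1, n_iterations=400, burn_in=100)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        trace = cm.forward_select({}, small_table, design, cfg)
    assert trace.selected == [] and trace.steps == []
    assert len(trace.dic_path) == 1


def test_bayes_factor_of_model_against_itself_is_one(small_table):
    design = cm.build_design(
        cm.ModelSpec(cancer_type="lung", max_age_power=1), small_table
    )
    lml1 = log_marginal_likelihood_laplace(small_table, design)
    lml2 = log_marginal_likelihood_laplace(small_table, design)
    assert np.exp(lml1 - lml2) == pytest.approx(1.0)


def test_selection_trace_validation_rejects_bad_acceptance():
    trace = cm.SelectionTrace(
        steps=[], selected=[], dic_path=[100.0]
    )
    trace.steps.append(
        cm.mcmc_inference.SelectionStep(term="x", dic=150.0, accepted=True)
    )
    with pytest.raises(AssertionError):
        trace.validate()


# ---------------------------------------------------------- persistence

def test_save_load_draws_round_trip(tmp_path, small_table):
    design = cm.build_design(cm.default_spec("lung"), small_table)
    cfg = cm.SamplerConfig(seed=5, n_chains=2, n_iterations=200, burn_in=100)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        d = cm.run_chain(small_table, design, cfg)
    p = tmp_path / "draws.csv"
    cm.save_draws(d, p)
    back = cm.load_draws(p)
    np.testing.assert_allclose(back.beta, d.beta, rtol=1e-9)
    np.testing.assert_allclose(back.sigma2, d.sigma2, rtol=1e-9)
    np.testing.assert_allclose(back.log_theta, d.log_theta, rtol=1e-9)
    assert back.columns == d.columns
    assert back.config.seed == 5
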