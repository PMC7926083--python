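"""RAM adaptation, hyperparameter updates and particle Gibbs samplers."""

import numpy as np
import pytest
from scipy.stats import kstest, norm

from diffcpf import (
    ParameterisedModel,
    RamState,
    Trajectory,
    condition_on_initial_state,
    dpg_bs,
    mcse_mean,
    ram_update,
    rts_smoother,
    theta_update,
)
from diffcpf.diagnostics import estimate_iact
from diffcpf.models import LgssParams, lgss_model, simulate_lgss


def test_ram_rank_one_update_arithmetic():
    ram = RamState.initial(1, 1.0)
    out = ram_update(ram, 1.0, np.array([1.0]), 0.1)
    # S^2 <- 1 * (1 + 0.1 * (1 - 0.441)) = 1.0559
    np.testing.assert_allclose(out.S, [[np.sqrt(1.0559)]], rtol=1e-10)
    same = ram_update(ram, 0.441, np.array([0.7]), 0.1)
    np.testing.assert_allclose(same.S, ram.S, rtol=1e-12)
    with pytest.raises(ValueError, match="noise"):
        ram_update(ram, 0.5, np.zeros(1), 0.1)
    with pytest.raises(ValueError, match="accepted_prob"):
        ram_update(ram, 1.5, np.array([1.0]), 0.1)


def test_ram_random_walk_metropolis_hits_target_acceptance(rng):
    """Adaptive RWM on a standard normal: the realised acceptance rate
    converges to the RAM target 0.441."""
    ram = RamState.initial(1, 1.0)
    x = 0.0
    accs = []
    for j in range(1, 50_001):
        u = rng.standard_normal(1)
        prop = x + (ram.S @ u)[0]
        alpha = min(1.0, np.exp(0.5 * x**2 - 0.5 * prop**2))
        if rng.random() < alpha:
            x = prop
        ram = ram_update(ram, alpha, u, (j + 1) ** (-2 / 3))
        accs.append(alpha)
    assert abs(np.mean(accs[10_000:]) - 0.441) < 0.05


def test_theta_update_with_flat_posterior_always_accepts(rng):
    pm = ParameterisedModel(
        build=lambda th: None, log_prior=lambda th: 0.0, theta_dim=2
    )
    pm.log_gamma = lambda theta, states: 0.0
    ram = RamState.initial(2, 0.5)
    x = Trajectory(np.zeros((1, 1)))
    theta = np.zeros(2)
    for _ in range(50):
        theta, acc, _, _ = theta_update(theta, x, pm, ram, rng)
        assert acc == 1.0


def test_theta_update_errors_on_zero_density_start(rng):
    pm = ParameterisedModel(
        build=lambda th: None, log_prior=lambda th: -np.inf, theta_dim=1
    )
    pm.log_gamma = lambda theta, states: 0.0
    with pytest.raises(ValueError, match="zero posterior"):
        theta_update(np.zeros(1), Trajectory(np.zeros((1, 1))), pm,
                     RamState.initial(1), rng)


def test_theta_chain_matches_conjugate_posterior(rng):
    """Normal prior x Normal likelihood with the path held fixed: the
    Metropolis theta-chain must reproduce the closed-form posterior."""
    data = np.array([1.2, 0.8, 1.5, 0.9, 1.1])
    prior_mu, prior_var, lik_var = 0.0, 4.0, 1.0
    post_var = 1.0 / (1.0 / prior_var + len(data) / lik_var)
    post_mu = post_var * (data.sum() / lik_var + prior_mu / prior_var)

    pm = ParameterisedModel(
        build=lambda th: None,
        log_prior=lambda th: float(norm.logpdf(th[0], prior_mu, np.sqrt(prior_var))),
        theta_dim=1,
    )
    pm.log_gamma = lambda theta, states: float(
        norm.logpdf(data, theta[0], np.sqrt(lik_var)).sum()
    )
    ram = RamState.initial(1, 0.5)
    x = Trajectory(np.zeros((1, 1)))
    theta = np.zeros(1)
    n = 40_000
    chain = np.empty(n)
    log_post = None
    for j in range(1, n + 1):
        theta, acc, u, log_post = theta_update(theta, x, pm, ram, rng, log_post)
        ram = ram_update(ram, acc, u, (j + 1) ** (-2 / 3))
        chain[j - 1] = theta[0]
    kept = chain[5000:]
    assert abs(kept.mean() - post_mu) < 3 * mcse_mean(kept)
    assert abs(kept.var() - post_var) < 0.1 * post_var


def test_condition_on_initial_state_shifts_model_correctly(lgss_setup, rng):
    model = lgss_setup["model"]
    x1 = np.array([0.4])
    reduced = condition_on_initial_state(model, x1)
    assert reduced.T == model.T - 1
    x = np.array([[0.9], [-0.2]])
    np.testing.assert_allclose(
        reduced.potential(0, None, x), model.potential(1, None, x)
    )
    np.testing.assert_allclose(
        reduced.transition_logdensity(1, x, x[:1]),
        model.transition_logdensity(2, x, x[:1]),
    )
    draws = reduced.m1_sample(2000, rng)[:, 0]
    # M~1 = M_2(x1, .) = N(rho * x1, sigma_x^2)
    assert abs(draws.mean() - 0.8 * 0.4) < 4 * 0.5 / np.sqrt(2000)
    with pytest.raises(ValueError, match="T >= 2"):
        condition_on_initial_state(
            lgss_model(np.zeros(1), LgssParams(0.8, 0.5, 0.5, 1, 10.0)), x1
        )


def test_dpg_with_single_step_is_adaptive_rwm_on_x1(rng):
    """T = 1 degenerates to random-walk Metropolis on x_1 whose target is
    the G_1-weighted initial law, here N(0,10^2) x N(y; x1, 0.5^2)."""
    params = LgssParams(rho=0.8, sigma_x=0.5, sigma_y=0.5, T=1, sigma_1=10.0)
    y = np.array([1.0])
    pm = ParameterisedModel(
        build=lambda th: lgss_model(y, params), log_prior=lambda th: 0.0, theta_dim=1
    )
    out = dpg_bs(pm, 20_000, 2000, 8, rng, np.zeros(1), Trajectory(np.array([[0.0]])))
    post_var = 1.0 / (1.0 / 10.0**2 + 1.0 / 0.5**2)
    post_mu = post_var * y[0] / 0.5**2
    kept = out.kept[:, 0, 0]
    _, p = kstest((kept[::10] - post_mu) / np.sqrt(post_var), "norm")
    assert p > 0.001


def test_dpg_long_run_matches_rts_smoother(rng):
    params = LgssParams(rho=0.8, sigma_x=0.5, sigma_y=0.5, T=10, sigma_1=10.0)
    x, y = simulate_lgss(params, 0.0, rng)
    pm = ParameterisedModel(
        build=lambda th: lgss_model(y, params), log_prior=lambda th: 0.0, theta_dim=1
    )
    out = dpg_bs(pm, 12_000, 2000, 16, rng, np.zeros(1), Trajectory(x[:, None]))
    means, variances = rts_smoother(y, params)
    for k in (0, 9):
        chain = out.kept[:, k, 0]
        assert abs(chain.mean() - means[k]) < 3 * mcse_mean(chain)
        assert abs(chain.var() - variances[k]) < 0.15 * variances[k]


def test_dpg_x1_mixing_is_insensitive_to_particle_count(rng):
    """The x_1 chain of the DPG baseline is limited by its Metropolis-
    within-Gibbs block, not by N: IACTs at N=32 and N=256 agree within a
    factor of two."""
    params = LgssParams(rho=0.8, sigma_x=0.5, sigma_y=0.5, T=25, sigma_1=50.0)
    x, y = simulate_lgss(params, 0.0, np.random.default_rng(21))
    pm = ParameterisedModel(
        build=lambda th: lgss_model(y, params), log_prior=lambda th: 0.0, theta_dim=1
    )
    iacts = []
    for N in (32, 256):
        out = dpg_bs(
            pm, 6000, 1000, N, np.random.default_rng(4), np.zeros(1),
            Trajectory(x[:, None]),
        )
        iacts.append(estimate_iact(out.kept[:, 0, 0]))
    ratio = iacts[1] / iacts[0]
    assert 0.5 < ratio < 2.0
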