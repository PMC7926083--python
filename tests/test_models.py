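"""Built-in models: simulators, densities, and the SEIR initial kernel."""

import numpy as np
import pytest
from scipy.stats import chisquare, norm

from diffcpf.models import (
    LgssParams,
    SeirInitialKernel,
    SeirParams,
    SvParams,
    lgss_model,
    mvn_static_model,
    negbin_logpmf,
    seir_domain,
    seir_model,
    simulate_lgss,
    simulate_seir,
    simulate_sv,
    sv_model,
)
from diffcpf.models.seir import SeirX1Map


class _StubRng:
    def __init__(self, value):
        self.value = value

    def standard_normal(self, shape=None):
        return np.full(shape, self.value) if shape is not None else self.value


# ---------------------------------------------------------------- noisy AR(1)


def test_lgss_noiseless_limit_is_geometric_decay(rng):
    params = LgssParams(rho=0.8, sigma_x=1e-12, sigma_y=1e-12, T=10, sigma_1=1.0)
    x, y = simulate_lgss(params, 2.0, rng)
    np.testing.assert_allclose(y, 2.0 * 0.8 ** np.arange(10), atol=1e-9)


def test_lgss_observation_variance_matches_stationary_formula(rng):
    rho, sx, sy = 0.8, 0.5, 0.5
    params = LgssParams(rho=rho, sigma_x=sx, sigma_y=sy, T=5000, sigma_1=1.0)
    _, y = simulate_lgss(params, 0.0, rng)
    target = sx**2 / (1 - rho**2) + sy**2
    # autocorrelation-inflated standard error of the sample variance
    se = target * np.sqrt(2.0 / 5000 * (1 + rho**2) / (1 - rho**2))
    assert abs(y[100:].var() - target) < 4 * se


def test_lgss_replay_is_bit_identical():
    params = LgssParams(rho=0.8, sigma_x=0.5, sigma_y=0.5, T=30, sigma_1=1.0)
    x1, y1 = simulate_lgss(params, 0.0, np.random.default_rng(5))
    x2, y2 = simulate_lgss(params, 0.0, np.random.default_rng(5))
    np.testing.assert_array_equal(x1, x2)
    np.testing.assert_array_equal(y1, y2)


def test_lgss_potential_at_observation_is_normal_mode_density():
    params = LgssParams(rho=0.8, sigma_x=0.5, sigma_y=0.5, T=3, sigma_1=10.0)
    y = np.array([0.3, -1.0, 2.0])
    model = lgss_model(y, params)
    logg = model.potential(1, None, np.array([[-1.0]]))
    np.testing.assert_allclose(logg, [-0.5 * np.log(2 * np.pi * 0.25)], rtol=1e-12)


def test_lgss_fully_diffuse_has_no_sampler_and_flat_logdensity():
    params = LgssParams(rho=1.0, sigma_x=0.5, sigma_y=0.5, T=3, fully_diffuse=True)
    model = lgss_model(np.zeros(3), params)
    assert model.m1_sample is None
    np.testing.assert_array_equal(model.m1_logdensity(np.array([[5.0], [-9.0]])), 0.0)


def test_lgss_observation_length_mismatch():
    params = LgssParams(rho=0.8, sigma_x=0.5, sigma_y=0.5, T=5, sigma_1=1.0)
    with pytest.raises(ValueError, match="observations"):
        lgss_model(np.zeros(4), params)
    with pytest.raises(ValueError, match="sigma_1"):
        LgssParams(rho=0.8, sigma_x=0.5, sigma_y=0.5, T=5)


# ---------------------------------------------------------- stochastic volatility


def test_sv_flat_volatility_gives_gaussian_returns(rng):
    params = SvParams(sigma_x=1e-12, sigma_y=1.5, T=4000, sigma_1=1.0)
    _, y = simulate_sv(params, 0.0, rng)
    assert abs(y.var() - 1.5**2) < 4 * 1.5**2 * np.sqrt(2.0 / 4000)
    assert abs(y.mean()) < 4 * 1.5 / np.sqrt(4000)


def test_sv_log_abs_returns_track_volatility(rng):
    params = SvParams(sigma_x=1.0, sigma_y=1.0, T=2000, sigma_1=1.0)
    x, y = simulate_sv(params, 0.0, rng)
    assert np.corrcoef(x, np.log(np.abs(y) + 1e-12))[0, 1] > 0.5


def test_sv_potential_is_finite_at_zero_observation():
    params = SvParams(sigma_x=1.0, sigma_y=2.0, T=1, sigma_1=1.0)
    model = sv_model(np.array([0.0]), params)
    logg = model.potential(0, None, np.array([[0.7]]))
    np.testing.assert_allclose(
        logg, norm.logpdf(0.0, 0.0, 2.0 * np.exp(0.7)), rtol=1e-12
    )


# ------------------------------------------------------------------ static MVN


def test_mvn_static_target_density_and_validation():
    model = mvn_static_model(2, 3.0)
    x = np.array([[0.5, -1.0]])
    np.testing.assert_allclose(
        model.potential(0, None, x),
        norm.logpdf(x, 0.0, 3.0).sum(axis=1),
        rtol=1e-12,
    )
    assert model.T == 1 and model.m1_sample is None
    with pytest.raises(ValueError):
        mvn_static_model(0, 1.0)
    with pytest.raises(ValueError):
        mvn_static_model(2, -1.0)


# ------------------------------------------------------------------------ SEIR


def test_seir_population_is_conserved_everywhere(seir_setup):
    path = seir_setup["path"]
    np.testing.assert_array_equal(
        path[:, :4].sum(axis=1), seir_setup["params"].n_pop
    )


def test_seir_incubation_probability_arithmetic():
    params = SeirParams(
        n_pop=100, r0_max=10.0, a=1 / 3, gamma=1 / 7, e=0.15, p=0.134, sigma=0.15, T=2
    )
    np.testing.assert_allclose(params.p_a, 0.2834687, atol=1e-6)
    np.testing.assert_allclose(params.p_gamma, 1 - np.exp(-1 / 7), rtol=1e-12)


def test_seir_extinct_epidemic_is_absorbing(rng):
    params = SeirParams(
        n_pop=1000, r0_max=10.0, a=1 / 3, gamma=1 / 7, e=0.15, p=0.134, sigma=0.15, T=30
    )
    path, counts = simulate_seir(params, np.array([1000, 0, 0, 0, 0.0]), rng)
    np.testing.assert_array_equal(path[:, 1:4], 0.0)
    np.testing.assert_array_equal(counts, 0)


def test_negbin_logpmf_closed_forms():
    # P(Y=0) = p^r
    r, p = 2.7, 0.134
    np.testing.assert_allclose(negbin_logpmf(0.0, r, p), r * np.log(p), rtol=1e-12)
    # r = 0: point mass at zero
    assert negbin_logpmf(0.0, 0.0, p) == 0.0
    assert negbin_logpmf(3.0, 0.0, p) == -np.inf
    # agreement with scipy's convention (mean r(1-p)/p)
    from scipy.stats import nbinom

    ys = np.arange(40.0)
    np.testing.assert_allclose(
        negbin_logpmf(ys, r, p), nbinom.logpmf(ys, r, p), rtol=1e-10
    )
    # pmf sums to ~1 over a truncated support
    big = np.arange(5000.0)
    assert abs(np.exp(negbin_logpmf(big, 10.0, 0.134)).sum() - 1.0) < 1e-10


def test_seir_observation_mean_matches_sampling_effort(rng):
    """E[Y_k | I_k] = e * p_gamma * I_k under the adopted convention."""
    params = SeirParams(
        n_pop=10**6, r0_max=10.0, a=1 / 3, gamma=1 / 7, e=0.15, p=0.134,
        sigma=1e-9, T=2,
    )
    hits = []
    for _ in range(400):
        _, counts = simulate_seir(
            params, np.array([10**6 - 20_000, 0, 20_000, 0, -20.0]), rng
        )
        hits.append(counts[0])
    mean_expected = 0.15 * params.p_gamma * 20_000
    se = np.sqrt(mean_expected / 0.134 / len(hits))
    assert abs(np.mean(hits) - mean_expected) < 4 * se


def test_seir_transition_density_rejects_impossible_moves(seir_setup):
    model = seir_model(seir_setup["counts"], seir_setup["params"])
    x_prev = np.array([[9000.0, 500.0, 400.0, 100.0, -1.0]])
    # Delta E = 9000 - 8000 = 1000 <= S ok, but Delta I = 500+1000-2000 < 0
    bad = np.array([[8000.0, 2000.0, 400.0, 100.0, -1.0]])
    assert model.transition_logdensity(None, x_prev, bad)[0] == -np.inf
    # Delta E exceeding S
    worse = np.array([[-100.0, 9600.0, 400.0, 100.0, -1.0]])
    assert model.transition_logdensity(None, x_prev, worse)[0] == -np.inf
    # non-integer increment
    frac = np.array([[8999.5, 500.5, 400.0, 100.0, -1.0]])
    assert model.transition_logdensity(None, x_prev, frac)[0] == -np.inf


def test_seir_jitted_density_matches_numpy_reference(seir_setup, rng):
    model = seir_model(seir_setup["counts"], seir_setup["params"])
    path = seir_setup["path"]
    a = model.transition_logdensity(None, path[:-1], path[1:])
    b = model.transition_logdensity_numpy(None, path[:-1], path[1:])
    np.testing.assert_allclose(a, b, rtol=1e-9)


def test_seir_initial_kernel_constraint_rejection_and_rounding():
    params = SeirParams(
        n_pop=100, r0_max=10.0, a=1 / 3, gamma=1 / 7, e=0.15, p=0.134, sigma=0.15, T=2
    )
    kernel = SeirInitialKernel(np.eye(3), params)
    x = np.array([90.0, 6.0, 4.0, 0.0, 0.5])
    # large negative noise drives E*, I* below zero -> proposal rejected
    out = kernel.sample(x, _StubRng(-30.0))
    np.testing.assert_array_equal(out, x)
    # tiny noise rounds back to the current lattice point
    out = kernel.sample(x, _StubRng(1e-8))
    np.testing.assert_array_equal(out[1:4], x[1:4])
    with pytest.raises(ValueError, match="constraints"):
        kernel.sample(np.array([90.0, 6.0, 4.0, 1.0, 0.5]), _StubRng(0.0))
    assert seir_domain(params)(x) and not seir_domain(params)(x + [0, 0, 0, 1, 0])


def test_seir_initial_kernel_is_uniform_on_small_simplex(rng):
    """On n_pop = 10 the (E, I) sub-chain of the constrained kernel has the
    uniform distribution over the 66 lattice points as its stationary law."""
    params = SeirParams(
        n_pop=10, r0_max=10.0, a=1 / 3, gamma=1 / 7, e=0.15, p=0.134, sigma=0.15, T=2
    )
    kernel = SeirInitialKernel(np.diag([1.0, 9.0, 9.0]), params)
    x = np.array([10.0, 0.0, 0.0, 0.0, 0.0])
    counts = {}
    n = 100_000
    thin = 20  # decorrelate: the chi-square below assumes i.i.d. draws
    for i in range(n):
        x = kernel.sample(x, rng)
        if i % thin:
            continue
        key = (int(x[1]), int(x[2]))
        counts[key] = counts.get(key, 0) + 1
    cells = [(e, i) for e in range(11) for i in range(11 - e)]
    assert set(counts) <= set(cells)
    observed = np.array([counts.get(c, 0) for c in cells], dtype=float)
    _, p = chisquare(observed)
    assert p > 0.001


def test_seir_x1_map_roundtrip_and_invalidity():
    params = SeirParams(
        n_pop=100, r0_max=10.0, a=1 / 3, gamma=1 / 7, e=0.15, p=0.134, sigma=0.15, T=2
    )
    m = SeirX1Map(params)
    x1 = np.array([90.0, 6.0, 4.0, 0.0, 0.5])
    np.testing.assert_array_equal(m.from_vec(m.to_vec(x1)), x1)
    assert m.from_vec(np.array([0.0, -3.0, 4.0])) is None
    assert m.from_vec(np.array([0.0, 60.0, 41.0])) is None


def test_simulate_seir_validates_initial_simplex(rng):
    params = SeirParams(
        n_pop=100, r0_max=10.0, a=1 / 3, gamma=1 / 7, e=0.15, p=0.134, sigma=0.15, T=5
    )
    with pytest.raises(ValueError, match="simplex|sum|integer"):
        simulate_seir(params, np.array([90, 6, 3, 0, 0.0]), rng)


def test_seir_numpy_step_fallback_conserves_population(rng):
    from diffcpf.models.seir import _step_numpy

    params = SeirParams(
        n_pop=5000, r0_max=10.0, a=1 / 3, gamma=1 / 7, e=0.15, p=0.134,
        sigma=0.15, T=2,
    )
    x = np.tile(np.array([4000.0, 600.0, 300.0, 100.0, -0.5]), (50, 1))
    out = _step_numpy(params, x, rng)
    np.testing.assert_array_equal(out[:, :4].sum(axis=1), 5000)
    assert np.all(out[:, :4] >= 0)
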