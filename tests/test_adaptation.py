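"""Stochastic-approximation adaptation rules and the AAI-CPF driver."""

import numpy as np
import pytest

from diffcpf import (
    AdaptConfig,
    AdaptationState,
    Trajectory,
    aai_cpf,
    ai_cpf_step,
    am_update,
    aswam_update,
    dgi_update,
    step_size,
)
from diffcpf.adaptation import make_kernel
from diffcpf.models import lgss_model


def test_step_size_values_and_decay():
    assert step_size(1, 1.0) == 0.5
    etas = np.array([step_size(j) for j in range(1, 500)])
    assert np.all(np.diff(etas) < 0)
    with pytest.raises(ValueError):
        step_size(0)
    with pytest.raises(ValueError, match="exponent"):
        step_size(3, 0.4)


def test_step_size_series_diverges_while_squares_converge():
    """Robbins–Monro: sum eta_j grows without bound (like n^(1/3) for
    exponent 2/3, so the partial sum doubles from n to 8n) while the
    partial sums of eta_j^2 settle."""
    js = np.arange(1, 800_001)
    etas = (js + 1.0) ** (-2.0 / 3.0)
    s1 = etas[: 10**5].sum()
    s8 = etas.sum()
    assert 1.85 < s8 / s1 < 2.05
    sq = etas**2
    assert sq[400_000:].sum() < 0.01 * sq.sum()


def test_am_constant_stream_follows_closed_form_recursion():
    """With eta_j = (j+1)^-1 the mean recursion telescopes to
    mu_n = v * n/(n+1); with a constant step it converges geometrically."""
    v = np.array([2.5])
    state = AdaptationState.initial(1, AdaptConfig(step_exponent=1.0))
    for j in range(1, 101):
        state = am_update(state, v, step_size(j, 1.0))
    np.testing.assert_allclose(state.mu, v * 100 / 101, rtol=1e-12)
    state = AdaptationState.initial(1)
    for _ in range(100):
        state = am_update(state, v, 0.2)
    assert abs(state.mu[0] - v[0]) < 1e-6  # (1 - 0.2)^100 * 2.5 ~ 5e-10


def test_am_recovers_moments_of_iid_stream(rng):
    m, s = np.array([1.0, -2.0]), np.array([[2.0, 0.3], [0.3, 0.5]])
    chol = np.linalg.cholesky(s)
    state = AdaptationState.initial(2)
    n = 10**5
    for j in range(1, n + 1):
        x = m + chol @ rng.standard_normal(2)
        state = am_update(state, x, step_size(j))
    np.testing.assert_allclose(state.mu, m, atol=0.1)
    np.testing.assert_allclose(state.sigma, s, atol=0.15)


def test_am_rejects_dimension_mismatch():
    state = AdaptationState.initial(2)
    with pytest.raises(ValueError, match="dimension"):
        am_update(state, np.zeros(3), 0.1)


def test_aswam_delta_fixed_point_and_increment():
    state = AdaptationState.initial(1, AdaptConfig(alpha_star=0.8))
    p1 = np.array([[0.0], [1.0]])
    # alpha = 1 - bw1[0] = alpha_star -> delta unchanged
    s2 = aswam_update(state, p1, np.array([0.2, 0.8]), 0.1)
    assert s2.delta == state.delta
    # alpha = 1, eta = 0.1 -> delta increases by 0.1 * (1 - 0.8) = 0.02
    s3 = aswam_update(state, p1, np.array([0.0, 1.0]), 0.1)
    np.testing.assert_allclose(s3.delta - state.delta, 0.02, rtol=1e-12)


def test_aswam_reference_always_kept_shrinks_scale_until_clamp():
    cfg = AdaptConfig(alpha_star=0.8, delta_clamp=1.0)
    state = AdaptationState.initial(1, cfg)
    p1 = np.array([[0.0], [5.0]])
    bw = np.array([1.0, 0.0])  # reference re-selected every sweep: alpha = 0
    deltas = []
    for j in range(1, 2001):
        state = aswam_update(state, p1, bw, step_size(j, 1.0))
        deltas.append(state.delta)
    assert all(np.diff(deltas) <= 0)
    assert state.delta == -1.0  # clamped


def test_aswam_requires_normalised_backward_weights():
    state = AdaptationState.initial(1)
    with pytest.raises(ValueError, match="normalised"):
        aswam_update(state, np.zeros((2, 1)), np.array([0.7, 0.7]), 0.1)


def test_dgi_logit_arithmetic_and_clamp():
    state = AdaptationState.initial(1, AdaptConfig(alpha_star=0.5))
    s2 = dgi_update(state, 0.5, 0.2)
    assert s2.zeta_logit == state.zeta_logit
    s3 = dgi_update(state, 1.0, 0.2)
    np.testing.assert_allclose(s3.zeta_logit, 0.1, rtol=1e-12)
    np.testing.assert_allclose(s3.beta, 0.52498, atol=5e-6)
    # repeated alpha = 0 drives beta toward (but never to) zero
    state = AdaptationState.initial(1, AdaptConfig(alpha_star=0.8))
    for j in range(1, 5001):
        state = dgi_update(state, 0.0, 1.0)
    assert state.zeta_logit == -20.0
    assert 0.0 < state.beta < 1e-8


def test_adaptation_monotonicity_in_alpha():
    """Persistent alpha above (below) the target grows (shrinks) the
    adapted scale, for both the ASWAM log-scale and the DGI logit-beta."""
    cfg = AdaptConfig(alpha_star=0.5)
    up, down = AdaptationState.initial(1, cfg), AdaptationState.initial(1, cfg)
    p1, bw_hi, bw_lo = np.array([[0.0], [1.0]]), np.array([0.1, 0.9]), np.array([0.9, 0.1])
    for j in range(1, 51):
        up = aswam_update(up, p1, bw_hi, step_size(j))
        down = aswam_update(down, p1, bw_lo, step_size(j))
    assert up.delta > 0 > down.delta
    up, down = AdaptationState.initial(1, cfg), AdaptationState.initial(1, cfg)
    for j in range(1, 51):
        up = dgi_update(up, 0.9, step_size(j))
        down = dgi_update(down, 0.1, step_size(j))
    assert up.beta > 0.5 > down.beta


def test_eigen_floor_is_enforced():
    cfg = AdaptConfig(eigen_floor=0.5)
    state = AdaptationState.initial(2, cfg)
    for j in range(1, 301):
        state = am_update(state, np.zeros(2), step_size(j, 1.0))
        assert np.linalg.eigvalsh(state.sigma)[0] >= 0.5 - 1e-12


def test_incompatible_rule_kernel_pairs_are_rejected(lgss_setup):
    model, ref = lgss_setup["model"], lgss_setup["reference"]
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError, match="incompatible"):
        aai_cpf(model, "ar", "am", 10, 2, 4, rng, ref)
    with pytest.raises(ValueError, match="backward sampling"):
        aai_cpf(model, "rw", "aswam", 10, 2, 4, rng, ref, pickpath="at")
    with pytest.raises(ValueError, match="exceed"):
        aai_cpf(model, "ar", "dgi", 10, 10, 4, rng, ref)


def test_disabled_adaptation_reduces_to_iterated_ai_step(lgss_setup):
    """With the rule set to None the driver is exactly the fixed-kernel
    AI-CPF chain: bitwise-identical trajectories from the same stream."""
    model, ref = lgss_setup["model"], lgss_setup["reference"]
    state = AdaptationState.initial(1)
    out = aai_cpf(
        model, "ar", None, 20, 5, 8, np.random.default_rng(3), ref,
        initial_state=state,
    )
    rng = np.random.default_rng(3)
    r = ref
    for j in range(20):
        kernel = make_kernel(state, "ar", model=model)
        step = ai_cpf_step(model, kernel, r, 8, rng)
        r = step.trajectory
        np.testing.assert_array_equal(out.trajectories[j], r.states)
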