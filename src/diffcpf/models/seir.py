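"""Stochastic discrete-time SEIR compartment model with random-walk R0.

The population of fixed size ``n_pop`` is split into susceptible (S),
exposed (E), infected (I) and removed (R) compartments.  The basic
reproduction number is time-varying through a latent Gaussian random walk
``rho_k`` on the logit scale, ``R0_k = r0_max * logit^{-1}(rho_k)``.  One
day of the epidemic moves binomial increments between compartments:

    dE ~ Binomial(S_k, 1 - exp(-beta_k I_k / n_pop)),
    dI ~ Binomial(E_k, 1 - exp(-a)),
    dR ~ Binomial(I_k, 1 - exp(-gamma)),
    drho ~ N(0, sigma^2),

with infection rate ``beta_k = r0_max * logit^{-1}(rho_k) * p_gamma``;
``1/a`` and ``1/gamma`` are the mean incubation and recovery times.  Daily
case counts are negative-binomial in the number of infected,

    Y_k ~ NegBin(r_k, p),   r_k = e * p_gamma * p / (1 - p) * I_k,

parameterised so that ``E[Y_k] = e * p_gamma * I_k`` (``e`` = sampling
effort, the average observed fraction of removals) and
``Var[Y_k] = E[Y_k] / p``; ``NegBin(r, p)`` has pmf
``C(y + r - 1, y) p^r (1 - p)^y``, so ``Pr(Y = 0) = p^r``.  The degenerate
case ``I_k = 0`` (r = 0) is a point mass at zero counts.

At the start of an epidemic the initial compartment sizes are effectively
unknown, so the initial measure is the improper uniform indicator

    M1 = 1(S_1 + E_1 + I_1 = n_pop) 1(S_1, E_1, I_1 >= 0) 1(R_1 = 0),

which makes the fully diffuse initialisation the natural sampler.  The
state vector is ``(S, E, I, R, rho)``, d = 5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit, gammaln, xlog1py, xlogy

from ..fk import FeynmanKacModel, Trajectory

try:  # optional JIT acceleration of the per-particle inner loops
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is normally present
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]

__all__ = [
    "SeirParams",
    "simulate_seir",
    "seir_model",
    "SeirInitialKernel",
    "seir_domain",
    "seir_initial_reference",
    "negbin_logpmf",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class SeirParams:
    n_pop: int
    r0_max: float
    a: float
    gamma: float
    e: float
    p: float
    sigma: float
    T: int

    def __post_init__(self):
        if self.n_pop < 1:
            raise ValueError("n_pop must be a positive integer")
        if not (0.0 < self.e <= 1.0):
            raise ValueError("sampling effort e must be in (0, 1]")
        if not (0.0 < self.p < 1.0):
            raise ValueError("negative-binomial failure probability p must be in (0, 1)")
        if self.sigma <= 0 or self.a <= 0 or self.gamma <= 0 or self.r0_max <= 0:
            raise ValueError("sigma, a, gamma and r0_max must be positive")
        if self.T < 1:
            raise ValueError("T must be >= 1")

    @property
    def p_a(self) -> float:
        return float(1.0 - np.exp(-self.a))

    @property
    def p_gamma(self) -> float:
        return float(1.0 - np.exp(-self.gamma))


def _binom_logpmf(k: np.ndarray, n: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Vectorised Binomial(n, p) log-pmf with exact handling of p in {0, 1}.

    ``xlogy``/``xlog1py`` give the correct 0·log 0 = 0 limits, so the
    degenerate success probabilities need no special-casing; out-of-support
    or non-integer arguments map to -inf.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = (
            gammaln(n + 1.0)
            - gammaln(k + 1.0)
            - gammaln(n - k + 1.0)
            + xlogy(k, p)
            + xlog1py(n - k, -p)
        )
    invalid = (k < 0) | (k > n) | (k != np.floor(k)) | (n != np.floor(n))
    return np.where(invalid | np.isnan(res), -np.inf, res)


def negbin_logpmf(y: np.ndarray, r: np.ndarray, p: float) -> np.ndarray:
    """Log-pmf of NegBin(r, p) with pmf ``C(y+r-1, y) p^r (1-p)^y``.

    ``r`` may be non-integer; ``r = 0`` is treated as a point mass at 0.
    """
    y = np.asarray(y, dtype=float)
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = (
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1.0)
            + r * np.log(p)
            + xlog1py(y, -p)
        )
    invalid = (y < 0) | (y != np.floor(y))
    res = np.where(invalid | np.isnan(res), -np.inf, res)
    if np.any(r == 0.0):
        res = np.where((r == 0.0) & (y == 0.0), 0.0, res)
    return res


def _step_numpy(params: SeirParams, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Advance a batch of states (n, 5) by one day (vectorised numpy)."""
    S, E, I, R, rho = (x[:, j] for j in range(5))
    beta = params.r0_max * expit(rho) * params.p_gamma
    p_beta = -np.expm1(-beta * I / params.n_pop)
    dE = rng.binomial(S.astype(np.int64), p_beta)
    dI = rng.binomial(E.astype(np.int64), params.p_a)
    dR = rng.binomial(I.astype(np.int64), params.p_gamma)
    out = np.empty_like(x)
    out[:, 0] = S - dE
    out[:, 1] = E + dE - dI
    out[:, 2] = I + dI - dR
    out[:, 3] = R + dR
    out[:, 4] = rho + params.sigma * rng.standard_normal(x.shape[0])
    return out


@_njit
def _step_jit(x, n_pop, r0max, p_a, p_g, sigma, rng):  # pragma: no cover - jit
    n = x.shape[0]
    out = np.empty_like(x)
    for i in range(n):
        S = x[i, 0]; E = x[i, 1]; I = x[i, 2]; R = x[i, 3]; rho = x[i, 4]
        beta = r0max / (1.0 + math.exp(-rho)) * p_g
        p_beta = -math.expm1(-beta * I / n_pop)
        dE = rng.binomial(np.int64(S), p_beta)
        dI = rng.binomial(np.int64(E), p_a)
        dR = rng.binomial(np.int64(I), p_g)
        out[i, 0] = S - dE
        out[i, 1] = E + dE - dI
        out[i, 2] = I + dI - dR
        out[i, 3] = R + dR
        out[i, 4] = rho + sigma * rng.standard_normal()
    return out


@_njit
def _trans_jit(xp, xn, n_pop, r0max, p_a, p_g, sigma,
               log_pa, log_qa, log_pg, log_qg, log_norm_rho):  # pragma: no cover
    n = xp.shape[0]
    out = np.empty(n)
    for i in range(n):
        S = xp[i, 0]; E = xp[i, 1]; I = xp[i, 2]
        dE = S - xn[i, 0]
        dI = E + dE - xn[i, 1]
        dR = xn[i, 3] - xp[i, 3]
        if (dE < 0 or dE > S or dI < 0 or dI > E or dR < 0 or dR > I
                or dE != math.floor(dE) or dI != math.floor(dI)
                or dR != math.floor(dR)):
            out[i] = -np.inf
            continue
        beta = r0max / (1.0 + math.exp(-xp[i, 4])) * p_g
        p_beta = -math.expm1(-beta * I / n_pop)
        if p_beta <= 0.0:
            t1 = 0.0 if dE == 0.0 else -np.inf
        else:
            t1 = (math.lgamma(S + 1) - math.lgamma(dE + 1) - math.lgamma(S - dE + 1)
                  + dE * math.log(p_beta) + (S - dE) * math.log1p(-p_beta))
        t2 = (math.lgamma(E + 1) - math.lgamma(dI + 1) - math.lgamma(E - dI + 1)
              + dI * log_pa + (E - dI) * log_qa)
        t3 = (math.lgamma(I + 1) - math.lgamma(dR + 1) - math.lgamma(I - dR + 1)
              + dR * log_pg + (I - dR) * log_qg)
        z = (xn[i, 4] - xp[i, 4]) / sigma
        out[i] = t1 + t2 + t3 + log_norm_rho - 0.5 * z * z
    return out


def _step(params: SeirParams, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Advance a batch of states (n, 5) by one day."""
    if _HAVE_NUMBA:
        return _step_jit(
            np.ascontiguousarray(x), float(params.n_pop), params.r0_max,
            params.p_a, params.p_gamma, params.sigma, rng,
        )
    return _step_numpy(params, x, rng)


def simulate_seir(
    params: SeirParams,
    initial_state: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the epidemic and the observed daily counts.

    ``initial_state = (S1, E1, I1, R1, rho1)`` must lie on the population
    simplex with non-negative integer compartments.  Returns the state path
    ``(T, 5)`` and counts ``(T,)``.
    """
    x0 = np.asarray(initial_state, dtype=float).reshape(-1)
    if x0.size != 5:
        raise ValueError("initial_state must have 5 components (S, E, I, R, rho)")
    comps = x0[:4]
    if comps.sum() != params.n_pop or np.any(comps < 0) or np.any(comps != np.floor(comps)):
        raise ValueError("initial compartments must be non-negative integers summing to n_pop")
    T = params.T
    path = np.empty((T, 5))
    path[0] = x0
    for k in range(1, T):
        path[k] = _step(params, path[k - 1 : k], rng)[0]
    r = params.e * params.p_gamma * params.p / (1.0 - params.p) * path[:, 2]
    counts = np.where(
        r > 0, rng.negative_binomial(np.maximum(r, 1e-300), params.p), 0
    ).astype(np.int64)
    return path, counts


def seir_domain(params: SeirParams):
    """Indicator of the diffuse initial support (population simplex, R1 = 0)."""

    def domain(x: np.ndarray) -> bool:
        S, E, I, R = x[0], x[1], x[2], x[3]
        return (
            S >= 0
            and E >= 0
            and I >= 0
            and R == 0
            and S + E + I == params.n_pop
            and S == np.floor(S)
            and E == np.floor(E)
            and I == np.floor(I)
        )

    return domain


def seir_model(counts: np.ndarray, params: SeirParams) -> FeynmanKacModel:
    """Bootstrap Feynman–Kac form of the SEIR model.

    Transitions simulate one epidemic day; the transition log-density is
    the product of the three binomial increment pmfs and the Gaussian
    random-walk density of ``rho`` (available, so backward sampling is
    usable); potentials are the negative-binomial count pmfs.
    """
    y = np.asarray(counts, dtype=np.int64).reshape(-1)
    if y.size != params.T:
        raise ValueError(f"expected {params.T} observation counts, got {y.size}")
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    p = params.p
    r_coef = params.e * params.p_gamma * p / (1.0 - p)
    log_norm_rho = -0.5 * _LOG_2PI - np.log(params.sigma)

    def potential(k, x_prev, x):
        return negbin_logpmf(y[k], r_coef * x[:, 2], p)

    def transition_sample(k, x_prev, rng):
        return _step(params, x_prev, rng)

    p_a, p_gamma = params.p_a, params.p_gamma
    log_pa, log_qa = np.log(p_a), np.log1p(-p_a)
    log_pg, log_qg = np.log(p_gamma), np.log1p(-p_gamma)

    def _transition_logdensity_numpy(k, x_prev, x):
        # fused product of the three binomial increment pmfs and the
        # Gaussian rho step; single validity mask (hot path)
        x_prev = np.atleast_2d(x_prev)
        x = np.atleast_2d(x)
        S, E, I = x_prev[:, 0], x_prev[:, 1], x_prev[:, 2]
        dE = S - x[:, 0]
        dI = E + dE - x[:, 1]
        dR = x[:, 3] - x_prev[:, 3]
        beta = params.r0_max * expit(x_prev[:, 4]) * p_gamma
        p_beta = -np.expm1(-beta * I / params.n_pop)
        with np.errstate(divide="ignore", invalid="ignore"):
            logp = (
                gammaln(S + 1.0) - gammaln(dE + 1.0) - gammaln(S - dE + 1.0)
                + xlogy(dE, p_beta) + xlog1py(S - dE, -p_beta)
                + gammaln(E + 1.0) - gammaln(dI + 1.0) - gammaln(E - dI + 1.0)
                + dI * log_pa + (E - dI) * log_qa
                + gammaln(I + 1.0) - gammaln(dR + 1.0) - gammaln(I - dR + 1.0)
                + dR * log_pg + (I - dR) * log_qg
                + log_norm_rho
                - 0.5 * ((x[:, 4] - x_prev[:, 4]) / params.sigma) ** 2
            )
        invalid = (
            (dE < 0) | (dE > S) | (dI < 0) | (dI > E) | (dR < 0) | (dR > I)
            | (dE != np.floor(dE)) | (dI != np.floor(dI)) | (dR != np.floor(dR))
        )
        return np.where(invalid | np.isnan(logp), -np.inf, logp)

    if _HAVE_NUMBA:
        _jit_args = (
            float(params.n_pop), params.r0_max, p_a, p_gamma, params.sigma,
            float(log_pa), float(log_qa), float(log_pg), float(log_qg),
            float(log_norm_rho),
        )

        def transition_logdensity(k, x_prev, x):
            x_prev = np.atleast_2d(x_prev)
            x = np.atleast_2d(x)
            if x.shape[0] != x_prev.shape[0]:
                x_prev, x = np.broadcast_arrays(x_prev, x)
            return _trans_jit(
                np.ascontiguousarray(x_prev), np.ascontiguousarray(x), *_jit_args
            )
    else:
        transition_logdensity = _transition_logdensity_numpy

    def m1_logdensity(x):
        x = np.atleast_2d(x)
        ok = (
            (x[:, 0] >= 0)
            & (x[:, 1] >= 0)
            & (x[:, 2] >= 0)
            & (x[:, 3] == 0)
            & (x[:, 0] + x[:, 1] + x[:, 2] == params.n_pop)
        )
        return np.where(ok, 0.0, -np.inf)

    def path_logdensity(states):
        states = np.atleast_2d(states)
        lp = float(m1_logdensity(states[:1])[0])
        if not np.isfinite(lp):
            return -np.inf
        lp += float(np.sum(negbin_logpmf(y, r_coef * states[:, 2], p)))
        if states.shape[0] > 1:
            lp += float(np.sum(transition_logdensity(None, states[:-1], states[1:])))
        return lp

    model = FeynmanKacModel(
        potential_depends_on_x_prev=False,
        T=params.T,
        state_dim=5,
        potential=potential,
        transition_sample=transition_sample,
        transition_logdensity=transition_logdensity,
        m1_sample=None,
        m1_logdensity=m1_logdensity,
        path_logdensity=path_logdensity,
    )
    # pure-numpy reference implementation, kept for cross-validation of the
    # jitted density in the test-suite
    model.transition_logdensity_numpy = _transition_logdensity_numpy
    return model


class SeirInitialKernel:
    """Constrained random walk on the SEIR initial state.

    Proposals act on the three free coordinates ``(rho_1, E_1, I_1)``;
    ``E_1`` and ``I_1`` are rounded to the nearest integer, ``R_1`` is set
    to 0 and ``S_1 = n_pop - E_1 - I_1``.  A proposal violating the
    simplex constraints is rejected (the current state is returned), the
    Metropolis acceptance against the indicator M1.  Rounding makes the
    kernel a random walk on the integer lattice; on the diffuse scales of
    interest the induced asymmetry is negligible.
    """

    kind = "rw_constrained"

    def __init__(self, cov: np.ndarray, params: SeirParams):
        cov = np.atleast_2d(np.asarray(cov, dtype=float))
        if cov.shape != (3, 3):
            raise ValueError("cov must be 3x3, acting on (rho, E, I)")
        self._chol = np.linalg.cholesky(cov)
        self.cov = cov
        self.params = params
        self.dim = 5

    def _check(self, x: np.ndarray) -> None:
        if not seir_domain(self.params)(np.asarray(x, dtype=float).reshape(-1)):
            raise ValueError("current state violates the SEIR initial constraints")

    def sample(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return self.sample_n(x, 1, rng)[0]

    def sample_n(self, x: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
        x = np.asarray(x, dtype=float).reshape(-1)
        self._check(x)
        u = np.array([x[4], x[1], x[2]])  # (rho, E, I)
        prop = u[None, :] + rng.standard_normal((n, 3)) @ self._chol.T
        rho_new = prop[:, 0]
        e_new = np.round(prop[:, 1])
        i_new = np.round(prop[:, 2])
        s_new = self.params.n_pop - e_new - i_new
        ok = (e_new >= 0) & (i_new >= 0) & (s_new >= 0)
        out = np.empty((n, 5))
        out[:, 0] = np.where(ok, s_new, x[0])
        out[:, 1] = np.where(ok, e_new, x[1])
        out[:, 2] = np.where(ok, i_new, x[2])
        out[:, 3] = 0.0
        out[:, 4] = np.where(ok, rho_new, x[4])
        return out


def seir_kernel_factory(params: SeirParams, jitter: float = 1e-6):
    """Adapter from a 5-d adaptation state to the 3-d initial kernel.

    The ASWAM adaptation tracks the mean and covariance of the full time-1
    state ``(S, E, I, R, rho)``; the initial kernel proposes on
    ``(rho_1, E_1, I_1)`` only, so the factory extracts that block, applies
    the adapted log-scale and regularises with a small diagonal jitter so
    the proposal stays non-degenerate while the covariance is still being
    learned.  Usable as ``kernel_factory`` for both the adaptive FDI-CPF
    (one argument) and particle Gibbs (state, theta).
    """
    idx = np.array([4, 1, 2])

    def factory(state, theta=None):
        cov = np.exp(state.delta) * state.sigma[np.ix_(idx, idx)]
        cov = cov + jitter * np.eye(3)
        return SeirInitialKernel(cov, params)

    return factory


class SeirX1Map:
    """Translate the SEIR initial state to/from the DPG proposal vector.

    The proposal space is ``(rho_1, E_1, I_1)``; reconstruction rounds the
    compartments to integers, sets ``R_1 = 0``, ``S_1 = n_pop - E_1 - I_1``
    and reports an off-simplex proposal as invalid (None), which the
    Metropolis-within-Gibbs step counts as a rejection.
    """

    dim = 3

    def __init__(self, params: SeirParams, initial_scale=(0.5, 20.0, 20.0)):
        self.params = params
        self.initial_scale = np.asarray(initial_scale, dtype=float)

    def to_vec(self, x1: np.ndarray) -> np.ndarray:
        x1 = np.asarray(x1, dtype=float).reshape(-1)
        return np.array([x1[4], x1[1], x1[2]])

    def from_vec(self, u: np.ndarray) -> Optional[np.ndarray]:
        rho = float(u[0])
        e1 = float(np.round(u[1]))
        i1 = float(np.round(u[2]))
        s1 = self.params.n_pop - e1 - i1
        if e1 < 0 or i1 < 0 or s1 < 0:
            return None
        return np.array([s1, e1, i1, 0.0, rho])


def seir_initial_reference(
    counts: np.ndarray,
    params: SeirParams,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> Trajectory:
    """Draw a feasible starting trajectory for the fully diffuse chain.

    The initial measure is improper, so the first reference cannot be
    sampled from it; instead the initial infected/exposed counts are drawn
    uniformly from a box whose scale is set by inverting the observation
    mean relation ``E[Y] ≈ e * p_gamma * I`` on the early counts, and the
    path is propagated through the model transitions.  Retries until every
    potential along the path is positive.
    """
    y = np.asarray(counts, dtype=np.int64).reshape(-1)
    model = seir_model(y, params)
    scale = max(10, int(np.ceil(y[: min(5, y.size)].max() / (params.e * params.p_gamma))))
    cap = min(4 * scale, params.n_pop // 2)
    for _ in range(max_tries):
        i1 = int(rng.integers(0, cap + 1))
        e1 = int(rng.integers(0, cap + 1))
        rho1 = rng.normal(0.0, 1.0)
        x1 = np.array([params.n_pop - e1 - i1, e1, i1, 0.0, rho1])
        if x1[0] < 0:
            continue
        states = np.empty((params.T, 5))
        states[0] = x1
        ok = np.isfinite(model.potential(0, None, states[:1])[0])
        for k in range(1, params.T):
            if not ok:
                break
            states[k] = model.transition_sample(k, states[k - 1 : k], rng)[0]
            ok = np.isfinite(model.potential(k, states[k - 1 : k], states[k : k + 1])[0])
        if ok:
            return Trajectory(states)
    raise RuntimeError(
        "could not find a feasible initial SEIR trajectory; the counts may "
        "be inconsistent with the model parameters"
    )
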