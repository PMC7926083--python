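"""Particle Gibbs with adaptive auxiliary initialisation, and baselines.

Joint inference of hyperparameters ``theta`` and the latent path proceeds
by Gibbs alternation: a Metropolis-within-Gibbs update of ``theta`` given
the path (shaped by the robust adaptive Metropolis, RAM, rank-one
covariance recursion), then one (adaptive) auxiliary-initialisation CPF
step for the path given ``theta``.  The initial measure M1 is assumed
diffuse and independent of ``theta``.

``theta`` lives on an unconstrained sampling scale chosen by the model
builder (log for positive parameters, logit for probabilities); priors are
densities on that same scale, so the Metropolis ratio needs no Jacobian
corrections.

The DPG-BS baseline instead treats the first latent state as a parameter:
``x_1`` (optionally jointly with ``theta``) is updated by a RAM-adapted
random-walk Metropolis-within-Gibbs step targeting its full conditional,
and ``x_{2:T}`` by a standard CPF-BS conditional on ``x_1``.  It needs no
diffuse-initialisation machinery, which is precisely why it mixes poorly
when the first smoothing marginal is far from the early observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

from .adaptation import (
    AdaptConfig,
    AdaptationState,
    am_update,
    aswam_update,
    dgi_update,
    make_kernel,
    step_size,
)
from .fk import FeynmanKacModel, Trajectory, cpf_bs_kernel
from .kernels import ai_cpf_step

__all__ = [
    "ParameterisedModel",
    "RamState",
    "ram_update",
    "theta_update",
    "condition_on_initial_state",
    "aai_pg",
    "dpg_bs",
    "PGOutput",
]


@dataclass
class ParameterisedModel:
    """A family of Feynman–Kac models indexed by hyperparameters.

    ``build(theta)`` returns the model at ``theta`` (M1 must not depend on
    ``theta``); ``log_prior`` is the prior density on the sampling scale.
    ``log_gamma(theta, states)`` evaluates the joint density
    ``log p(y_{1:T}, x_{1:T} | theta)`` (including the M1 indicator); the
    default walks the model's potentials and transition densities, or uses
    the model's vectorised ``path_logdensity`` when available.
    """

    build: Callable[[np.ndarray], FeynmanKacModel]
    log_prior: Callable[[np.ndarray], float]
    theta_dim: int
    theta_names: Optional[tuple] = None

    def log_gamma(self, theta: np.ndarray, states: np.ndarray) -> float:
        model = self.build(theta)
        states = np.atleast_2d(states)
        if model.path_logdensity is not None:
            return float(model.path_logdensity(states))
        lp = 0.0
        if model.m1_logdensity is not None:
            lp += float(model.m1_logdensity(states[:1])[0])
        if not np.isfinite(lp):
            return -np.inf
        lp += float(model.potential(0, None, states[:1])[0])
        for k in range(1, model.T):
            if not np.isfinite(lp):
                return -np.inf
            lp += float(
                model.transition_logdensity(k, states[k - 1 : k], states[k : k + 1])[0]
            )
            lp += float(model.potential(k, states[k - 1 : k], states[k : k + 1])[0])
        return lp


@dataclass
class RamState:
    """Robust adaptive Metropolis proposal shape.

    ``S`` is the lower-triangular scale factor of the Gaussian proposal
    ``theta' = theta + S u``, ``u ~ N(0, I)``; the rank-one recursion
    steers the realised acceptance probability towards ``alpha_star``
    (0.441, the classical univariate random-walk optimum, by default).
    """

    S: np.ndarray
    alpha_star: float = 0.441
    j: int = 0

    def __post_init__(self):
        self.S = np.atleast_2d(np.asarray(self.S, dtype=float))
        if np.any(np.diag(self.S) <= 0):
            raise ValueError("S must have a positive diagonal")

    @classmethod
    def initial(cls, dim: int, scale=0.1, alpha_star: float = 0.441) -> "RamState":
        """Diagonal starting shape; ``scale`` may be a scalar or per-coordinate."""
        scale = np.broadcast_to(np.asarray(scale, dtype=float), (dim,))
        return cls(S=np.diag(scale), alpha_star=alpha_star)


def ram_update(
    state: RamState,
    accepted_prob: float,
    proposal_noise: np.ndarray,
    eta: float,
) -> RamState:
    """Rank-one RAM update ``S S^T <- S (I + eta (a - a*) uu^T/|u|^2) S^T``."""
    if not (0.0 <= accepted_prob <= 1.0):
        raise ValueError("accepted_prob must be in [0, 1]")
    u = np.asarray(proposal_noise, dtype=float).reshape(-1)
    norm2 = float(u @ u)
    if norm2 <= 0.0:
        raise ValueError("degenerate proposal noise vector")
    p = u.shape[0]
    factor = np.eye(p) + eta * (accepted_prob - state.alpha_star) * np.outer(u, u) / norm2
    new_sq = state.S @ factor @ state.S.T
    S = np.linalg.cholesky(0.5 * (new_sq + new_sq.T))
    return replace(state, S=S, j=state.j + 1)


def theta_update(
    theta: np.ndarray,
    x: Trajectory,
    pm: ParameterisedModel,
    ram: RamState,
    rng: np.random.Generator,
    log_post_cur: Optional[float] = None,
) -> tuple[np.ndarray, float, np.ndarray, float]:
    """Metropolis update of ``theta`` given the path, RAM-shaped proposal.

    Returns ``(theta_new, accept_prob, proposal_noise, log_post_new)``
    where ``log_post`` is ``log_prior + log_gamma`` at the returned theta,
    reusable by the caller to avoid recomputation.
    """
    theta = np.asarray(theta, dtype=float).reshape(-1)
    states = x.states
    if log_post_cur is None:
        log_post_cur = pm.log_prior(theta) + pm.log_gamma(theta, states)
    if not np.isfinite(log_post_cur):
        raise ValueError("current theta has zero posterior density")
    u = rng.standard_normal(theta.shape[0])
    prop = theta + ram.S @ u
    log_post_prop = pm.log_prior(prop) + pm.log_gamma(prop, states)
    log_ratio = log_post_prop - log_post_cur
    accept_prob = float(min(1.0, np.exp(min(log_ratio, 0.0))))
    if rng.random() < accept_prob:
        return prop, accept_prob, u, float(log_post_prop)
    return theta, accept_prob, u, float(log_post_cur)


def condition_on_initial_state(model: FeynmanKacModel, x1: np.ndarray) -> FeynmanKacModel:
    """Reduced (T-1)-step model for ``x_{2:T}`` given a fixed ``x_1``.

    The transition out of ``x_1`` becomes the (proper) initial sampler and
    the first potential becomes ``G_2(x_1, ·)``; later steps shift by one.
    """
    if model.T < 2:
        raise ValueError("conditioning requires T >= 2")
    x1 = np.asarray(x1, dtype=float).reshape(-1)

    def m1_sample(n, rng):
        return model.transition_sample(1, np.tile(x1, (n, 1)), rng)

    def potential(k, x_prev, x):
        if k == 0:
            x_prev = np.tile(x1, (x.shape[0], 1))
        return model.potential(k + 1, x_prev, x)

    def transition_sample(k, x_prev, rng):
        return model.transition_sample(k + 1, x_prev, rng)

    transition_logdensity = None
    if model.transition_logdensity is not None:

        def transition_logdensity(k, x_prev, x):
            return model.transition_logdensity(k + 1, x_prev, x)

    return FeynmanKacModel(
        T=model.T - 1,
        state_dim=model.state_dim,
        potential=potential,
        transition_sample=transition_sample,
        transition_logdensity=transition_logdensity,
        m1_sample=m1_sample,
        potential_depends_on_x_prev=model.potential_depends_on_x_prev,
    )


@dataclass
class PGOutput:
    """Joint chain of hyperparameters and trajectories."""

    thetas: np.ndarray  # (n_iter, p)
    trajectories: np.ndarray  # (n_iter, T, d)
    alphas_theta: np.ndarray
    alphas_state: np.ndarray
    burn_in: int
    theta_names: Optional[tuple] = None
    final_ram: Optional[RamState] = None
    final_adapt: Optional[AdaptationState] = None

    @property
    def kept_thetas(self) -> np.ndarray:
        return self.thetas[self.burn_in :]

    @property
    def kept(self) -> np.ndarray:
        return self.trajectories[self.burn_in :]

    def coordinate_chain(self, k: int, dim: int = 0) -> np.ndarray:
        return self.kept[:, k, dim]


def aai_pg(
    pm: ParameterisedModel,
    kernel_family: str,
    adapt_rule: Optional[str],
    n_iter: int,
    burn_in: int,
    N: int,
    rng: np.random.Generator,
    theta0: np.ndarray,
    initial_reference: Trajectory,
    config: Optional[AdaptConfig] = None,
    domain_factory: Optional[Callable[[np.ndarray], Callable]] = None,
    kernel_factory=None,
    theta_alpha_star: float = 0.441,
    ram_scale0: float = 0.1,
    update_theta: bool = True,
    pickpath: str = "bs",
) -> PGOutput:
    """Adaptive particle Gibbs with the AAI-CPF as the state update.

    Each sweep first updates ``theta`` by a RAM-adapted Metropolis step
    leaving the conditional posterior invariant, then runs one
    auxiliary-initialisation CPF step on the model built at the new
    ``theta`` and adapts the initialisation kernel.  With both adaptations
    frozen, a sweep is a valid Markov kernel for the joint posterior;
    diminishing step sizes keep post-burn-in averages consistent.

    ``domain_factory(theta)`` supplies the constraint indicator for
    constrained random-walk kernels; ``kernel_factory(adapt_state, theta)``
    overrides kernel construction entirely (used for lattice-valued
    initial states such as the SEIR model).
    """
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    theta = np.asarray(theta0, dtype=float).reshape(-1).copy()
    if theta.shape[0] != pm.theta_dim:
        raise ValueError("theta0 dimension mismatch")
    reference = initial_reference
    model = pm.build(theta)
    T, d = model.T, model.state_dim
    ram = RamState.initial(pm.theta_dim, ram_scale0, theta_alpha_star)
    adapt_state = AdaptationState.initial(d, config=config)

    thetas = np.empty((n_iter, pm.theta_dim))
    trajectories = np.empty((n_iter, T, d))
    alphas_theta = np.full(n_iter, np.nan)
    alphas_state = np.full(n_iter, np.nan)
    log_post = None

    for j in range(1, n_iter + 1):
        if update_theta:
            theta_new, acc, u, log_post = theta_update(
                theta, reference, pm, ram, rng, log_post
            )
            ram = ram_update(ram, acc, u, step_size(j))
            alphas_theta[j - 1] = acc
            if not np.array_equal(theta_new, theta):
                theta = theta_new
                model = pm.build(theta)
        thetas[j - 1] = theta

        if kernel_factory is not None:
            kernel = kernel_factory(adapt_state, theta)
        else:
            domain = domain_factory(theta) if domain_factory is not None else None
            family = kernel_family
            if adapt_rule == "aswam" and not family.endswith("_aswam"):
                family = family + "_aswam"
            kernel = make_kernel(adapt_state, family, model=model, domain=domain)
        step = ai_cpf_step(model, kernel, reference, N, rng, pickpath)
        if not np.array_equal(step.trajectory.states, reference.states):
            log_post = None  # path changed; cached conditional is stale
        reference = step.trajectory
        trajectories[j - 1] = reference.states
        alpha = 1.0 - float(step.bw1[0]) if step.bw1 is not None else np.nan
        alphas_state[j - 1] = alpha
        if adapt_rule is not None:
            eta = step_size(j, adapt_state.config.step_exponent)
            if adapt_rule == "am":
                adapt_state = am_update(adapt_state, reference.states[0], eta)
            elif adapt_rule == "aswam":
                adapt_state = aswam_update(adapt_state, step.particles1, step.bw1, eta)
            elif adapt_rule == "dgi":
                adapt_state = dgi_update(adapt_state, alpha, eta)
            else:
                raise ValueError(f"unknown adaptation rule {adapt_rule!r}")

    return PGOutput(
        thetas,
        trajectories,
        alphas_theta,
        alphas_state,
        burn_in,
        pm.theta_names,
        ram,
        adapt_state,
    )


class IdentityX1Map:
    """Continuous initial states: the parameter vector is x_1 itself."""

    def __init__(self, dim: int, initial_scale=1.0):
        self.dim = dim
        self.initial_scale = initial_scale

    def to_vec(self, x1: np.ndarray) -> np.ndarray:
        return np.asarray(x1, dtype=float).reshape(-1).copy()

    def from_vec(self, u: np.ndarray) -> Optional[np.ndarray]:
        return np.asarray(u, dtype=float).reshape(-1).copy()


def dpg_bs(
    pm: ParameterisedModel,
    n_iter: int,
    burn_in: int,
    N: int,
    rng: np.random.Generator,
    theta0: np.ndarray,
    initial_reference: Trajectory,
    update_theta: bool = False,
    x1_map=None,
    theta_alpha_star: float = 0.441,
    ram_scale0: float = 0.1,
) -> PGOutput:
    """Diffuse particle Gibbs baseline (DPG-BS).

    The first latent state (with ``theta`` when ``update_theta``) is a
    Metropolis-within-Gibbs block with a RAM-adapted random-walk proposal
    targeting its full conditional — the product of all joint-density
    terms that involve the block — and ``x_{2:T}`` is refreshed by a
    standard CPF with backward sampling conditional on ``x_1``.  One inner
    Metropolis step is taken per sweep.  With ``T = 1`` the sweep is pure
    adaptive random-walk Metropolis on ``x_1``.

    ``x1_map`` translates between ``x_1`` and the unconstrained proposal
    vector (identity by default; the SEIR model proposes on
    ``(rho_1, E_1, I_1)`` with rounding and returns None off the simplex,
    which counts as a rejection).
    """
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    theta = np.asarray(theta0, dtype=float).reshape(-1).copy()
    model = pm.build(theta)
    T, d = model.T, model.state_dim
    if x1_map is None:
        x1_map = IdentityX1Map(d)
    reference = initial_reference
    states = reference.states.copy()

    p_theta = pm.theta_dim if update_theta else 0
    block_dim = p_theta + x1_map.dim
    # per-coordinate starting scales: theta block, then x1 block (lattice
    # coordinates need steps at least of order 1 to escape rounding)
    x1_scale = np.broadcast_to(
        np.asarray(getattr(x1_map, "initial_scale", 1.0), dtype=float), (x1_map.dim,)
    )
    scale0 = np.concatenate([np.full(p_theta, ram_scale0), x1_scale])
    ram = RamState.initial(block_dim, scale0, theta_alpha_star)

    thetas = np.empty((n_iter, pm.theta_dim))
    trajectories = np.empty((n_iter, T, d))
    alphas_theta = np.full(n_iter, np.nan)
    log_post = pm.log_prior(theta) + pm.log_gamma(theta, states)
    if not np.isfinite(log_post):
        raise ValueError("initial (theta, trajectory) has zero posterior density")

    for j in range(1, n_iter + 1):
        # --- block update of (theta,) x_1 by random-walk Metropolis
        u = rng.standard_normal(block_dim)
        step_vec = ram.S @ u
        theta_prop = theta + step_vec[:p_theta] if update_theta else theta
        x1_prop = x1_map.from_vec(x1_map.to_vec(states[0]) + step_vec[p_theta:])
        if x1_prop is None:
            acc = 0.0
        else:
            states_prop = states.copy()
            states_prop[0] = x1_prop
            lp_prop = pm.log_prior(theta_prop) + pm.log_gamma(theta_prop, states_prop)
            acc = float(min(1.0, np.exp(min(lp_prop - log_post, 0.0))))
            if rng.random() < acc:
                theta, states, log_post = theta_prop, states_prop, lp_prop
                if update_theta:
                    model = pm.build(theta)
        ram = ram_update(ram, acc, u, step_size(j))
        alphas_theta[j - 1] = acc

        # --- CPF-BS refresh of x_{2:T} conditional on x_1
        if T > 1:
            reduced = condition_on_initial_state(model, states[0])
            ref_tail = Trajectory(states[1:])
            tail, _ = cpf_bs_kernel(reduced, ref_tail, N, rng, pickpath="bs")
            states = np.vstack([states[:1], tail.states])
            log_post = pm.log_prior(theta) + pm.log_gamma(theta, states)

        thetas[j - 1] = theta
        trajectories[j - 1] = states

    return PGOutput(
        thetas, trajectories, alphas_theta, np.full(n_iter, np.nan), burn_in,
        pm.theta_names, ram, None,
    )
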