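"""Online adaptation of the initialisation kernels (AAI-CPF).

Tuning the random-walk covariance C of the FDI-CPF or the autoregressive
parameter beta of the DGI-CPF by hand is tedious; the schemes here learn
them on the fly by stochastic approximation with step sizes decaying to
zero (diminishing adaptation), so post-burn-in ergodic averages remain
consistent for the smoothing target.

Three rules are provided:

* AM — adaptive-Metropolis covariance learning from the chain's own time-1
  states; kernel covariance ``C = c * Sigma_j`` with the classical scaling
  ``c = 2.38^2 / d`` as default.
* ASWAM — Rao–Blackwellised adaptive scaling within AM: mean and covariance
  are learned from *all* time-1 particles weighted by their backward-sampling
  weights, and a log-scale ``delta`` is steered so that the realised
  "acceptance rate" — the probability ``alpha = 1 - v^(1)`` that the
  reference's time-1 coordinate is *not* re-selected — matches a target
  ``alpha_star``; ``C = exp(delta) * Sigma_j``.
* DGI — the same acceptance-rate steering applied to ``logit(beta)`` of the
  autoregressive kernel.

A target acceptance rate around 0.8 (the default) tends to give good
mixing for moderate particle numbers; values in 0.7–0.9 are all
reasonable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

from .fk import FeynmanKacModel, Trajectory
from .kernels import ARKernel, ConstrainedRWKernel, RWKernel, ai_cpf_step

__all__ = [
    "AdaptConfig",
    "AdaptationState",
    "ChainOutput",
    "step_size",
    "am_update",
    "aswam_update",
    "dgi_update",
    "make_kernel",
    "aai_cpf",
]


@dataclass(frozen=True)
class AdaptConfig:
    """Tuning constants shared by the adaptation rules.

    ``alpha_star`` is the target acceptance rate; ``c`` the AM covariance
    scaling (default 2.38^2/d, resolved at driver level); ``eigen_floor``
    a lower bound enforced on the eigenvalues of the learned covariance
    (the stabiliser required by the consistency theory — 0 disables it);
    ``step_exponent`` the decay rate of the stochastic-approximation step
    sizes; ``delta_clamp``/``logit_clamp`` box constraints on the log-scale
    and logit-beta parameters.
    """

    alpha_star: float = 0.8
    c: Optional[float] = None
    eigen_floor: float = 0.0
    step_exponent: float = 2.0 / 3.0
    delta_clamp: float = float(np.e)
    logit_clamp: float = 20.0

    def __post_init__(self):
        if not (0.0 < self.alpha_star < 1.0):
            raise ValueError("alpha_star must be in (0, 1)")
        if not (0.5 < self.step_exponent <= 1.0):
            raise ValueError("step_exponent must be in (0.5, 1]")


@dataclass
class AdaptationState:
    """Running kernel-parameter estimates ``zeta_j``.

    ``mu``/``sigma`` are the learned location and covariance of the time-1
    smoothing marginal, ``delta`` the ASWAM log-scale, ``zeta_logit`` the
    logit of the DGI autoregressive parameter, and ``j`` the iteration
    counter.
    """

    mu: np.ndarray
    sigma: np.ndarray
    delta: float = 0.0
    zeta_logit: float = 0.0
    j: int = 0
    config: AdaptConfig = field(default_factory=AdaptConfig)

    @classmethod
    def initial(
        cls,
        dim: int,
        config: Optional[AdaptConfig] = None,
        mu0: Optional[np.ndarray] = None,
        sigma0: Optional[np.ndarray] = None,
        beta0: float = 0.5,
    ) -> "AdaptationState":
        """Neutral starting point: zero mean, identity covariance, beta 1/2."""
        mu = np.zeros(dim) if mu0 is None else np.asarray(mu0, dtype=float).copy()
        sigma = np.eye(dim) if sigma0 is None else np.asarray(sigma0, dtype=float).copy()
        return cls(
            mu=mu,
            sigma=sigma,
            delta=0.0,
            zeta_logit=float(np.log(beta0 / (1.0 - beta0))),
            j=0,
            config=config or AdaptConfig(),
        )

    @property
    def beta(self) -> float:
        return float(1.0 / (1.0 + np.exp(-self.zeta_logit)))


def step_size(j: int, exponent: float = 2.0 / 3.0) -> float:
    """Stochastic-approximation step ``eta_j = (j + 1)^(-exponent)``.

    With exponent in (0.5, 1] the sequence satisfies the Robbins–Monro
    conditions (sum diverges, sum of squares converges).
    """
    if j < 1:
        raise ValueError("j must be >= 1")
    if not (0.5 < exponent <= 1.0):
        raise ValueError("exponent must be in (0.5, 1]")
    return float((j + 1) ** (-exponent))


def _floor_eigenvalues(sigma: np.ndarray, eps: float) -> np.ndarray:
    """Project a symmetric matrix so its smallest eigenvalue is >= eps."""
    if eps <= 0.0:
        return sigma
    sigma = 0.5 * (sigma + sigma.T)
    vals, vecs = np.linalg.eigh(sigma)
    if vals[0] >= eps:
        return sigma
    return (vecs * np.maximum(vals, eps)) @ vecs.T


def am_update(state: AdaptationState, x1: np.ndarray, eta: float) -> AdaptationState:
    """Adaptive-Metropolis mean/covariance recursion on one chain sample.

    ``mu <- mu + eta (x1 - mu)``;
    ``sigma <- sigma + eta ((x1 - mu_old)(x1 - mu_old)^T - sigma)``.
    """
    x1 = np.asarray(x1, dtype=float).reshape(-1)
    if x1.shape[0] != state.mu.shape[0]:
        raise ValueError("dimension mismatch in am_update")
    diff = x1 - state.mu
    mu = state.mu + eta * diff
    sigma = state.sigma + eta * (np.outer(diff, diff) - state.sigma)
    sigma = _floor_eigenvalues(sigma, state.config.eigen_floor)
    return replace(state, mu=mu, sigma=sigma, j=state.j + 1)


def aswam_update(
    state: AdaptationState,
    particles1: np.ndarray,
    bw1: np.ndarray,
    eta: float,
) -> AdaptationState:
    """Rao–Blackwellised adaptive-scaling-within-AM update.

    Uses all time-1 particles with their backward weights for the mean and
    covariance recursions, and moves the log-scale ``delta`` by
    ``eta (alpha - alpha_star)`` with ``alpha = 1 - bw1[0]`` (slot 0 holds
    the reference's time-1 coordinate).
    """
    particles1 = np.atleast_2d(np.asarray(particles1, dtype=float))
    bw1 = np.asarray(bw1, dtype=float)
    if abs(bw1.sum() - 1.0) > 1e-8 or np.any(bw1 < 0):
        raise ValueError("bw1 must be a normalised weight vector")
    m_hat = bw1 @ particles1
    diff = particles1 - state.mu
    s_hat = (bw1[:, None] * diff).T @ diff
    mu = state.mu + eta * (m_hat - state.mu)
    sigma = state.sigma + eta * (s_hat - state.sigma)
    sigma = _floor_eigenvalues(sigma, state.config.eigen_floor)
    alpha = 1.0 - float(bw1[0])
    clamp = state.config.delta_clamp
    delta = float(np.clip(state.delta + eta * (alpha - state.config.alpha_star), -clamp, clamp))
    return replace(state, mu=mu, sigma=sigma, delta=delta, j=state.j + 1)


def dgi_update(state: AdaptationState, alpha_observed: float, eta: float) -> AdaptationState:
    """Acceptance-rate steering of logit(beta) for the autoregressive kernel."""
    if not (0.0 <= alpha_observed <= 1.0):
        raise ValueError("alpha_observed must be in [0, 1]")
    clamp = state.config.logit_clamp
    zeta = float(
        np.clip(
            state.zeta_logit + eta * (alpha_observed - state.config.alpha_star),
            -clamp,
            clamp,
        )
    )
    return replace(state, zeta_logit=zeta, j=state.j + 1)


@dataclass
class ChainOutput:
    """Trace of an (adaptive) AI-CPF run.

    ``trajectories`` holds every selected path ``(n_iter, T, d)`` including
    burn-in; ``alphas`` the per-iteration Rao–Blackwellised acceptance rate
    (NaN under ancestor tracing); ``x0s`` the auxiliary pseudo-states;
    ``scale_trace`` the adapted scalar parameter (beta for DGI, exp(delta)
    for ASWAM, the leading covariance entry for AM); ``burn_in`` the number
    of initial iterations to discard.
    """

    trajectories: np.ndarray
    alphas: np.ndarray
    x0s: np.ndarray
    scale_trace: np.ndarray
    burn_in: int
    final_state: Optional[AdaptationState] = None

    @property
    def kept(self) -> np.ndarray:
        """Post-burn-in trajectories, shape (n_iter - burn_in, T, d)."""
        return self.trajectories[self.burn_in :]

    def coordinate_chain(self, k: int, dim: int = 0, include_burn_in: bool = False) -> np.ndarray:
        """The sampled chain of one state coordinate (zero-based time k)."""
        src = self.trajectories if include_burn_in else self.kept
        return src[:, k, dim]


def make_kernel(
    state: AdaptationState,
    kind: str,
    model: Optional[FeynmanKacModel] = None,
    domain: Optional[Callable[[np.ndarray], bool]] = None,
):
    """Build the kernel corresponding to the current adaptation state.

    ``kind``: "rw" (AM: C = c Sigma), "rw_aswam" (C = exp(delta) Sigma),
    "rw_constrained"/"rw_constrained_aswam" (as above with a domain
    indicator), or "ar" (beta from zeta_logit; mean/covariance taken from
    the model's Gaussian-M1 metadata).
    """
    d = state.mu.shape[0]
    if kind in ("rw", "rw_constrained"):
        c = state.config.c if state.config.c is not None else 2.38**2 / d
        cov = c * state.sigma
    elif kind in ("rw_aswam", "rw_constrained_aswam"):
        cov = np.exp(state.delta) * state.sigma
    elif kind == "ar":
        if model is None or model.m1_mean is None or model.m1_cov is None:
            raise ValueError("AR kernel needs Gaussian M1 metadata (m1_mean, m1_cov)")
        return ARKernel(state.beta, model.m1_mean, model.m1_cov)
    else:
        raise ValueError(f"unknown kernel kind {kind!r}")
    if kind.startswith("rw_constrained"):
        if domain is None:
            raise ValueError("constrained kernel requires a domain indicator")
        return ConstrainedRWKernel(cov, domain)
    return RWKernel(cov)


_COMPAT = {
    "am": ("rw", "rw_constrained"),
    "aswam": ("rw_aswam", "rw_constrained_aswam"),
    "dgi": ("ar",),
    None: ("rw", "rw_aswam", "rw_constrained", "rw_constrained_aswam", "ar"),
}


def aai_cpf(
    model: FeynmanKacModel,
    kernel_family: str,
    adapt_rule: Optional[str],
    n_iter: int,
    burn_in: int,
    N: int,
    rng: np.random.Generator,
    initial_reference: Trajectory,
    config: Optional[AdaptConfig] = None,
    initial_state: Optional[AdaptationState] = None,
    domain: Optional[Callable[[np.ndarray], bool]] = None,
    kernel_factory=None,
    pickpath: str = "bs",
) -> ChainOutput:
    """Run the adaptive auxiliary-initialisation CPF.

    Iterates :func:`ai_cpf_step` with the kernel rebuilt from the current
    :class:`AdaptationState` each sweep, then applies the chosen adaptation
    rule (``"am"``, ``"aswam"``, ``"dgi"`` or ``None`` for a fixed
    kernel).  ``kernel_family`` is one of ``"rw"``, ``"rw_constrained"``,
    ``"ar"``; a custom ``kernel_factory(state)`` overrides it.  AM works
    with either path-selection rule; ASWAM and DGI need the backward
    weights, hence ``pickpath="bs"``.
    """
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    if adapt_rule in ("aswam", "dgi") and pickpath != "bs":
        raise ValueError(f"{adapt_rule} adaptation requires backward sampling")
    family = kernel_family
    if adapt_rule == "aswam" and not family.endswith("_aswam"):
        family = family + "_aswam"
    if adapt_rule in _COMPAT and kernel_factory is None:
        if family not in _COMPAT[adapt_rule]:
            raise ValueError(
                f"kernel family {kernel_family!r} is incompatible with "
                f"adaptation rule {adapt_rule!r}"
            )
    state = initial_state if initial_state is not None else AdaptationState.initial(
        model.state_dim, config=config
    )

    T, d = model.T, model.state_dim
    trajectories = np.empty((n_iter, T, d))
    alphas = np.full(n_iter, np.nan)
    x0s = np.empty((n_iter, d))
    scale_trace = np.empty(n_iter)
    reference = initial_reference

    for j in range(1, n_iter + 1):
        kernel = (
            kernel_factory(state) if kernel_factory is not None
            else make_kernel(state, family, model=model, domain=domain)
        )
        step = ai_cpf_step(model, kernel, reference, N, rng, pickpath)
        reference = step.trajectory
        trajectories[j - 1] = reference.states
        x0s[j - 1] = step.x0
        alpha = 1.0 - float(step.bw1[0]) if step.bw1 is not None else np.nan
        alphas[j - 1] = alpha
        if adapt_rule is not None:
            eta = step_size(j, state.config.step_exponent)
            if adapt_rule == "am":
                state = am_update(state, reference.states[0], eta)
            elif adapt_rule == "aswam":
                state = aswam_update(state, step.particles1, step.bw1, eta)
            elif adapt_rule == "dgi":
                state = dgi_update(state, alpha, eta)
            else:
                raise ValueError(f"unknown adaptation rule {adapt_rule!r}")
        if adapt_rule == "dgi":
            scale_trace[j - 1] = state.beta
        elif adapt_rule == "aswam":
            scale_trace[j - 1] = np.exp(state.delta)
        else:
            scale_trace[j - 1] = state.sigma[0, 0]

    return ChainOutput(trajectories, alphas, x0s, scale_trace, burn_in, state)
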