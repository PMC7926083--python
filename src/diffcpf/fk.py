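"""Feynman–Kac models and the conditional particle filter (CPF).

A Feynman–Kac model represents a path distribution

    pi(dx_{1:T}) ∝ M1(dx_1) G_1(x_1) prod_{k=2}^T M_k(x_{k-1}, dx_k) G_k(x_{k-1}, x_k)

through an initial measure ``M1`` (possibly improper, e.g. uniform on R^d),
Markov transition kernels ``M_k`` and non-negative potential functions
``G_k``.  For a state-space model in bootstrap form, ``M1`` and ``M_k`` are
the latent-state prior and transitions and ``G_k(x) = p(y_k | x_k)`` is the
observation likelihood.

The conditional particle filter runs a particle filter that is conditioned
on retaining one "reference" trajectory; selecting a new trajectory from the
resulting particle system (by ancestor tracing or backward sampling) defines
a Markov kernel on paths that leaves ``pi`` invariant.

Conventions
-----------
Times are 1..T and particle slots 1..N in the documentation; arrays are
zero-based, so "slot 1" is row 0.  The reference trajectory always occupies
slot 0.  All weight arithmetic is done in log space with log-sum-exp
normalisation, and every stochastic operation takes an explicit
:class:`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "FeynmanKacModel",
    "ParticleHistory",
    "Trajectory",
    "DegenerateWeightsError",
    "multinomial_resample",
    "conditional_multinomial_resample",
    "forward_cpf",
    "pickpath_at",
    "pickpath_bs",
    "cpf_bs_kernel",
]


class DegenerateWeightsError(ValueError):
    """All particle weights vanished — the model cannot explain the data.

    Carries the (zero-based) time index at which the particle system
    degenerated, when known.
    """

    def __init__(self, message: str, time_index: Optional[int] = None):
        super().__init__(message)
        self.time_index = time_index


@dataclass
class FeynmanKacModel:
    """Bundle of the ingredients M1, M_k, G_k defining a smoothing target.

    Parameters
    ----------
    T:
        Number of time steps (≥ 1).
    state_dim:
        Dimension ``d`` of the state space.
    potential:
        ``potential(k, x_prev, x) -> (n,) log-potentials``, the log of
        ``G_{k+1}`` evaluated at ``n`` particles.  ``k`` is the zero-based
        time index of ``x``; ``x_prev`` is ``None`` for ``k = 0``.  Must
        return finite values or ``-inf`` (zero potential), vectorised over
        rows of the ``(n, d)`` inputs.
    transition_sample:
        ``transition_sample(k, x_prev, rng) -> (n, d)`` draws from
        ``M_{k+1}(x_prev, ·)`` for ``k = 1..T-1`` (zero-based destination
        index), vectorised over rows.
    transition_logdensity:
        ``transition_logdensity(k, x_prev, x) -> (n,)`` pointwise log
        transition density; required by backward sampling only.  ``x`` may
        be a single state of shape ``(d,)`` broadcast against ``(n, d)``
        ``x_prev``.
    m1_sample:
        ``m1_sample(n, rng) -> (n, d)`` sampler from M1; absent when M1 is
        improper.
    m1_logdensity:
        Pointwise ``log M1(x)`` up to a constant (``(n, d) -> (n,)``);
        needed by the fully-diffuse potential rewrite and by constrained
        kernels.  For an improper uniform M1 this is identically 0 on the
        support.
    m1_mean, m1_cov:
        Optional Gaussian-M1 metadata (mean vector and covariance) used by
        the autoregressive initialisation kernel.
    """

    T: int
    state_dim: int
    potential: Callable[[int, Optional[np.ndarray], np.ndarray], np.ndarray]
    transition_sample: Optional[
        Callable[[int, np.ndarray, np.random.Generator], np.ndarray]
    ] = None
    transition_logdensity: Optional[
        Callable[[int, np.ndarray, np.ndarray], np.ndarray]
    ] = None
    m1_sample: Optional[Callable[[int, np.random.Generator], np.ndarray]] = None
    m1_logdensity: Optional[Callable[[np.ndarray], np.ndarray]] = None
    m1_mean: Optional[np.ndarray] = None
    m1_cov: Optional[np.ndarray] = None
    #: optional fast evaluation of log[M1 G_1 prod M_k G_k] along one (T, d)
    #: path; when absent, callers fall back to a per-step loop.
    path_logdensity: Optional[Callable[[np.ndarray], float]] = None
    #: False for bootstrap-form models whose G_k depends on x_k only; lets
    #: backward sampling drop the potential factor (constant in the
    #: candidate, so it cancels in the normalised backward weights).
    potential_depends_on_x_prev: bool = True

    def __post_init__(self):
        if self.T < 1:
            raise ValueError(f"T must be >= 1, got {self.T}")
        if self.state_dim < 1:
            raise ValueError(f"state_dim must be >= 1, got {self.state_dim}")
        if self.T > 1 and self.transition_sample is None:
            raise ValueError("transition_sample is required when T > 1")


@dataclass
class Trajectory:
    """A single latent path ``x_{1:T}`` with an optional pseudo-state x0."""

    states: np.ndarray  # (T, d)
    x0: Optional[np.ndarray] = None  # (d,)

    def __post_init__(self):
        self.states = np.atleast_2d(np.asarray(self.states, dtype=float))
        if not np.all(np.isfinite(self.states)):
            raise ValueError("trajectory contains non-finite states")


@dataclass
class ParticleHistory:
    """Output of one forward CPF pass.

    ``particles`` has shape ``(T, N, d)``, ``ancestors`` shape ``(T-1, N)``
    (``ancestors[k]`` are the time-``k`` parents of the time-``k+1``
    particles) and ``weights`` shape ``(T, N)`` with each row normalised to
    sum to one.  The reference lineage is pinned to slot 0:
    ``ancestors[k, 0] == 0`` for every ``k``.
    """

    particles: np.ndarray
    ancestors: np.ndarray
    weights: np.ndarray
    log_weights: np.ndarray = field(repr=False, default=None)

    @property
    def T(self) -> int:
        return self.particles.shape[0]

    @property
    def N(self) -> int:
        return self.particles.shape[1]

    def validate(self, atol: float = 1e-12) -> None:
        """Check the structural invariants (normalisation, pinned lineage)."""
        if np.any(self.weights < 0):
            raise ValueError("negative weights")
        if not np.allclose(self.weights.sum(axis=1), 1.0, atol=atol):
            raise ValueError("weights do not sum to 1")
        if self.T > 1 and np.any(self.ancestors[:, 0] != 0):
            raise ValueError("reference lineage not pinned to slot 0")


def _categorical(weights: np.ndarray, count: int, rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF categorical draws: one uniform per draw."""
    cdf = np.cumsum(weights)
    cdf /= cdf[-1]
    u = rng.random(count)
    return np.minimum(np.searchsorted(cdf, u, side="right"), len(weights) - 1)


def _check_weights(weights: np.ndarray) -> np.ndarray:
    weights = np.asarray(weights, dtype=float)
    if weights.ndim != 1:
        raise ValueError("weights must be a vector")
    if np.any(weights < 0) or np.any(~np.isfinite(weights)):
        raise DegenerateWeightsError("weights must be finite and non-negative")
    if weights.sum() <= 0:
        raise DegenerateWeightsError("all weights are zero: degenerate particle system")
    return weights


def multinomial_resample(
    weights: np.ndarray, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``count`` ancestor indices i.i.d. Categorical(weights).

    ``Pr(A = i) = weights[i]`` for each returned entry independently.
    """
    weights = _check_weights(weights)
    return _categorical(weights, count, rng)


def conditional_multinomial_resample(
    weights: np.ndarray, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Multinomial resampling conditioned on retaining the reference.

    The first returned index is always 0 (the reference slot); the
    remaining ``count - 1`` are i.i.d. Categorical(weights).
    """
    weights = _check_weights(weights)
    out = np.empty(count, dtype=np.intp)
    out[0] = 0
    if count > 1:
        out[1:] = _categorical(weights, count - 1, rng)
    return out


def _normalise_log_weights(logw: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    # max-shifted exponentiation; hot path, so no scipy indirection here
    logw = np.asarray(logw, dtype=float)
    m = logw.max()
    if not np.isfinite(m):
        if m == -np.inf:
            raise DegenerateWeightsError(
                f"all potentials are zero at time index {k} (model/data mismatch)",
                time_index=k,
            )
        raise ValueError(f"potential returned +inf or NaN at time index {k}")
    w = np.exp(logw - m)
    s = w.sum()
    w = w / s
    logw_norm = logw - (m + np.log(s))
    return logw_norm, w


def forward_cpf(
    model: FeynmanKacModel,
    initial_particles: np.ndarray,
    reference: Trajectory,
    rng: np.random.Generator,
) -> ParticleHistory:
    """Run the forward pass of the conditional particle filter.

    The time-1 particles are given (with ``initial_particles[0]`` equal to
    the reference's first state); for subsequent times the ancestors are
    drawn by conditional multinomial resampling on the previous weights,
    slot 0 is set to the reference state, and the other slots are
    propagated through ``transition_sample``.  Weights at each time are
    proportional to the potentials, normalised in log space.
    """
    initial_particles = np.atleast_2d(np.asarray(initial_particles, dtype=float))
    N, d = initial_particles.shape
    if N < 2:
        raise ValueError("forward_cpf requires N >= 2 particles")
    if d != model.state_dim:
        raise ValueError("initial particle dimension does not match state_dim")
    if not np.array_equal(initial_particles[0], reference.states[0]):
        raise ValueError("initial_particles[0] must equal the reference's first state")

    T = model.T
    particles = np.empty((T, N, d))
    ancestors = np.empty((max(T - 1, 0), N), dtype=np.intp)
    weights = np.empty((T, N))
    log_weights = np.empty((T, N))

    particles[0] = initial_particles
    logw, w = _normalise_log_weights(model.potential(0, None, initial_particles), 0)
    log_weights[0], weights[0] = logw, w

    for k in range(1, T):
        anc = conditional_multinomial_resample(weights[k - 1], N, rng)
        ancestors[k - 1] = anc
        parents = particles[k - 1][anc]
        xk = np.empty((N, d))
        xk[0] = reference.states[k]
        xk[1:] = model.transition_sample(k, parents[1:], rng)
        particles[k] = xk
        logw, w = _normalise_log_weights(model.potential(k, parents, xk), k)
        log_weights[k], weights[k] = logw, w

    return ParticleHistory(particles, ancestors, weights, log_weights)


def pickpath_at(history: ParticleHistory, rng: np.random.Generator) -> Trajectory:
    """Select a path by ancestor tracing.

    Draws the terminal index from the final weights and follows the stored
    ancestor links backwards.
    """
    T, N = history.T, history.N
    b = int(_categorical(_check_weights(history.weights[T - 1]), 1, rng)[0])
    states = np.empty((T, history.particles.shape[2]))
    states[T - 1] = history.particles[T - 1, b]
    for k in range(T - 2, -1, -1):
        b = int(history.ancestors[k, b])
        states[k] = history.particles[k, b]
    return Trajectory(states)


def pickpath_bs(
    model: FeynmanKacModel,
    history: ParticleHistory,
    rng: np.random.Generator,
) -> tuple[Trajectory, np.ndarray]:
    """Select a path by backward sampling.

    Draws the terminal index from the final weights, then redraws each
    earlier index from backward weights

        v_k^(i) ∝ W_k^(i) · M_{k+1}(x_k^(i), x_{k+1}^(B)) · G_{k+1}(x_k^(i), x_{k+1}^(B)),

    computed in log space.  Valid when the potentials depend on at most two
    consecutive states.  Returns the selected trajectory and the normalised
    backward-weight vector at time 1; its first component is the
    probability that the reference's time-1 coordinate would be
    re-selected, which drives the acceptance-rate adaptations.
    """
    T, N, d = history.particles.shape
    if model.transition_logdensity is None and T > 1:
        raise ValueError("backward sampling requires transition_logdensity")
    b = int(_categorical(_check_weights(history.weights[T - 1]), 1, rng)[0])
    states = np.empty((T, d))
    states[T - 1] = history.particles[T - 1, b]
    bw = history.weights[T - 1]
    for k in range(T - 2, -1, -1):
        xk = history.particles[k]
        xnext = np.broadcast_to(states[k + 1], (N, d))
        logv = history.log_weights[k] + model.transition_logdensity(k + 1, xk, xnext)
        if model.potential_depends_on_x_prev:
            logv = logv + model.potential(k + 1, xk, xnext)
        try:
            _, bw = _normalise_log_weights(logv, k)
        except DegenerateWeightsError as err:
            raise DegenerateWeightsError(
                f"all backward weights zero at time index {k}", time_index=k
            ) from err
        b = int(_categorical(bw, 1, rng)[0])
        states[k] = xk[b]
    return Trajectory(states), bw


def cpf_bs_kernel(
    model: FeynmanKacModel,
    reference: Trajectory,
    N: int,
    rng: np.random.Generator,
    pickpath: str = "bs",
) -> tuple[Trajectory, Optional[np.ndarray]]:
    """One step of the standard CPF Markov kernel (proper M1).

    Draws fresh time-1 particles from M1 (keeping the reference in slot 0),
    runs the forward CPF and selects a path by ancestor tracing
    (``pickpath="at"``) or backward sampling (``pickpath="bs"``).  This is
    the auxiliary-initialisation step with Q(x0, ·) = M1(·): the redundant
    pseudo-state draw from M1 is kept so that the random-number stream
    aligns exactly with the autoregressive kernel at β = 1.

    Returns the new trajectory and, under backward sampling, the
    time-1 backward weights (else ``None``).
    """
    if model.m1_sample is None:
        raise ValueError(
            "M1 is improper: the standard CPF is unavailable; use the "
            "fully-diffuse initialisation (FDI-CPF) instead"
        )
    _ = model.m1_sample(1, rng)  # pseudo-state draw; redundant when Q = M1
    init = np.empty((N, model.state_dim))
    init[0] = reference.states[0]
    init[1:] = model.m1_sample(N - 1, rng)
    history = forward_cpf(model, init, reference, rng)
    if pickpath == "at":
        return pickpath_at(history, rng), None
    elif pickpath == "bs":
        return pickpath_bs(model, history, rng)
    raise ValueError(f"unknown pickpath {pickpath!r}; expected 'at' or 'bs'")
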