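"""M1-reversible auxiliary kernels and the auxiliary-initialisation CPF.

The CPF mixes poorly when the initial measure M1 is diffuse relative to the
first smoothing marginal: nearly all fresh time-1 particles land in
irrelevant regions.  The remedy implemented here augments the target with a
pseudo-state ``x0`` linked to ``x1`` through a Markov kernel Q that is
reversible with respect to M1.  One sweep (the AI-CPF step) Gibbs-samples
``x0`` from Q(x1, ·), draws the fresh time-1 particles from Q(x0, ·), and
proceeds with the ordinary conditional particle filter.  Reversibility of Q
w.r.t. M1 — which may be improper — is exactly what makes the augmented
target well defined with pi as its marginal.

Two concrete kernels are provided:

* :class:`ARKernel` — an autoregressive (Crank–Nicolson style) proposal for
  a Gaussian M1 = N(mu, Sigma), ``z = sqrt(1 - beta^2)(x - mu) + beta W + mu``
  with ``W ~ N(0, Sigma)``; the resulting sampler is the "diffuse Gaussian
  initialisation" DGI-CPF.  At beta = 1 the kernel equals M1 and the method
  reduces to the standard CPF.
* :class:`RWKernel` / :class:`ConstrainedRWKernel` — Gaussian random walks,
  symmetric and hence reversible w.r.t. the improper uniform M1 ≡ 1, with an
  optional Metropolis-style indicator-domain constraint; the resulting
  sampler is the "fully diffuse initialisation" FDI-CPF.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .fk import FeynmanKacModel, Trajectory, forward_cpf, pickpath_at, pickpath_bs

__all__ = [
    "ARKernel",
    "RWKernel",
    "ConstrainedRWKernel",
    "AIStepResult",
    "ai_cpf_step",
    "fdi_rewrite",
]


def _chol_spd(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.atleast_2d(np.asarray(mat, dtype=float))
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T):
        raise ValueError(f"{name} must be a symmetric matrix")
    try:
        return np.linalg.cholesky(mat)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"{name} must be symmetric positive definite") from err


class RWKernel:
    """Gaussian random-walk kernel ``x -> x + W``, ``W ~ N(0, C)``.

    Symmetric, hence reversible with respect to the improper uniform
    density M1 ≡ 1 on R^d.
    """

    kind = "rw"

    def __init__(self, cov: np.ndarray):
        self._chol = _chol_spd(cov, "C")
        self.cov = self._chol @ self._chol.T
        self.dim = self._chol.shape[0]

    def sample(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return self.sample_n(x, 1, rng)[0]

    def sample_n(self, x: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
        x = np.asarray(x, dtype=float).reshape(-1)
        w = rng.standard_normal((n, self.dim)) @ self._chol.T
        return x[None, :] + w


class ConstrainedRWKernel:
    """Random walk with Metropolis rejection against an indicator domain.

    For M1(x) = 1(x in D) the Metropolis–Hastings acceptance ratio
    ``min(1, M1(y)/M1(x))`` reduces to the indicator 1(y in D): a proposal
    outside D is rejected and the current state is kept.  The resulting
    kernel is reversible w.r.t. the (possibly improper) uniform on D.
    """

    kind = "rw_constrained"

    def __init__(self, cov: np.ndarray, domain: Callable[[np.ndarray], bool]):
        self._rw = RWKernel(cov)
        self.cov = self._rw.cov
        self.dim = self._rw.dim
        self.domain = domain

    def sample(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        x = np.asarray(x, dtype=float).reshape(-1)
        if not self.domain(x):
            raise ValueError("current state is outside the constraint domain")
        y = self._rw.sample(x, rng)
        return y if self.domain(y) else x.copy()

    def sample_n(self, x: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
        x = np.asarray(x, dtype=float).reshape(-1)
        if not self.domain(x):
            raise ValueError("current state is outside the constraint domain")
        ys = self._rw.sample_n(x, n, rng)
        for i in range(n):
            if not self.domain(ys[i]):
                ys[i] = x
        return ys


class ARKernel:
    """Autoregressive kernel reversible w.r.t. a Gaussian M1 = N(mu, Sigma).

    ``sample(x) = sqrt(1 - beta^2) (x - mu) + beta W + mu`` with
    ``W ~ N(0, Sigma)`` and ``beta in (0, 1]``.  This is the
    "preconditioned Crank–Nicolson" proposal; detailed balance w.r.t.
    N(mu, Sigma) holds for every beta, and at beta = 1 the kernel is M1
    itself (draws independent of x).
    """

    kind = "ar"

    def __init__(self, beta: float, mu: np.ndarray, sigma: np.ndarray):
        if not (0.0 < beta <= 1.0):
            raise ValueError(f"beta must be in (0, 1], got {beta}")
        self.beta = float(beta)
        self.mu = np.atleast_1d(np.asarray(mu, dtype=float))
        self._chol = _chol_spd(sigma, "Sigma")
        self.sigma = self._chol @ self._chol.T
        self.dim = self._chol.shape[0]
        if self.mu.shape[0] != self.dim:
            raise ValueError("mu and Sigma dimensions disagree")

    def sample(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return self.sample_n(x, 1, rng)[0]

    def sample_n(self, x: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
        x = np.asarray(x, dtype=float).reshape(-1)
        w = rng.standard_normal((n, self.dim)) @ self._chol.T
        shrink = np.sqrt(1.0 - self.beta**2)
        return shrink * (x - self.mu)[None, :] + self.beta * w + self.mu[None, :]


def fdi_rewrite(model: FeynmanKacModel) -> FeynmanKacModel:
    """Rewrite a model with evaluable M1 into fully-diffuse form.

    Replaces M1 by the improper uniform and folds the M1 density into the
    first potential: ``G~_1(x) = M1(x) G_1(x)``.  The rewritten model has
    the same smoothing target and can be run with the FDI-CPF even though
    the original M1 was proper.
    """
    if model.m1_logdensity is None:
        raise ValueError("fdi_rewrite requires m1_logdensity")
    base_potential = model.potential
    base_logm1 = model.m1_logdensity

    def potential(k, x_prev, x):
        logg = base_potential(k, x_prev, x)
        if k == 0:
            logg = logg + base_logm1(x)
        return logg

    return FeynmanKacModel(
        T=model.T,
        state_dim=model.state_dim,
        potential=potential,
        transition_sample=model.transition_sample,
        transition_logdensity=model.transition_logdensity,
        m1_sample=None,
        m1_logdensity=None,
        potential_depends_on_x_prev=model.potential_depends_on_x_prev,
    )


@dataclass
class AIStepResult:
    """One AI-CPF sweep: the selected path plus adaptation inputs.

    ``bw1`` are the normalised time-1 backward weights (None under
    ancestor tracing); ``particles1`` the time-1 particle cloud with the
    reference in slot 0 (the pair drives the ASWAM adaptation); ``x0`` the
    auxiliary pseudo-state, reported for diagnostics only.
    """

    trajectory: Trajectory
    bw1: Optional[np.ndarray]
    x0: np.ndarray
    particles1: np.ndarray

    def __iter__(self):  # (trajectory, bw1) unpacking convenience
        return iter((self.trajectory, self.bw1))


def ai_cpf_step(
    model: FeynmanKacModel,
    kernel,
    reference: Trajectory,
    N: int,
    rng: np.random.Generator,
    pickpath: str = "bs",
) -> AIStepResult:
    """One auxiliary-initialisation CPF step.

    (i) Gibbs-draw the pseudo-state ``x0 ~ Q(x1, ·)`` from the reference's
    first coordinate; (ii) set slot 0 to the reference and draw slots 2..N
    i.i.d. from ``Q(x0, ·)``; (iii) run the forward CPF; (iv) select a path
    by the requested rule.  Provided Q is M1-reversible, the step leaves
    the smoothing distribution pi invariant (marginally over x0).
    """
    if N < 2:
        raise ValueError("ai_cpf_step requires N >= 2")
    x1_ref = reference.states[0]
    x0 = np.asarray(kernel.sample(x1_ref, rng))
    init = np.empty((N, model.state_dim))
    init[0] = x1_ref
    init[1:] = kernel.sample_n(x0, N - 1, rng)
    history = forward_cpf(model, init, reference, rng)
    if pickpath == "at":
        return AIStepResult(pickpath_at(history, rng), None, x0, history.particles[0])
    elif pickpath == "bs":
        traj, bw1 = pickpath_bs(model, history, rng)
        return AIStepResult(traj, bw1, x0, history.particles[0])
    raise ValueError(f"unknown pickpath {pickpath!r}; expected 'at' or 'bs'")
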