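"""Mixing diagnostics and exact oracles.

The mixing of a trajectory sampler is summarised by the integrated
autocorrelation time (IACT) of a scalar chain, the effective sample size
``n_eff = n / IACT``, and the inverse relative efficiency ``IRE = IACT * N``
which charges each iteration its particle cost so that samplers run with
different N are comparable.

Two exact references used throughout the test-suite also live here: the
Kalman filter / Rauch–Tung–Striebel smoother for the scalar linear-Gaussian
model, and a brute-force enumeration of the path-selection distribution of
the conditional particle filter on tiny systems.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.fft import next_fast_len

from .fk import FeynmanKacModel, Trajectory

__all__ = [
    "MixingSummary",
    "estimate_iact",
    "mixing_summary",
    "mcse_mean",
    "mcse_var",
    "rts_smoother",
    "enumerate_cpf_distribution",
]


@dataclass(frozen=True)
class MixingSummary:
    """IACT / n_eff / IRE for one chain.

    ``n`` is the chain length the IACT was computed from and ``n_total``
    the iteration count used in ``n_eff``; they may differ when the IACT
    is estimated post burn-in.  A well-mixing chain has IACT near 1; the
    estimator can legitimately dip below 1 on anticorrelated chains.
    """

    iact: float
    n_eff: float
    ire: float
    n: int
    N: int


def _autocorrelations(chain: np.ndarray) -> np.ndarray:
    chain = np.asarray(chain, dtype=float).reshape(-1)
    n = chain.size
    if n < 100:
        raise ValueError("chain too short for IACT estimation (need >= 100)")
    x = chain - chain.mean()
    nfft = next_fast_len(2 * n)
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n] / n
    if acov[0] <= 0:
        raise ValueError("constant chain: zero variance, IACT undefined")
    return acov / acov[0]


def estimate_iact(chain: np.ndarray, method: str = "gpss") -> float:
    """Integrated autocorrelation time ``1 + 2 * sum_k rho_k``.

    ``method="gpss"`` (default) truncates by Geyer's initial positive
    sequence rule: consecutive autocorrelation pairs
    ``Gamma_m = rho_{2m} + rho_{2m+1}`` are summed while positive (the
    first pair is always included).  ``method="sokal"`` uses Sokal's
    adaptive window: the smallest M with ``M >= 5 * tau_M``.
    """
    rho = _autocorrelations(chain)
    n = rho.size
    if method == "gpss":
        total = 0.0
        for m in range(n // 2):
            gamma = rho[2 * m] + (rho[2 * m + 1] if 2 * m + 1 < n else 0.0)
            if m > 0 and gamma <= 0:
                break
            total += gamma
        return 2.0 * total - 1.0
    elif method == "sokal":
        tau = 1.0
        for window in range(1, n):
            tau = 1.0 + 2.0 * rho[1 : window + 1].sum()
            if window >= 5.0 * tau:
                break
        return float(tau)
    raise ValueError(f"unknown IACT method {method!r}")


def mixing_summary(chain: np.ndarray, n_total: int, N: int, method: str = "gpss") -> MixingSummary:
    """IACT of ``chain`` with n_eff against ``n_total`` and IRE against N."""
    iact = estimate_iact(chain, method)
    return MixingSummary(
        iact=iact,
        n_eff=n_total / iact,
        ire=iact * N,
        n=len(np.asarray(chain).reshape(-1)),
        N=N,
    )


def mcse_mean(chain: np.ndarray) -> float:
    """Monte-Carlo standard error of the chain mean, IACT-inflated."""
    chain = np.asarray(chain, dtype=float).reshape(-1)
    iact = max(estimate_iact(chain), 1e-12)
    return float(chain.std(ddof=1) * np.sqrt(iact / chain.size))


def mcse_var(chain: np.ndarray) -> float:
    """Monte-Carlo standard error of the chain variance.

    Gaussian-motivated approximation ``var * sqrt(2 * IACT / n)``; adequate
    for the 3-standard-error agreement checks used here.
    """
    chain = np.asarray(chain, dtype=float).reshape(-1)
    iact = max(estimate_iact(chain), 1e-12)
    return float(chain.var(ddof=1) * np.sqrt(2.0 * iact / chain.size))


def rts_smoother(observations: np.ndarray, params) -> tuple[np.ndarray, np.ndarray]:
    """Exact smoothed means and variances for the scalar noisy-AR(1) model.

    Forward Kalman filter followed by the Rauch–Tung–Striebel backward
    pass for ``x_{k+1} = rho x_k + N(0, sigma_x^2)``,
    ``y_k = x_k + N(0, sigma_y^2)``, ``x_1 ~ N(0, sigma_1^2)``.  Requires a
    proper (finite-variance) initial law; for a diffuse analysis use a
    large finite ``sigma_1``, to which the smoothed moments are insensitive
    once the data dominate.
    """
    y = np.asarray(observations, dtype=float).reshape(-1)
    T = y.size
    if getattr(params, "fully_diffuse", False) or params.sigma_1 is None:
        raise ValueError(
            "rts_smoother needs a proper initial law; use a large finite sigma_1"
        )
    rho, sx2, sy2 = params.rho, params.sigma_x**2, params.sigma_y**2

    m_filt = np.empty(T)
    p_filt = np.empty(T)
    m_pred = np.empty(T)
    p_pred = np.empty(T)
    m_pred[0], p_pred[0] = 0.0, params.sigma_1**2
    for k in range(T):
        if k > 0:
            m_pred[k] = rho * m_filt[k - 1]
            p_pred[k] = rho**2 * p_filt[k - 1] + sx2
        gain = p_pred[k] / (p_pred[k] + sy2)
        m_filt[k] = m_pred[k] + gain * (y[k] - m_pred[k])
        p_filt[k] = (1.0 - gain) * p_pred[k]

    m_smooth = np.empty(T)
    p_smooth = np.empty(T)
    m_smooth[-1], p_smooth[-1] = m_filt[-1], p_filt[-1]
    for k in range(T - 2, -1, -1):
        c = p_filt[k] * rho / p_pred[k + 1]
        m_smooth[k] = m_filt[k] + c * (m_smooth[k + 1] - m_pred[k + 1])
        p_smooth[k] = p_filt[k] + c**2 * (p_smooth[k + 1] - p_pred[k + 1])
    return m_smooth, p_smooth


def _path_key(states: np.ndarray) -> tuple:
    return tuple(tuple(np.round(row, 12)) for row in states)


def enumerate_cpf_distribution(
    model: FeynmanKacModel,
    initial_particles: np.ndarray,
    reference: Trajectory,
    pickpath: str = "bs",
    max_outcomes: int = 10**6,
) -> dict:
    """Exact path-selection distribution of the CPF by brute force.

    Enumerates every conditional-resampling outcome (ancestors of the
    non-reference slots) and every path-selection outcome, weighting each
    by its probability, and returns a dict mapping the selected path
    (tuple of per-time state tuples, rounded to 12 decimals) to its exact
    probability.  The model's ``transition_sample`` must be deterministic
    (it is called with ``rng=None``) so that the particle system is a
    fixed function of the ancestry; only tiny systems (guarded at
    ``max_outcomes`` elementary outcomes) are tractable.
    """
    initial_particles = np.atleast_2d(np.asarray(initial_particles, dtype=float))
    N, d = initial_particles.shape
    T = model.T
    n_anc = N ** ((N - 1) * max(T - 1, 0))
    n_sel = N**T if pickpath == "bs" else N
    if n_anc * n_sel > max_outcomes:
        raise ValueError("system too large to enumerate")

    out: dict = {}
    logw0 = model.potential(0, None, initial_particles)
    w0 = np.exp(logw0 - logw0.max())
    w0 = w0 / w0.sum()

    for flat in itertools.product(range(N), repeat=(N - 1) * max(T - 1, 0)):
        particles = [initial_particles]
        weights = [w0]
        ancestors = []
        prob_anc = 1.0
        for k in range(1, T):
            anc = np.array((0,) + flat[(k - 1) * (N - 1) : k * (N - 1)], dtype=np.intp)
            prob_anc *= float(np.prod(weights[k - 1][anc[1:]]))
            parents = particles[k - 1][anc]
            xk = np.empty((N, d))
            xk[0] = reference.states[k]
            xk[1:] = model.transition_sample(k, parents[1:], None)
            logw = model.potential(k, parents, xk)
            w = np.exp(logw - logw.max())
            particles.append(xk)
            weights.append(w / w.sum())
            ancestors.append(anc)
        if prob_anc == 0.0:
            continue

        if pickpath == "at":
            for b in range(N):
                p = prob_anc * weights[T - 1][b]
                if p == 0.0:
                    continue
                states = np.empty((T, d))
                idx = b
                states[T - 1] = particles[T - 1][idx]
                for k in range(T - 2, -1, -1):
                    idx = int(ancestors[k][idx])
                    states[k] = particles[k][idx]
                key = _path_key(states)
                out[key] = out.get(key, 0.0) + p
        elif pickpath == "bs":
            # backward weights depend on the next selected index only
            for sel in itertools.product(range(N), repeat=T):
                p = prob_anc * weights[T - 1][sel[T - 1]]
                for k in range(T - 2, -1, -1):
                    xk = particles[k]
                    xnext = np.broadcast_to(particles[k + 1][sel[k + 1]], (N, d))
                    logv = (
                        np.log(np.maximum(weights[k], 1e-300))
                        + model.transition_logdensity(k + 1, xk, xnext)
                        + model.potential(k + 1, xk, xnext)
                    )
                    v = np.exp(logv - logv.max())
                    v /= v.sum()
                    p *= float(v[sel[k]])
                    if p == 0.0:
                        break
                if p == 0.0:
                    continue
                states = np.array([particles[k][sel[k]] for k in range(T)])
                key = _path_key(states)
                out[key] = out.get(key, 0.0) + p
        else:
            raise ValueError(f"unknown pickpath {pickpath!r}")
    return out
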