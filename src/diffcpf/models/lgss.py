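"""Noisy AR(1) (linear-Gaussian) state-space model.

    x_{k+1} = rho * x_k + eta_k,    eta_k ~ N(0, sigma_x^2)
    y_k     = x_k + eps_k,          eps_k ~ N(0, sigma_y^2)

with ``x_1 ~ N(0, sigma_1^2)`` (proper case) or an improper uniform initial
law (fully diffuse case).  ``rho = 1`` gives the noisy random-walk model.
The exact smoothing moments are available from the Kalman/RTS smoother,
which makes this the primary correctness oracle for the samplers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ..fk import FeynmanKacModel

__all__ = ["LgssParams", "simulate_lgss", "lgss_model"]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class LgssParams:
    rho: float
    sigma_x: float
    sigma_y: float
    T: int
    sigma_1: Optional[float] = None
    fully_diffuse: bool = False

    def __post_init__(self):
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError("sigma_x and sigma_y must be positive")
        if not self.fully_diffuse and (self.sigma_1 is None or self.sigma_1 <= 0):
            raise ValueError("a positive sigma_1 is required unless fully_diffuse")
        if self.T < 1:
            raise ValueError("T must be >= 1")


def simulate_lgss(
    params: LgssParams, x1_value: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a latent path and observations with ``x_1`` fixed.

    Returns ``(x, y)`` of shape ``(T,)`` each.
    """
    T = params.T
    x = np.empty(T)
    x[0] = x1_value
    for k in range(1, T):
        x[k] = params.rho * x[k - 1] + params.sigma_x * rng.standard_normal()
    y = x + params.sigma_y * rng.standard_normal(T)
    return x, y


def lgss_model(observations: np.ndarray, params: LgssParams) -> FeynmanKacModel:
    """Bootstrap Feynman–Kac form of the noisy AR(1) model.

    ``G_k(x_k) = N(y_k; x_k, sigma_y^2)``; Gaussian transitions; M1 either
    N(0, sigma_1^2) or (``fully_diffuse``) the improper uniform on R, in
    which case ``m1_sample`` is absent and ``log M1 ≡ 0``.
    """
    y = np.asarray(observations, dtype=float).reshape(-1)
    if y.size != params.T:
        raise ValueError(f"expected {params.T} observations, got {y.size}")
    rho, sx, sy = params.rho, params.sigma_x, params.sigma_y
    log_norm_y = -0.5 * _LOG_2PI - np.log(sy)
    log_norm_x = -0.5 * _LOG_2PI - np.log(sx)

    def potential(k, x_prev, x):
        return log_norm_y - 0.5 * ((y[k] - x[:, 0]) / sy) ** 2

    def transition_sample(k, x_prev, rng):
        return rho * x_prev + sx * rng.standard_normal(x_prev.shape)

    def transition_logdensity(k, x_prev, x):
        return log_norm_x - 0.5 * ((x[:, 0] - rho * x_prev[:, 0]) / sx) ** 2

    if params.fully_diffuse:
        m1_sample = None
        m1_logdensity = lambda x: np.zeros(x.shape[0])  # noqa: E731
        m1_mean = m1_cov = None
    else:
        m1_mean = np.zeros(1)
        m1_cov = np.array([[params.sigma_1**2]])
        chol = np.linalg.cholesky(m1_cov)

        def m1_sample(n, rng):
            return rng.standard_normal((n, 1)) @ chol.T + m1_mean[None, :]

        log_norm_1 = -0.5 * _LOG_2PI - np.log(params.sigma_1)

        def m1_logdensity(x):
            return log_norm_1 - 0.5 * (x[:, 0] / params.sigma_1) ** 2

    return FeynmanKacModel(
        potential_depends_on_x_prev=False,
        T=params.T,
        state_dim=1,
        potential=potential,
        transition_sample=transition_sample,
        transition_logdensity=transition_logdensity,
        m1_sample=m1_sample,
        m1_logdensity=m1_logdensity,
        m1_mean=m1_mean,
        m1_cov=m1_cov,
    )
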