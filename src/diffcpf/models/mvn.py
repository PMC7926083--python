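"""Static multivariate-normal target with a single time step.

With ``T = 1``, improper uniform M1 and ``G_1(x) = N(x; 0, sigma^2 I_d)``
the smoothing distribution is exactly N(0, sigma^2 I_d).  This stripped-down
model isolates the initialisation kernel: the fully-diffuse CPF on it is a
multiple-try-flavoured sampler whose behaviour as a function of the state
dimension d, particle number N and target acceptance rate can be compared
against the closed form.
"""

from __future__ import annotations

import numpy as np

from ..fk import FeynmanKacModel

__all__ = ["mvn_static_model"]


def mvn_static_model(d: int, sigma: float) -> FeynmanKacModel:
    """T = 1 model: M1 ∝ 1 on R^d, target N(0, sigma^2 I_d).

    ``sigma`` is the per-coordinate standard deviation.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    log_norm = -0.5 * d * float(np.log(2.0 * np.pi)) - d * float(np.log(sigma))

    def potential(k, x_prev, x):
        return log_norm - 0.5 * np.sum((x / sigma) ** 2, axis=1)

    return FeynmanKacModel(
        potential_depends_on_x_prev=False,
        T=1,
        state_dim=d,
        potential=potential,
        m1_logdensity=lambda x: np.zeros(x.shape[0]),
    )
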