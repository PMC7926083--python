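"""Repairing the diffuse-initialisation problem with the adaptive DGI-CPF.

The autoregressive kernel proposes fresh initial particles in a
beta-shrunk neighbourhood of the reference instead of from the wide M1;
the adaptation steers beta so that the reference's first state is
replaced with probability 0.8 per sweep.
"""

import numpy as np

from diffcpf import AdaptConfig, Trajectory, aai_cpf, estimate_iact, rts_smoother
from diffcpf.models import LgssParams, lgss_model, simulate_lgss

params = LgssParams(rho=0.8, sigma_x=0.5, sigma_y=0.5, T=50, sigma_1=1000.0)
x_true, y = simulate_lgss(params, 0.0, np.random.default_rng(1))
model = lgss_model(y, params)

out = aai_cpf(
    model, kernel_family="ar", adapt_rule="dgi",
    n_iter=5000, burn_in=1000, N=16,
    rng=np.random.default_rng(3),
    initial_reference=Trajectory(x_true[:, None]),
    config=AdaptConfig(alpha_star=0.8),
)

chain = out.coordinate_chain(0)
means, variances = rts_smoother(y, params)
print(f"adapted beta          : {out.final_state.beta:.4f}")
print(f"realised acceptance   : {np.nanmean(out.alphas[1000:]):.3f} (target 0.8)")
print(f"IACT(x1), sigma_1=1000: {estimate_iact(chain):.2f}  (plain CPF-BS: >100)")
print(f"x1 mean  : sampler {chain.mean():+.3f}  exact {means[0]:+.3f}")
print(
    "Even under an extremely diffuse initial law the adapted sampler\n"
    "mixes like the well-initialised CPF: beta shrinks until fresh\n"
    "particles are proposed at the scale of the smoothing marginal."
)
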