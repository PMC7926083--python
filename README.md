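# diffcpf

Conditional particle filters (CPF) for state-space models whose initial
distribution is **diffuse** — much wider than the first smoothing marginal,
possibly improper — with online adaptation of the initialisation kernel and
adaptive particle Gibbs for joint parameter-and-state inference.

## The problem

A hidden Markov model with latent path `x_{1:T}` and observations `y_{1:T}`
has smoothing distribution

    pi(x_{1:T}) ∝ M1(dx1) G1(x1) prod_{k=2}^T M_k(x_{k-1}, dx_k) G_k(x_{k-1:k}),

the Feynman–Kac form with initial measure `M1`, transitions `M_k` and
potentials `G_k` (for the bootstrap factorisation, `G_k = p(y_k | x_k)`).
The CPF with backward sampling is an excellent trajectory sampler for pi —
until `M1` is uninformative.  Then almost every fresh time-1 particle is
drawn where pi has no mass, the reference's first state is almost never
replaced, and mixing collapses: on a noisy AR(1) model the integrated
autocorrelation time (IACT) of the `x1` chain grows from ~4 to >100 as the
initial standard deviation goes from 10 to 1000.

## The method

Augment pi with a pseudo-state `x0` tied to `x1` through a Markov kernel
`Q` that is **reversible with respect to M1** (which may be improper).  One
sweep of the auxiliary-initialisation CPF (AI-CPF):

1. draw `x0 ~ Q(x1, ·)` from the reference's first state,
2. draw the fresh time-1 particles i.i.d. from `Q(x0, ·)`,
3. run the ordinary forward CPF and select a path by ancestor tracing or
   backward sampling.

M1-reversibility of `Q` makes this a pi-invariant Markov kernel, while the
fresh particles are now proposed *near the reference* instead of from the
wide `M1`.  Two concrete kernels:

- **DGI-CPF** (diffuse Gaussian initialisation), for Gaussian
  `M1 = N(mu, Sigma)`: the autoregressive / preconditioned-Crank–Nicolson
  kernel `z = sqrt(1-beta^2)(x-mu) + beta*W + mu`, `W ~ N(0, Sigma)`,
  `beta in (0, 1]`; at `beta = 1` it *is* `M1` and the sampler reduces to
  the standard CPF, bitwise.
- **FDI-CPF** (fully diffuse initialisation), for uniform (possibly
  constrained, possibly improper) `M1`: a Gaussian random walk with
  covariance `C`, Metropolis-rejected against the constraint indicator.

The free parameters (`beta`, `C`) are tuned online by stochastic
approximation with decaying steps: adaptive-Metropolis covariance learning
(AM), a Rao–Blackwellised adaptive-scaling variant (ASWAM) driven by the
probability `alpha = 1 - v1` that the reference's first coordinate is *not*
re-selected by backward sampling, and the analogous logit-beta rule for the
DGI kernel.  A target rate `alpha* ≈ 0.8` works well at moderate particle
counts.  For joint inference of hyperparameters theta the AI-CPF slots into
particle Gibbs (AAI-PG), with a robust-adaptive-Metropolis (RAM) proposal
for theta targeting acceptance 0.441.

Built-in test models: the noisy AR(1)/random-walk model (with exact
Kalman/RTS smoother oracle), a stochastic volatility model, a static
multivariate normal target, and a stochastic SEIR epidemic model with
negative-binomial case counts and an improper uniform initial law on the
population simplex — the motivating application.

## Worked example

```python
import numpy as np
from diffcpf import AdaptConfig, Trajectory, aai_cpf, estimate_iact, rts_smoother
from diffcpf.models import LgssParams, lgss_model, simulate_lgss

params = LgssParams(rho=0.8, sigma_x=0.5, sigma_y=0.5, T=50, sigma_1=1000.0)
x_true, y = simulate_lgss(params, 0.0, np.random.default_rng(1))
out = aai_cpf(lgss_model(y, params), kernel_family="ar", adapt_rule="dgi",
              n_iter=5000, burn_in=1000, N=16, rng=np.random.default_rng(3),
              initial_reference=Trajectory(x_true[:, None]),
              config=AdaptConfig(alpha_star=0.8))
chain = out.coordinate_chain(0)          # sampled x1 values
means, _ = rts_smoother(y, params)
print(out.final_state.beta, estimate_iact(chain), chain.mean(), means[0])
```

Running `examples/03_adaptive_dgi.py` (this script) prints

```
adapted beta          : 0.0011
realised acceptance   : 0.800 (target 0.8)
IACT(x1), sigma_1=1000: 2.01  (plain CPF-BS: >100)
x1 mean  : sampler +0.441  exact +0.445
```

meaning: the adaptation shrank beta to ~1e-3 so fresh particles are
proposed at the scale of the smoothing marginal, the reference's first
state is replaced 80% of sweeps, and the chain mixes two orders of
magnitude faster than the standard CPF on the same problem while agreeing
with the exact smoother.  The other scripts in `examples/` cover plain CPF
smoothing, the degradation ladder, the static-target FDI-CPF, and SEIR
particle Gibbs.

A thin CLI mirrors the runner: `diffcpf simulate|run|fixtures|report`
(`diffcpf run --config cfg.yaml --out out/` executes a config sweep and
writes `results.csv` with one IACT/n_eff/IRE row per cell).

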