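# Methods

## Model class and target

The package targets joint smoothing distributions in Feynman–Kac form,

    pi(dx_{1:T}) ∝ M1(dx1) G1(x1) prod_{k=2}^T M_k(x_{k-1}, dx_k) G_k(x_{k-1:k}),

with a sigma-finite (possibly improper) initial measure `M1`, Markov
transitions `M_k` and non-negative potentials `G_k`.  A
`FeynmanKacModel` bundles samplers and pointwise log-densities for these
ingredients; the transition density is needed only by backward sampling,
and `M1` needs a sampler only for the standard CPF.  All built-in models
use the bootstrap factorisation (`G_k = p(y_k | x_k)`), which they
advertise through a flag letting backward sampling drop the potential
factor — constant in the candidate index — from its weights.

## Samplers

**Forward CPF.**  Times carry 1..T and particles 1..N in the
documentation; arrays are zero-based and the reference trajectory is
pinned to slot 0 at every time.  Resampling is conditional multinomial
(slot 0's ancestor is slot 0, the rest i.i.d. categorical in the previous
weights); the weight-timing convention is resample-propagate-weight.  Only
multinomial resampling is implemented.  Path selection is ancestor tracing
(AT) or backward sampling (BS); BS additionally returns the normalised
time-1 backward weights, whose first component is the probability of
re-selecting the reference's first coordinate — the quantity the
acceptance-rate adaptations steer.

**Auxiliary initialisation.**  The AI-CPF step draws a pseudo-state
`x0 ~ Q(x1, ·)` and the fresh time-1 particles from `Q(x0, ·)`, where `Q`
satisfies detailed balance with respect to `M1`.  All of slots 2..N come
from `Q(x0, ·)`.  The standard CPF is implemented as the special case
`Q = M1`, *including* the then-redundant pseudo-state draw: this keeps the
random-number stream aligned with the autoregressive kernel at `beta = 1`,
so the reduction identity holds bitwise and is tested bitwise.

**Kernels.**  The autoregressive kernel (Gaussian `M1`) is
`z = sqrt(1-beta^2)(x-mu) + beta W + mu`, `W ~ N(0, Sigma)`, `beta` in
(0, 1].  The random-walk kernel (uniform `M1`) adds `N(0, C)` noise;
under a constraint indicator it Metropolis-rejects proposals outside the
domain.  Kernels evaluate the `M1` ratio as an indicator only; a
non-indicator improper `M1` should instead be folded into the first
potential (`fdi_rewrite`), which is tested to target the same law.

**Adaptation.**  Step sizes are `eta_j = (j+1)^(-2/3)` — any exponent in
(0.5, 1] satisfies the Robbins–Monro conditions; 2/3 trades fast early
adaptation against averaging noise.  AM updates mean and covariance from
the chain's own time-1 states and scales the kernel covariance by
`c = 2.38^2/d` by default; ASWAM updates them from *all* time-1 particles
with their backward weights (Rao–Blackwellisation) and steers a log-scale
`delta` by `eta_j (alpha - alpha*)`; the DGI rule applies the same
recursion to `logit(beta)`.  The Rao–Blackwellised `alpha = 1 - v1` is
used rather than a binary replacement indicator, for variance reduction.
Within one ASWAM step the mean and covariance recursions use the
pre-update mean (AM-style two-line recursion); any ordering with the same
stochastic-approximation fixed points would do.  Defaults:
`alpha* = 0.8` (values in 0.7–0.9 behave similarly at moderate N), initial
`mu = 0`, `Sigma = I`, `delta = 0`, `beta = 1/2`.  Stability is enforced
by clamping (`|logit beta| <= 20`, `|delta| <= e`, both configurable) and
an optional eigenvalue floor on the learned covariance; the floor is the
stabiliser the consistency theory asks for, and is exposed rather than a
more elaborate rejection device.

**Particle Gibbs.**  `aai_pg` alternates a Metropolis update of theta
given the path with one AI-CPF step given theta.  theta lives on an
unconstrained sampling scale chosen by the model builder (log for positive
parameters, logit for probabilities) and priors are specified as densities
on that scale, so no Jacobian terms appear in the acceptance ratio.  The
theta proposal is shaped by the robust adaptive Metropolis (RAM) rank-one
recursion with target acceptance 0.441, the classical univariate
random-walk optimum.  Update order is theta first, then the state —
arbitrary but fixed for reproducibility.  The `dpg_bs` baseline treats
`x_1` (jointly with theta when requested) as a parameter updated by one
RAM-adapted random-walk Metropolis step per sweep, followed by a standard
CPF-BS refresh of `x_{2:T}` conditional on `x_1` via a reduced
Feynman–Kac model whose initial sampler is `M_2(x_1, ·)`.  Its
block-update target contains every joint-density term involving the block;
the implementation simply evaluates the full joint density, which is exact
and (with the vectorised path density) cheap.

## Built-in models and the synthetic-data generator

The generator defaults are the study conditions used throughout the
tests:

- **Noisy AR(1)**: `rho = 0.8` (`rho = 1` gives the random-walk variant),
  `sigma_x = sigma_y = 0.5`, `T = 50`, `x1 = 0` fixed in simulation;
  initial law `N(0, sigma_1^2)` with `sigma_1` swept over 10/100/1000, or
  improper uniform.  The Kalman/RTS smoother provides exact smoothing
  moments and is cross-checked against an independent state-space
  implementation in the tests.
- **Stochastic volatility**: Gaussian random-walk log-volatility,
  `y_k = exp(x_k) eps_k`.
- **Static multivariate normal**: `T = 1`, improper uniform `M1`, target
  `N(0, sigma^2 I_d)` with `sigma` a per-coordinate standard deviation
  (the sweep treats it as a scale).
- **SEIR**: binomial compartment flows with
  `p_a = 1 - exp(-a)`, `p_gamma = 1 - exp(-gamma)`, infection probability
  `1 - exp(-beta_k I_k / n_pop)`, logit-random-walk reproduction number
  bounded by `r0_max`; counts `Y_k ~ NegBin(r_k, p)` with
  `r_k = e p_gamma p/(1-p) I_k`, i.e. mean `e p_gamma I_k` and variance
  mean/`p` (the "observed fraction of removals" reading; `r = 0` is a
  point mass at zero).  Study conditions: `n_pop = 10^4`, `T = 60`,
  `r0_max = 10`, `a = 1/3`, `gamma = 1/7`, `e = 0.15`, `sigma = 0.15`,
  `p = 0.134`, initial state `(E1, I1, rho1) = (20, 10, -1)` — an early
  epidemic with `R0 ≈ 2.7`, chosen once as a realistic outbreak seed; the
  generator is a first-class simulator, not a fixture.  The diffuse
  initial measure is the indicator of the population simplex with
  `R1 = 0`.  The initial kernel proposes a Gaussian step on
  `(rho_1, E_1, I_1)`, rounds the compartments to integers and rejects
  off-simplex proposals.  Rounding makes the proposal a symmetric
  random walk on the lattice, so uniform invariance survives exactly (and
  is verified by enumeration-scale chi-square on `n_pop = 10`).

What the generator does *not* emulate: real surveillance data have
day-of-week reporting effects, testing-policy changes, imported cases and
age/regional structure; passing tests show correct inference *under the
model*, not robustness to those misspecifications.

## Diagnostics

IACT is estimated as `1 + 2 sum rho_k` with the truncation chosen by
Geyer's initial-positive-sequence rule on autocorrelation pairs (the
first pair is always kept, so antithetic chains report values below 1);
Sokal's adaptive window is selectable.  `n_eff = n_total / IACT` uses the
*total* iteration count while the IACT itself is computed post burn-in —
both conventions are reported to avoid ambiguity.  `IRE = IACT x N`
charges each sweep its particle cost.  Note the estimator's sampling
error: for a chain with true IACT tau estimated from n samples the
relative standard error scales like `sqrt(tau/n)`-ish; at `tau ~ 10^2` and
`n = 5000` individual estimates routinely deviate by several tens of
percent, which is why ladder reproductions are compared with wide
stochastic tolerances and monotonicity checks rather than point equality.

The brute-force oracle `enumerate_cpf_distribution` computes the exact
path-selection law of the CPF on tiny systems (N, T <= 3) by summing over
every conditional-resampling and selection outcome; it requires a
deterministic transition map so the particle system is a function of the
ancestry, and it guards at 10^6 elementary outcomes.

## Problem sizes used in the test-suite

The deep end-to-end checks run at the following sizes, chosen so the full
suite completes comfortably on one CPU: the diffuse ladder at its native
6000 iterations (with four additional 2000-iteration replicates for the
monotonicity check); adapted-DGI exactness at 5x10^4 iterations; the
static-target recovery at 2x10^4; SEIR parameter recovery as 10
replicates of 2000-iteration chains; and the FDI-vs-baseline mixing
comparison as three seeds of 5000-iteration chains per sampler.  Longer
chains sharpen all of these checks but do not change their verdicts.

## Numerical choices

All weight arithmetic is in log space with max-shifted normalisation (no
overflow for log-potentials up to ~700); an all-zero weight vector raises
an error naming the offending time step.  Categorical draws use a single
uniform through the inverse CDF, so every run is reproducible from
(configuration, seed) and every stochastic routine takes an explicit
generator.  SEIR transition sampling and densities have numba-jitted inner
loops with an equivalent pure-numpy path (used automatically when numba is
absent and cross-validated in the tests).  RAM updates recompute a
Cholesky factor of the rank-one-updated square, which keeps `S` lower
triangular without an explicit triangular update.

## Known limitations

Only multinomial (conditional) resampling is provided; no systematic or
stratified variants, no adaptive particle counts, no parallel filtering.
Backward sampling requires pairwise potentials and pointwise transition
densities.  The `alpha* = 0.8` default is an empirical heuristic, not an
optimality result; the best target rate drifts toward 1 as N grows and
depends on the state dimension.  Improper-`M1` chains need a user-supplied
feasible starting trajectory (helpers draw one from a bounding box and
propagate through the transitions).  The DPG-BS baseline is included for
comparison, not recommendation: its initial-state block mixes poorly
precisely in the diffuse settings this package addresses.
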