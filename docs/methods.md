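# Methods

## Model

One observation per row: group id \(i\), observed time
\(y_{ij}=\min(t_{ij},c_{ij})>0\), event indicator \(d_{ij}\in\{0,1\}\),
covariates, optional planar coordinates.  Hazards are proportional,
\(h_{ij}(t)=h_0(t)e^{\eta_{ij}}\), with additive predictor

\[ \eta_{ij} = x_{ij}^\top\beta + \sum_q \gamma_q(u_{qij}) + \xi_i + \gamma_s(s_{ij}). \]

Assumptions: independent (random) right censoring; no global intercept
(absorbed by \(h_0\) and unidentifiable under the partial likelihood);
Breslow convention for tied event times everywhere — tied events reuse the
full common risk set, and censored observations at an event time are *in*
that event's risk set (\(y_{kl}\ge y_{ij}\) with equality).  Left
truncation, interval censoring, time-varying covariates, competing risks,
Efron ties and stratified likelihoods are out of scope.

## Terms and priors

* **Linear**: \(\beta \sim N(0, v I)\), default \(v = 1000\) (variance;
  a vague prior on a log-hazard-ratio scale).  Constant columns are
  rejected — an intercept cannot be identified.
* **Smooth**: cubic B-splines on `n_knots` equally spaced knots spanning
  the observed covariate range, boundary knots at full multiplicity, so
  the basis dimension is `n_knots + 2`.  The prior precision of the
  weights is \(e^{\theta} P\) with \(P_{ij}=\int \phi_i''\phi_j''\),
  computed exactly (the integrand is piecewise quadratic; a 2-point
  Gauss–Legendre rule per inter-knot interval).  \(P\) has rank \(d-2\)
  (null space = affine functions); a diagonal jitter of
  \(10^{-5}\times\) mean(diag \(P\)) makes the precision full-rank without
  altering its conditional-independence pattern.  The scale-free jitter
  keeps behaviour invariant under rescaling of the covariate.
* **Frailty**: \(\xi_i \sim N(0, \sigma_\xi^2)\) i.i.d. over groups.
* **Spatial**: Matérn with fixed shape \(\nu = 1\),
  \(C(h)=\sigma^2(\kappa h)K_1(\kappa h)\), \(\kappa=\sqrt{8\nu}/\rho\), so
  the correlation at distance \(\rho\) (the *practical range*) is
  \(\sqrt8 K_1(\sqrt8)\approx 0.14\).  This \(\sqrt{8\nu}\) convention is
  one of two in circulation (the other fixes correlation 0.1); it is a
  package constant documented here and the range prior can be rescaled if
  the other convention is wanted.  The term stores the dense covariance
  over distinct locations and factorizes it per \(\theta\); this is
  acceptable because the latent dimension is fixed by the number of
  distinct sites, not by \(N\).

Hyperparameters are transformed: \(\theta=-2\log\sigma\) for smooth and
frailty SDs, \((\log\sigma,\log\rho)\) for Matérn.  Priors are
exponential on the natural scale (the penalized-complexity prior for a
standard deviation), specified through a median (\(\lambda=\log 2/m\)) or
a tail probability (\(\lambda=-\log p/q\)), with the change-of-variables
Jacobian included on the \(\theta\) scale.  Gaussian priors on \(\beta\)
live inside the prior precision of \(W\), not in \(\pi(\theta)\).

## Partial likelihood evaluation

\(\ell(\eta)=\sum_{d_{ij}=1}[\eta_{ij}-\log\sum_{R_{ij}}e^{\eta_{lk}}]\)
is computed by sorting once by time and sweeping a reverse cumulative sum
of \(e^{\eta-\max\eta}\) (O(N log N), stable to predictor spreads of
several hundred; a spread beyond the exp range raises an explicit error).
Derivatives are taken analytically with respect to \(W\) through the
design map \(\eta = XW\):

* gradient: \(X^\top g\), \(g_i = d_i - e^{\eta_i}\sum_{e: i\in R_e} 1/S_e\),
* Hessian: \(-X^\top\sum_e[\mathrm{diag}(p_e)-p_ep_e^\top]X\)
  accumulated with reverse cumulative sums of \(w x\) and \(w xx^\top\),
  so the dense \(\dim W\times\dim W\) Hessian costs \(O(N\,\dim W^2)\).

\(\ell\) is concave and shift-invariant; both properties are asserted in
tests against brute-force evaluation, finite differences and an
established Cox implementation.  The differenced parameterization
\(\Delta_{ij}=\eta_{\text{ref}}-\eta_{ij}\) is exposed for completeness;
the reference is the first record in input order, and all results are
invariant to that choice.  The "noised-predictor" device (including the
\(N\) predictors in the latent vector with added Gaussian noise) is
deliberately *not* used — keeping \(W=(\Gamma,\beta,\xi)\) small is the
point of the construction.

## Nested approximation

For fixed \(\theta\), \(-\tfrac12 W^\top Q_\theta W+\ell(XW)\) is strictly
concave; damped Newton (tolerance \(10^{-8}\) on the max-norm gradient,
50 iterations max, up to 30 step halvings) finds the unique maximizer.
Warm starts across \(\theta\) are used everywhere; uniqueness makes them
safe (tested against cold starts).  The Gaussian approximation is
\(N(\hat W_\theta, H_\theta^{-1})\), \(H=Q_\theta-\nabla^2\ell\), and the
Laplace approximation of the hyperparameter posterior is

\[ \log\tilde\pi_{LA}(\theta\mid y)=\log\pi(\theta)+\tfrac12\log|Q_\theta|
-\tfrac12\log|H_\theta|-\tfrac12\hat W^\top Q_\theta\hat W+\ell(\hat W), \]

with determinants from Cholesky factors (retained and reused for
sampling) and block closed forms for \(\log|Q_\theta|\) (penalty
eigendecompositions are computed once per term).  For event-free data the
construction collapses exactly to the prior — tested to \(10^{-10}\) —
and with a quadratic pseudo-likelihood substituted for \(\ell\) every
stage is exact, which the test suite uses as an end-to-end conjugate
check.

The \(\theta\) mode is found by BFGS on \(-\log\tilde\pi_{LA}\) with
central finite-difference gradients (step \(10^{-4}\); no automatic
differentiation is used anywhere in the package — derivatives in \(W\)
are analytic and the \(\theta\) dimension is tiny).  The curvature at the
mode is a symmetrized finite difference of that gradient (step
\(10^{-3}\)) and must be positive definite.  The AGHQ rule is a product
Gauss–Hermite grid, `K` nodes **per dimension** (15, 7 and 4 are the
settings used in the validation studies), recentred and rescaled so that
the matched Gaussian is integrated exactly; `K = 1` degenerates to a pure
Laplace approximation, and \(\dim\theta=0\) (no variance parameters) to a
single Gaussian.

Mixture weights \(\phi_k\propto\tilde\pi_{LA}(\theta_k)\delta_k\) are
normalized with log-sum-exp.  Posterior draws choose components
multinomially and solve the retained triangular factor against standard
normal noise; two runs with the same seed are bit-identical.

Smooth marginals of single hyperparameters (e.g. for plotting or KS
comparison of \(\sigma_\xi\)) come from a dense renormalized evaluation of
\(\tilde\pi_{LA}\) along the coordinate profile through the mode (default
201–401 points over ±6–8 curvature SDs), transformed to the natural scale
with its Jacobian; samples are drawn by inverse-CDF interpolation.  For a
1-D \(\theta\) this is the exact normalized approximate posterior; for
multi-dimensional \(\theta\) it is a profile cut, which is the
package's deliberate, documented simplification.

## Constraints

The sum-to-zero constraint \(\sum_i\gamma(u_i)=0\) is imposed on samples
by conditioning by kriging: each draw is corrected with *its own mixture
component's* covariance,
\(x^* = x-\Sigma_kA^\top(A\Sigma_kA^\top)^{-1}Ax\).  After correction the
constraint holds to machine precision.  A subtlety: under the
diagonal-jitter regularization the correction direction equals the
constant function only up to \(O(\text{jitter}/\lambda_2)\) — exactly
constant shifts would require a rank-deficient prior.  The fitted-value
shift is constant to about \(10^{-3}\)–\(10^{-2}\) relative, which is the
honest scale of the jitter approximation and is what the tests assert.

## Spatial prediction

Posterior-predictive simulation at new sites is conditional-Gaussian per
draw under the draw's component \(\theta\): mean
\(C_{*s}C_{ss}^{-1}\gamma(s)\), covariance
\(C_{**}-C_{*s}C_{ss}^{-1}C_{s*}\) (symmetrized eigenvalue square root;
sites coincident with observed locations get conditional variance exactly
zero and reproduce the observed-site draw).  Exceedance maps report the
fraction of draws with \(e^{\gamma(s^*)}\) above a threshold (1.5 is the
conventional headline level).

## The MCMC oracle

Validation compares the approximation against Hamiltonian Monte Carlo on
the *same* joint posterior \(\pi(W,\theta\mid y)\): leapfrog trajectories
of jittered length (1 to 24 steps), dual-averaging step-size adaptation to
a 0.8 acceptance target, and a diagonal mass matrix estimated from the
middle warmup window.  The sampler works in a **non-centred**
parameterization, \(V\sim N(0,I)\), \(W=T_\theta V\) with per-block
covariance scale roots (eigen roots for penalties, \(e^{-\theta/2}\) for
frailties, the Matérn Cholesky factor for spatial blocks, with analytic
\(\partial T/\partial\theta\) throughout).  The centred parameterization
mixes pathologically here — with sparse groups the \(\sigma_\xi\)-funnel
drove the \(\theta\) effective sample size below 20 per 10,000 draws —
while the non-centred sampler reaches R-hat < 1.001 on the same problems.
A run qualifies as an oracle only when all split-R-hat values (arviz) are
below 1.01; the acceptance runs report their diagnostics.  Both samples
being compared are finite, so Kolmogorov–Smirnov statistics between
approximation and oracle carry two-sample noise of order
\(1.36\sqrt{1/B_1+1/B_2}\); validation bounds add this to the reference
discrepancies.

## Synthetic-data generator

Survival times use exact inverse-transform sampling through the
cumulative baseline hazard, \(T=H_0^{-1}(E\,e^{-\eta})\), with closed-form
\(H_0^{-1}\) for piecewise-constant and piecewise-linear hazards.
Censoring selects exactly round(rate·N) observations uniformly at random
and replaces each time \(t\) by \(c\sim U(0,t)\) — a random-censoring
mechanism, so independent censoring holds by construction.

* **Study 1 (sparse frailties)**: 60 groups of \(m\) observations,
  \(\xi_i\sim N(0,\sigma_\xi^2)\), \(x\sim N(0,1)\) with \(\beta=0.2\),
  simple step baseline, 10% censoring.  Grids
  \(m\in\{1,2,3,4,5,10\}\), \(\sigma_\xi\in\{0.4,0.8,1,1.3\}\) are the
  canonical settings; varying group sizes are supported through an
  explicit size vector.
* **Study 2 (nonlinear effect)**: \(n\) independent records,
  \(u\sim U(-6,6)\), \(\eta=\gamma(u)=1.5[\sin(0.8u)+1]\), 10% censoring,
  with three baseline shapes of increasing wiggliness.

The three baseline hazard shapes (simple step 0.05/0.15 switching at
t = 15; oscillating step 0.05/0.25 with period 5; alternating
ramps ±0.04 and constants on length-2 intervals with floor 0.01) are
package defaults chosen to span the qualitative regimes — flat, rapidly
alternating, mixed ramp/constant.  They are config-overridable and should
not be read as canonical constants of the validation designs.

What the generator does *not* emulate: covariate-dependent or informative
censoring, measurement error in covariates, time-varying effects, and
non-Gaussian frailty distributions.  Passing tests therefore demonstrate
correctness of the inferential machinery under the model, not robustness
to misspecification.

## Problem sizes used in validation

The test suite runs the full method at the reference design sizes
(kidney: N = 76 with K = 15 and 10,000 draws; study 1: 60 groups at
m = 2 and m = 10) but drives the MCMC oracle with 4 chains of
4,000–6,000 iterations — the non-centred sampler's effective sample
sizes at those lengths already put two-sample KS noise near 0.03, small
against the discrepancies being measured.  The nonlinear-effect design is
validated at n = 200 (30 knots, K = 7) against the oracle and with a
100-replication pointwise-coverage study at n = 300; these are the
package's chosen verification sizes for a smooth model whose full-scale
MCMC is a multi-hour computation.  Frequentist calibration of the fixed
effect (interval coverage and bias of the posterior mean of \(\beta\)) is
checked over 60 replications of the m = 5 design.  The acceptance script runs the
sparse-frailty comparison at the full reference settings (4 × 35,000
iterations, 25,000 warmup).

## Known limitations

* The Laplace approximation of \(\pi(\sigma_\xi\mid y)\) is least
  accurate exactly where the design is hardest (few events per group);
  the validation quantifies this (KS ≈ 0.1 at m = 2 vs ≈ 0.02 at
  m = 10) rather than hiding it.
* Hyperparameter marginals are profile-based for \(\dim\theta>1\).
* No marginal-posterior corrections for individual coordinates of
  \(W\) (simplified/full Laplace refinements) are attempted.
* Model-choice criteria (DIC/WAIC), posterior-predictive survival curves
  and baseline-hazard estimation are out of scope by design — the partial
  likelihood never identifies \(h_0\).
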