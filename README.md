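# coxagq

Approximate Bayesian inference for Cox proportional hazards models based on
the **partial likelihood**, with linear covariate effects, penalized
B-spline nonlinear effects, i.i.d. group frailties and Matérn spatial
random effects.

## The problem

For grouped time-to-event data \(y_{ij} = \min(t_{ij}, c_{ij})\) with event
indicators \(d_{ij}\), the Cox model assumes hazards
\(h_{ij}(t) = h_0(t)\exp(\eta_{ij})\) with an additive predictor

\[
\eta_{ij} = x_{ij}^\top\beta + \sum_q \gamma_q(u_{qij}) + \xi_i,
\qquad \xi_i \sim N(0, \sigma_\xi^2),
\]

where the \(\gamma_q\) are smooth functions with penalized cubic B-spline
(O'Sullivan) priors, and a Matérn (\(\nu=1\)) Gaussian field can replace a
smooth term for spatial data.  Inference uses the partial likelihood

\[
\pi(y\mid\eta)=\prod_{ij}\Big\{\exp(\eta_{ij}) \big/ \textstyle\sum_{(l,k)\in R_{ij}}\exp(\eta_{lk})\Big\}^{d_{ij}},
\]

with risk sets \(R_{ij}=\{(k,l): y_{kl}\ge y_{ij}\}\) and Breslow tie
handling, so the baseline hazard \(h_0\) is never modeled or estimated.
Because the log partial likelihood has a *dense* Hessian, the standard
sparse-Hessian machinery of integrated nested Laplace approximations does
not apply.  The method here keeps the latent vector small —
\(W=(\Gamma,\beta,\xi)\), never the \(N\) predictors — so the dense Hessian
has fixed dimension regardless of the sample size.

Inference proceeds by nested approximation: for each value of the variance
parameters \(\theta\) (on the scale \(\theta_q=-2\log\sigma_q\)), a Newton
solver finds the conditional mode \(\hat W_\theta\) and a Gaussian
approximation \(\tilde\pi_G(W\mid y,\theta)\); the Tierney–Kadane Laplace
approximation \(\tilde\pi_{LA}(\theta\mid y)\) is then integrated with an
**adaptive Gauss–Hermite quadrature** rule (K nodes per dimension, centred
at the mode of \(\tilde\pi_{LA}\) and scaled by its curvature).  The
posterior of \(W\) is the resulting K-component Gaussian mixture

\[
\tilde\pi(W\mid y)=\sum_k \phi_k\, \tilde\pi_G(W\mid y,\theta_k),
\qquad \phi_k \propto \tilde\pi_{LA}(\theta_k\mid y)\,\delta_k,
\]

sampled exactly (multinomial component choice + Gaussian draws), with
sum-to-zero constraints on smooth terms imposed by conditioning by kriging.
Hyperpriors are exponential (penalized-complexity) distributions on
standard deviations and ranges, specified through a median or a tail
probability.  An in-repo Hamiltonian Monte Carlo oracle targets the same
exact joint posterior for validation, compared through two-sample
Kolmogorov–Smirnov statistics.

## Worked example: kidney catheter infections

The bundled fixture is the classic kidney-catheter dataset: 76 times to
infection for 38 patients (two catheters each), with covariates age, sex,
and disease type (GN/AN/PKD vs other).  Patient-level frailties capture the
within-patient correlation.

```python
import numpy as np
import coxagq as cq
from coxagq.design import LinearTerm, FrailtyTerm, ModelSpec
from coxagq.priors import exponential_prior

kid = cq.load_kidney()
cols = ["age", "female", "GN", "AN", "PKD"]
X = np.column_stack([kid.covariate(c) for c in cols])
spec = ModelSpec(
    linear=LinearTerm(X, cols, prior_variance=1000.0),
    frailty=FrailtyTerm(kid.group_codes, kid.n_groups,
                        prior=exponential_prior(median=2.0)),
)
res = cq.fit(spec, kid, K_per_dim=15, B=10_000, seed=1)
print(res.summaries.head(5)[["name", "mean", "sd"]].to_string(index=False))
```

```
   name      mean       sd
    age  0.004581 0.014922
 female -1.649783 0.470761
     GN  0.166516 0.539400
     AN  0.393567 0.534338
    PKD -1.189892 0.808028
```

Interpretation: female sex is strongly protective (hazard ratio
\(e^{-1.65}\approx 0.19\)), polycystic kidney disease (PKD) is associated
with a lower infection hazard relative to "other" disease, and age has a
negligible effect.  The frailty SD posterior (via
`res.sigma_marginal(0)`) concentrates around 0.6–0.7, i.e. substantial
within-patient correlation.  The whole fit takes well under a second.

A command-line interface wraps the same pipeline:

```sh
coxagq simulate --study 1 --m 2 --sigma-xi 1 --seed 3 --out data.csv
coxagq fit --data data.csv --config model.yaml --seed 7 --out run/
coxagq compare --data data.csv --config model.yaml --chains 4 \
    --iter 10000 --warmup 8000 --seed 7 --out ks_report.json
```

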