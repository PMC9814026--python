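"""Gaussian-mixture posterior: sampling, constraints, summaries, prediction.

The approximate posterior of the latent vector W is the K-component
Gaussian mixture

    pi(W|y) = sum_k phi_k N(W; W_hat_k, H_k^{-1}),

with one component per quadrature node theta_k and weights
phi_k propto pi_LA(theta_k|y) delta_k.  Sampling draws component indices
from Multinomial(phi) and then solves each component's retained Cholesky
factor against standard-normal noise.  Sum-to-zero constraints on smooth
terms are imposed on the samples by conditioning by kriging, each draw
corrected with its own component's covariance.  Spatial prediction at new
sites is conditional-Gaussian simulation under the Matern covariance of
each draw's component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from . import aghq as _aghq
from .design import ModelSpec, matern
from .laplace_core import LaplaceEvaluator, optimize_W
from .partial_likelihood import CoxPartialLikelihood
from .survdata import SurvivalDataset, build_risk_sets

__all__ = [
    "MixturePosterior",
    "PosteriorSamples",
    "FitResult",
    "fit",
    "sample",
    "apply_constraint",
    "summarize",
    "ks_statistic",
    "predict_spatial",
    "exceedance",
]


@dataclass
class MixturePosterior:
    components: list                 # InnerSolution per node (mean, chol kept)
    weights: np.ndarray              # phi, sums to 1
    spec: ModelSpec
    rule: object                     # QuadratureRule

    @property
    def K(self) -> int:
        return len(self.components)

    @property
    def dim(self) -> int:
        return self.spec.dim_W

    def exact_mean(self) -> np.ndarray:
        """Mixture-exact posterior mean sum_k phi_k W_hat_k."""
        means = np.stack([c.W_hat for c in self.components])
        return self.weights @ means

    def exact_cov(self) -> np.ndarray:
        """Mixture-exact posterior covariance (law of total covariance)."""
        m = self.exact_mean()
        cov = np.zeros((self.dim, self.dim))
        for phi, c in zip(self.weights, self.components):
            Sk = linalg.cho_solve(c.chol, np.eye(self.dim))
            dm = c.W_hat - m
            cov += phi * (Sk + np.outer(dm, dm))
        return cov


@dataclass
class PosteriorSamples:
    draws: np.ndarray                # B x dim(W)
    component_indices: np.ndarray    # B, which mixture component
    seed: int
    names: list = field(default_factory=list)
    constraint_applied: dict = field(default_factory=dict)

    @property
    def B(self) -> int:
        return len(self.draws)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.draws, columns=self.names or None)


def sample(mix: MixturePosterior, B: int, seed: int) -> PosteriorSamples:
    """B independent draws from the mixture (multinomial + Gaussian)."""
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    Z = rng.choice(mix.K, size=B, p=mix.weights)
    draws = np.empty((B, mix.dim))
    for k in range(mix.K):
        idx = np.flatnonzero(Z == k)
        if idx.size == 0:
            continue
        c = mix.components[k]
        noise = rng.standard_normal((idx.size, mix.dim))
        # H = R'R (upper cho_factor); cov = H^-1 = R^-1 R^-T: x = R^-1 z
        R, lower = c.chol
        if lower:
            dev = linalg.solve_triangular(R.T, noise.T, lower=False).T
        else:
            dev = linalg.solve_triangular(R, noise.T, lower=False).T
        draws[idx] = c.W_hat + dev
    return PosteriorSamples(
        draws=draws, component_indices=Z, seed=seed,
        names=list(mix.spec.latent_names),
    )


def apply_constraint(samples: PosteriorSamples, mix: MixturePosterior,
                     A: np.ndarray, block: slice) -> PosteriorSamples:
    """Condition draws on A w_block = 0 by kriging.

    Per draw from component k:  w* = w - Sigma_k A'(A Sigma_k A')^{-1} A w,
    restricted to the block; exact and idempotent.  The correction direction
    lies (up to O(jitter)) along the constant function, so fitted smooth
    values shift by an (almost) constant only.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    if not np.any(A):
        raise ValueError("constraint row is identically zero")
    dim = mix.dim
    A_full = np.zeros((A.shape[0], dim))
    A_full[:, block] = A
    draws = samples.draws.copy()
    for k in range(mix.K):
        idx = np.flatnonzero(samples.component_indices == k)
        if idx.size == 0:
            continue
        c = mix.components[k]
        V = linalg.cho_solve(c.chol, A_full.T)           # Sigma_k A'
        S = A_full @ V                                   # A Sigma_k A'
        try:
            corr = V @ np.linalg.solve(S, A_full[:, block] @ draws[idx][:, block].T)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError("A Sigma A' is singular") from exc
        draws[idx] -= corr.T
    out = PosteriorSamples(
        draws=draws, component_indices=samples.component_indices,
        seed=samples.seed, names=samples.names,
        constraint_applied=dict(samples.constraint_applied),
    )
    return out


def summarize(samples: PosteriorSamples, level: float = 0.95,
              mix: MixturePosterior | None = None) -> pd.DataFrame:
    """Per-coordinate empirical mean, SD and equal-tailed interval.

    If the mixture is supplied, mixture-exact means/SDs (law of total
    expectation/covariance over the K components) are reported alongside.
    """
    if samples.B < 2:
        raise ValueError("need at least two draws to summarize")
    lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
    q = np.quantile(samples.draws, [lo, hi], axis=0)
    out = pd.DataFrame({
        "name": samples.names or np.arange(samples.draws.shape[1]),
        "mean": samples.draws.mean(axis=0),
        "sd": samples.draws.std(axis=0, ddof=1),
        "lower": q[0],
        "upper": q[1],
    })
    if mix is not None:
        out["exact_mean"] = mix.exact_mean()
        out["exact_sd"] = np.sqrt(np.diag(mix.exact_cov()))
    return out


def ks_statistic(a, b) -> float:
    """Two-sample Kolmogorov-Smirnov statistic sup_x |F_a(x) - F_b(x)|."""
    a = np.sort(np.asarray(a, dtype=float).ravel())
    b = np.sort(np.asarray(b, dtype=float).ravel())
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([a, b])
    Fa = np.searchsorted(a, pooled, side="right") / a.size
    Fb = np.searchsorted(b, pooled, side="right") / b.size
    return float(np.max(np.abs(Fa - Fb)))


# ---------------------------------------------------------------------------
# spatial prediction


def predict_spatial(mix: MixturePosterior, samples: PosteriorSamples,
                    new_locations, seed: int = 0,
                    coincident_tol: float = 1e-12) -> np.ndarray:
    """Posterior-predictive draws of the spatial field at new sites.

    For each draw (with its component's theta giving sigma, rho), simulate
    gamma(s*) | gamma(s) from the conditional Gaussian under the Matern
    covariance: mean C_*s C_ss^-1 g, covariance C_** - C_*s C_ss^-1 C_s*.
    New sites coincident with observed ones return the observed-site value.
    Returns a B x L_new array.
    """
    spatial = mix.spec.spatial
    if spatial is None:
        raise ValueError("model has no spatial term")
    new_locations = np.atleast_2d(np.asarray(new_locations, dtype=float))
    block = mix.spec.block("spatial")
    obs = spatial.unique_locations
    d_new_obs = np.sqrt(
        ((new_locations[:, None, :] - obs[None, :, :]) ** 2).sum(-1))
    d_new_new = np.sqrt(
        ((new_locations[:, None, :] - new_locations[None, :, :]) ** 2).sum(-1))
    th_idx = mix.spec.theta_names.index("spatial_sd")
    rng = np.random.default_rng(seed)
    B = samples.B
    out = np.empty((B, len(new_locations)))
    for k in range(mix.K):
        idx = np.flatnonzero(samples.component_indices == k)
        if idx.size == 0:
            continue
        th = mix.components[k].theta
        sig, rho = np.exp(th[th_idx]), np.exp(th[th_idx + 1])
        C_ss = matern(spatial.distance_matrix, sig, rho)
        C_star_s = matern(d_new_obs, sig, rho)
        C_star_star = matern(d_new_new, sig, rho)
        cf = linalg.cho_factor(C_ss)
        W_proj = linalg.cho_solve(cf, C_star_s.T)        # C_ss^-1 C_s*
        cond_cov = C_star_star - C_star_s @ W_proj
        cond_cov = 0.5 * (cond_cov + cond_cov.T)
        # coincident sites: conditional variance exactly zero
        coincident = d_new_obs.min(axis=1) <= coincident_tol
        cond_cov[coincident, :] = 0.0
        cond_cov[:, coincident] = 0.0
        evals, evecs = np.linalg.eigh(cond_cov)
        root = evecs * np.sqrt(np.clip(evals, 0.0, None))
        g = samples.draws[idx][:, block]
        mean = g @ W_proj
        noise = rng.standard_normal((idx.size, len(new_locations)))
        out[idx] = mean + noise @ root.T
    return out


def exceedance(draws_per_location: np.ndarray, threshold: float) -> np.ndarray:
    """Per-location posterior probability that exp(effect) > threshold."""
    draws = np.atleast_2d(np.asarray(draws_per_location, dtype=float))
    return (np.exp(draws) > threshold).mean(axis=0)


# ---------------------------------------------------------------------------
# end-to-end fit


@dataclass
class FitResult:
    mixture: MixturePosterior
    samples: PosteriorSamples
    summaries: pd.DataFrame
    rule: object
    evaluator: LaplaceEvaluator
    theta_mode: np.ndarray
    seed: int

    def sigma_marginal(self, coord: int = 0, n_grid: int = 401,
                       half_width: float = 8.0):
        """Dense normalized marginal of the natural-scale hyperparameter."""
        return _aghq.sigma_marginal(
            self.evaluator, self.rule, self.mixture.spec, coord,
            n_grid=n_grid, half_width=half_width)

    def sample_sigma(self, coord: int = 0, B: int = 10_000,
                     seed: int | None = None, **kw) -> np.ndarray:
        """Inverse-CDF draws of sigma (or rho) from the dense marginal."""
        sig, dens = self.sigma_marginal(coord, **kw)
        cdf = np.concatenate([[0.0], np.cumsum(
            0.5 * (dens[1:] + dens[:-1]) * np.diff(sig))])
        cdf /= cdf[-1]
        rng = np.random.default_rng(self.seed + 1 if seed is None else seed)
        u = rng.uniform(size=B)
        return np.interp(u, cdf, sig)


def fit(spec: ModelSpec, data: SurvivalDataset, K_per_dim: int = 15,
        B: int = 10_000, seed: int = 0, likelihood=None,
        apply_constraints: bool = True, level: float = 0.95) -> FitResult:
    """Full inference pipeline; deterministic given the seed.

    Stages: risk sets -> theta mode -> AGHQ rule -> per-node inner
    optimization -> mixture sampling -> sum-to-zero correction ->
    summaries.  ``likelihood`` defaults to the Cox partial likelihood with
    Breslow ties; a pluggable replacement supports exact-limit validation.
    """
    if likelihood is None:
        risk = build_risk_sets(data, allow_empty=True)
        likelihood = CoxPartialLikelihood(risk)
    theta_hat, curvature, evaluator = _aghq.find_mode_theta(spec, likelihood)
    rule = _aghq.build_rule(theta_hat, curvature, K_per_dim)
    components = []
    log_values = np.empty(rule.K_total)
    for k in range(rule.K_total):
        sol = evaluator.solve(rule.nodes[k])
        components.append(sol)
        log_values[k] = sol.log_laplace
    phi = _aghq.mixture_weights(rule, log_values)
    mix = MixturePosterior(components=components, weights=phi,
                           spec=spec, rule=rule)
    samples = sample(mix, B, seed)
    if apply_constraints:
        for sm in spec.smooths:
            samples = apply_constraint(
                samples, mix, sm.constraint, spec.block(f"smooth:{sm.name}"))
            samples.constraint_applied[sm.name] = True
    summaries = summarize(samples, level=level, mix=mix)
    return FitResult(
        mixture=mix, samples=samples, summaries=summaries, rule=rule,
        evaluator=evaluator, theta_mode=theta_hat, seed=seed,
    )
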