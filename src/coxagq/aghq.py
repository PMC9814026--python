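"""Hyperparameter mode finding and adaptive Gauss-Hermite quadrature.

The AGHQ rule recentres a product Gauss-Hermite grid at the mode theta_hat
of log pi_LA(theta|y) and rescales it by the local curvature: with
curvature^{-1} = L L' and physicists' Gauss-Hermite abscissae/weights
(x_i, w_i),

    theta_k = theta_hat + sqrt(2) L x_k,
    delta_k = |sqrt(2) L| prod_i w_i exp(x_i^2),

so that  integral f(theta) dtheta  ~  sum_k f(theta_k) delta_k,  exact for
the matched Gaussian.  Mixture weights over the quadrature nodes are
phi_k propto exp(log pi_LA(theta_k)) delta_k, normalized.

K = 1 degenerates to a single node at the mode (pure Laplace).  With
dim(theta) = 0 (no hyperparameters) the rule is a single empty node of
weight one, and the whole pipeline collapses to one Gaussian approximation.

Smooth marginal posteriors of single hyperparameters (e.g. a frailty SD)
come from a dense renormalized evaluation of pi_LA along the coordinate
profile through the mode, not from the K nodes themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import linalg, optimize
from scipy.special import logsumexp

from .laplace_core import LaplaceEvaluator

__all__ = [
    "QuadratureRule",
    "find_mode_theta",
    "build_rule",
    "mixture_weights",
    "theta_coordinate_grid",
    "sigma_marginal",
]

FD_STEP_GRAD = 1e-4
FD_STEP_CURV = 1e-3
MODE_GTOL = 1e-6


@dataclass
class QuadratureRule:
    mode: np.ndarray
    curvature: np.ndarray        # negative Hessian of log pi_LA at the mode
    scale: np.ndarray            # lower-triangular L, L L' = curvature^{-1}
    nodes: np.ndarray            # K_total x dim_theta
    raw_weights: np.ndarray      # delta_k
    K_per_dim: int
    log_values: np.ndarray | None = None    # log pi_LA at the nodes
    mixture: np.ndarray | None = None       # normalized phi_k

    @property
    def K_total(self) -> int:
        return len(self.nodes)

    @property
    def dim(self) -> int:
        return self.mode.size

    def log_normalizing_constant(self) -> float:
        """AGHQ estimate of log integral exp(log pi_LA) dtheta."""
        if self.log_values is None:
            raise ValueError("rule has no evaluated log values")
        if self.dim == 0:
            return float(self.log_values[0])
        return float(logsumexp(self.log_values + np.log(self.raw_weights)))


def _fd_gradient(f, x, step=FD_STEP_GRAD):
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = step
        g[i] = (f(x + e) - f(x - e)) / (2 * step)
    return g


def find_mode_theta(spec, likelihood, start=None, evaluator=None):
    """Maximize log pi_LA(theta|y); returns (theta_hat, curvature, evaluator).

    Quasi-Newton (BFGS) with central finite-difference gradients on the
    theta scale; the curvature at the mode is a central finite difference of
    that gradient, symmetrized, and must be positive definite.
    """
    ev = evaluator or LaplaceEvaluator(spec, likelihood)
    if spec.dim_theta == 0:
        return np.zeros(0), np.zeros((0, 0)), ev
    x0 = np.zeros(spec.dim_theta) if start is None else np.asarray(start, float)

    def neg(th):
        return -ev(th)

    res = optimize.minimize(
        neg, x0, method="BFGS",
        jac=lambda th: _fd_gradient(neg, th),
        options={"gtol": MODE_GTOL, "maxiter": 200},
    )
    theta_hat = res.x
    d = theta_hat.size
    curv = np.zeros((d, d))
    for i in range(d):
        e = np.zeros(d)
        e[i] = FD_STEP_CURV
        gp = _fd_gradient(neg, theta_hat + e)
        gm = _fd_gradient(neg, theta_hat - e)
        curv[i] = (gp - gm) / (2 * FD_STEP_CURV)
    curv = 0.5 * (curv + curv.T)
    evals = np.linalg.eigvalsh(curv)
    if np.any(evals <= 0):
        raise RuntimeError(
            f"curvature at theta mode is not positive definite "
            f"(eigenvalues {evals}); try a different start or reparameterize"
        )
    return theta_hat, curv, ev


def build_rule(theta_hat, curvature, K_per_dim: int) -> QuadratureRule:
    """Product adaptive Gauss-Hermite rule with K_per_dim nodes per axis."""
    if K_per_dim < 1:
        raise ValueError("K_per_dim must be >= 1")
    theta_hat = np.atleast_1d(np.asarray(theta_hat, dtype=float))
    d = theta_hat.size
    if d == 0:
        return QuadratureRule(
            mode=theta_hat, curvature=np.zeros((0, 0)), scale=np.zeros((0, 0)),
            nodes=np.zeros((1, 0)), raw_weights=np.ones(1), K_per_dim=K_per_dim,
        )
    curvature = np.asarray(curvature, dtype=float).reshape(d, d)
    cov = np.linalg.inv(curvature)
    L = np.linalg.cholesky(0.5 * (cov + cov.T))
    x, w = np.polynomial.hermite.hermgauss(K_per_dim)
    nodes = np.empty((K_per_dim**d, d))
    raw = np.empty(K_per_dim**d)
    log_wex = np.log(w) + x**2
    det = np.sqrt(2.0) ** d * np.prod(np.diag(L))
    for k, idx in enumerate(product(range(K_per_dim), repeat=d)):
        z = x[list(idx)]
        nodes[k] = theta_hat + np.sqrt(2.0) * L @ z
        raw[k] = det * np.exp(np.sum(log_wex[list(idx)]))
    return QuadratureRule(
        mode=theta_hat, curvature=curvature, scale=L,
        nodes=nodes, raw_weights=raw, K_per_dim=K_per_dim,
    )


def mixture_weights(rule: QuadratureRule, log_values) -> np.ndarray:
    """phi_k propto exp(log pi_LA(theta_k)) delta_k, log-sum-exp normalized."""
    log_values = np.asarray(log_values, dtype=float)
    if log_values.size != rule.K_total:
        raise ValueError("log_values length does not match rule")
    if np.all(np.isneginf(log_values)):
        raise ValueError("all mixture log values are -inf")
    logw = log_values + np.log(rule.raw_weights)
    phi = np.exp(logw - logsumexp(logw))
    phi /= phi.sum()
    rule.log_values = log_values
    rule.mixture = phi
    return phi


# ---------------------------------------------------------------------------
# dense-grid marginals of single hyperparameters


def theta_coordinate_grid(evaluator, rule: QuadratureRule, coord: int,
                          n_grid: int = 201, half_width: float = 6.0):
    """Normalized density of theta[coord] on a profile grid through the mode.

    Other coordinates are held at the mode (a profile cut, rescaled to a
    proper density).  For a 1-D theta this is the exact normalized
    Laplace-approximate posterior on a dense grid.
    """
    sd = float(np.sqrt(np.linalg.inv(rule.curvature)[coord, coord]))
    grid = rule.mode[coord] + np.linspace(-half_width, half_width, n_grid) * sd
    logv = np.empty(n_grid)
    for i, g in enumerate(grid):
        th = rule.mode.copy()
        th[coord] = g
        logv[i] = evaluator(th)
    logv -= logv.max()
    dens = np.exp(logv)
    dens /= np.trapezoid(dens, grid)
    return grid, dens


def sigma_marginal(evaluator, rule: QuadratureRule, spec, coord: int,
                   n_grid: int = 201, half_width: float = 6.0):
    """Marginal density of the natural-scale parameter (sigma or rho).

    Change of variables from the theta grid using the coordinate's
    transformation Jacobian; returns (sigma_grid, density) with the grid
    ascending in sigma.
    """
    grid, dens = theta_coordinate_grid(evaluator, rule, coord, n_grid, half_width)
    prior = spec.theta_priors[coord]
    if prior.transformation == "minus_two_log_sigma":
        sig = np.exp(-grid / 2.0)
        jac = 2.0 / sig
    else:
        sig = np.exp(grid)
        jac = 1.0 / sig
    dens_sigma = dens * jac
    order = np.argsort(sig)
    sig, dens_sigma = sig[order], dens_sigma[order]
    dens_sigma /= np.trapezoid(dens_sigma, sig)
    return sig, dens_sigma
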