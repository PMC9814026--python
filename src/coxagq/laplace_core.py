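"""Inner optimization, Gaussian approximation and the Laplace marginal.

For fixed hyperparameters theta the conditional posterior of the latent
vector W is

    pi(W | theta, y)  propto  exp{ -1/2 W' Q_theta W + l(eta(W)) },

a strictly concave objective (Q_theta is PD, l is concave), maximized by
damped Newton iterations.  A second-order expansion at the maximizer
W_hat gives the Gaussian approximation N(W_hat, H^-1) with
H = Q_theta - d^2 l, and the Tierney-Kadane Laplace approximation of the
hyperparameter posterior is

    log pi_LA(theta | y) = log pi(theta) + 1/2 log|Q_theta|
                           - 1/2 log|H| - 1/2 W_hat' Q W_hat + l(W_hat)

up to an additive constant.

The likelihood is pluggable: anything exposing
``value_grad_hessquad(eta, X) -> (l, X'g, X'H_eta X)`` works.  Besides the
Cox partial likelihood this module ships a quadratic (Gaussian) pseudo
likelihood, for which every approximation here is exact — the basis of the
package's exact-limit validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .priors import log_prior_theta

__all__ = [
    "InnerSolution",
    "GaussianPseudoLikelihood",
    "optimize_W",
    "gaussian_approx",
    "log_laplace_theta",
    "LaplaceEvaluator",
]

INNER_TOL = 1e-8
INNER_MAX_ITER = 50
MAX_HALVINGS = 30


class GaussianPseudoLikelihood:
    """l(eta) = -1/2 (eta - z)' Lambda (eta - z): the exact-limit stand-in.

    Substituted for the partial likelihood, Laplace and Gauss-Hermite steps
    incur zero approximation error, so the whole pipeline must reproduce
    conjugate closed forms.
    """

    def __init__(self, z, precision):
        self.z = np.asarray(z, dtype=float)
        self.precision = np.asarray(precision, dtype=float)
        if self.precision.ndim == 1:
            self.precision = np.diag(self.precision)

    def value(self, eta) -> float:
        r = np.asarray(eta, float) - self.z
        return float(-0.5 * r @ self.precision @ r)

    def grad_eta(self, eta) -> np.ndarray:
        return -self.precision @ (np.asarray(eta, float) - self.z)

    def value_grad_hessquad(self, eta, X):
        r = np.asarray(eta, float) - self.z
        g = -self.precision @ r
        return self.value(eta), X.T @ g, -(X.T @ self.precision @ X)


@dataclass
class InnerSolution:
    """Mode, curvature and Laplace value of pi(W | theta, y) at one theta."""

    theta: np.ndarray
    W_hat: np.ndarray
    hessian: np.ndarray          # H = Q + (-d^2 l), positive definite
    chol: tuple                  # scipy cho_factor of H (reused for sampling)
    log_laplace: float
    loglik: float
    converged: bool
    iterations: int
    grad_norm: float


def optimize_W(spec, theta, likelihood, start=None, tol: float = INNER_TOL,
               max_iter: int = INNER_MAX_ITER) -> InnerSolution:
    """Maximize -1/2 W'QW + l(eta(W)) by Newton with step halving."""
    Q = spec.assemble_Q(theta)
    X = spec.design_matrix
    W = np.zeros(spec.dim_W) if start is None else np.asarray(start, float).copy()

    def objective_parts(W):
        val, grad, hess = likelihood.value_grad_hessquad(X @ W, X)
        QW = Q @ W
        return val - 0.5 * W @ QW, grad - QW, hess

    f, g, hess_l = objective_parts(W)
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        H = Q - hess_l
        H = 0.5 * (H + H.T)
        try:
            cf = linalg.cho_factor(H)
        except linalg.LinAlgError:
            H = H + 1e-10 * np.trace(H) / H.shape[0] * np.eye(H.shape[0])
            cf = linalg.cho_factor(H)
        step = linalg.cho_solve(cf, g)
        t = 1.0
        for _ in range(MAX_HALVINGS):
            W_new = W + t * step
            f_new, g_new, hess_new = objective_parts(W_new)
            if np.isfinite(f_new) and f_new >= f - 1e-12 * abs(f):
                break
            t /= 2.0
        W, f, g, hess_l = W_new, f_new, g_new, hess_new
        if np.max(np.abs(g)) <= tol:
            converged = True
            break

    H = Q - hess_l
    H = 0.5 * (H + H.T)
    cf = linalg.cho_factor(H)
    loglik = likelihood.value(X @ W) if hasattr(likelihood, "value") else float("nan")
    log_det_H = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    theta_arr = np.atleast_1d(np.asarray(theta, dtype=float))
    lp = log_prior_theta(spec.theta_priors, theta_arr) if spec.dim_theta else 0.0
    log_laplace = (
        lp
        + 0.5 * spec.log_det_Q(theta_arr)
        - 0.5 * log_det_H
        - 0.5 * W @ Q @ W
        + loglik
    )
    return InnerSolution(
        theta=theta_arr,
        W_hat=W,
        hessian=H,
        chol=cf,
        log_laplace=float(log_laplace),
        loglik=loglik,
        converged=converged,
        iterations=it,
        grad_norm=float(np.max(np.abs(g))),
    )


def gaussian_approx(sol: InnerSolution):
    """Mean and precision of the Gaussian approximation at one theta."""
    if not sol.converged:
        raise RuntimeError(
            f"inner optimization did not converge at theta={sol.theta} "
            f"(|grad|={sol.grad_norm:.2e} after {sol.iterations} iterations)"
        )
    return sol.W_hat, sol.hessian


def log_laplace_theta(spec, theta, likelihood, start=None) -> float:
    """Unnormalized log pi_LA(theta | y) (Tierney-Kadane)."""
    return optimize_W(spec, theta, likelihood, start=start).log_laplace


class LaplaceEvaluator:
    """Caches the inner solution across theta evaluations (warm starts).

    The inner objective is strictly concave, so warm and cold starts reach
    the same optimum; warm starts just get there in fewer Newton steps.
    """

    def __init__(self, spec, likelihood):
        self.spec = spec
        self.likelihood = likelihood
        self._warm = None
        self.n_evals = 0

    def solve(self, theta) -> InnerSolution:
        sol = optimize_W(self.spec, theta, self.likelihood, start=self._warm)
        if not sol.converged:   # retry cold before giving up
            sol = optimize_W(self.spec, theta, self.likelihood, start=None)
        self._warm = sol.W_hat.copy()
        self.n_evals += 1
        return sol

    def __call__(self, theta) -> float:
        return self.solve(theta).log_laplace
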