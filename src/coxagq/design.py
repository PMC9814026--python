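"""Design structures for the additive log-hazard predictor.

The predictor for observation ``ij`` is

    eta_ij = x_ij' beta + sum_q gamma_q(u_qij) + xi_group(ij) + gamma_s(s_ij)

with linear effects beta, penalized cubic B-spline smooths gamma_q, i.i.d.
Gaussian frailties xi and an optional Matern (nu = 1) spatial field.  The
latent vector W stacks the spline weights, beta, frailties and spatial
values — deliberately *not* the N predictors themselves, so its prior
precision Q_theta and the likelihood Hessian stay small and dense.

Smooth terms use the O'Sullivan construction: cubic B-splines on equally
spaced knots with an integrated squared second-derivative penalty, so the
penalty null space is exactly the affine functions.  The rank deficiency is
repaired by a tiny diagonal jitter, and identifiability under the partial
likelihood by a sum-to-zero constraint over the observed covariate values,
enforced on posterior samples by conditioning by kriging (see
:mod:`coxagq.posterior`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, special
from scipy.interpolate import BSpline

from .priors import PriorSpec, exponential_prior

__all__ = [
    "build_bspline_basis",
    "build_penalty",
    "matern",
    "LinearTerm",
    "SmoothTerm",
    "FrailtyTerm",
    "SpatialTerm",
    "ModelSpec",
]

# correlation at distance rho under the sqrt(8 nu)/rho practical-range
# convention: kappa*rho = sqrt(8), corr = (sqrt8) K1(sqrt8)
_SQRT8 = float(np.sqrt(8.0))
DEFAULT_JITTER_SCALE = 1e-5


# ---------------------------------------------------------------------------
# B-spline basis and penalty


def _knot_vector(lo: float, hi: float, n_knots: int) -> np.ndarray:
    """Full cubic knot vector: n_knots equally spaced knots on [lo, hi]
    with boundary knots repeated to full multiplicity; d = n_knots + 2."""
    inner = np.linspace(lo, hi, n_knots)
    return np.concatenate([[lo] * 3, inner, [hi] * 3])


def build_bspline_basis(u, n_knots: int):
    """Cubic B-spline design matrix on equally spaced knots over range(u).

    Returns ``(basis, knots)`` where ``basis`` is N x d with
    ``d = n_knots + 2`` and ``knots`` the full (clamped) knot vector.
    Rows sum to one (partition of unity).
    """
    u = np.asarray(u, dtype=float)
    if n_knots < 4:
        raise ValueError("n_knots must be at least 4")
    lo, hi = float(u.min()), float(u.max())
    if lo == hi:
        raise ValueError("covariate is constant: cannot build a spline basis")
    t = _knot_vector(lo, hi, n_knots)
    # clip to half-open support convention so u == hi gets the last spline
    x = np.clip(u, lo, np.nextafter(hi, lo))
    basis = BSpline.design_matrix(x, t, 3).toarray()
    return basis, t


def build_penalty(knots: np.ndarray) -> np.ndarray:
    """Integrated squared second-derivative penalty for a cubic basis.

    Entry (i, j) is the exact integral of phi_i'' phi_j'' over the knot
    span: the integrand is piecewise quadratic, so a 2-point Gauss-Legendre
    rule per inter-knot interval is exact.
    """
    t = np.asarray(knots, dtype=float)
    d = len(t) - 4
    uniq = np.unique(t)
    # second derivatives of all d basis functions at arbitrary points
    spl = BSpline(t, np.eye(d), 3)
    d2 = spl.derivative(2)
    P = np.zeros((d, d))
    gauss_x = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    for a, b in zip(uniq[:-1], uniq[1:]):
        half = (b - a) / 2.0
        mid = (a + b) / 2.0
        pts = mid + half * gauss_x
        vals = d2(pts)              # 2 x d
        P += half * vals.T @ vals   # equal unit weights
    return 0.5 * (P + P.T)


# ---------------------------------------------------------------------------
# Matern covariance (nu = 1, practical-range parametrization)


def matern(distance, sigma: float, rho: float):
    """Matern covariance with shape nu = 1.

    ``C(h) = sigma^2 (kappa h) K_1(kappa h)`` with ``kappa = sqrt(8)/rho``,
    so the correlation at ``h = rho`` is approximately 0.14 (the standard
    sqrt(8 nu) practical-range convention).  ``C(0) = sigma^2``.
    """
    if sigma <= 0 or rho <= 0:
        raise ValueError("sigma and rho must be positive")
    h = np.asarray(distance, dtype=float)
    if np.any(h < 0):
        raise ValueError("distances must be nonnegative")
    x = _SQRT8 * h / rho
    with np.errstate(invalid="ignore"):
        val = x * special.k1(x)
    val = np.where(x == 0.0, 1.0, val)
    out = sigma**2 * val
    return float(out) if np.isscalar(distance) else out


def _matern_dlogrho(dist: np.ndarray, sigma: float, rho: float) -> np.ndarray:
    """d C / d log(rho) for the nu=1 Matern above (analytic)."""
    x = _SQRT8 * dist / rho
    with np.errstate(invalid="ignore"):
        val = x * x * special.k0(x)
    val = np.where(x == 0.0, 0.0, val)
    return sigma**2 * val


# ---------------------------------------------------------------------------
# model terms


@dataclass
class LinearTerm:
    design: np.ndarray            # N x p
    coef_names: list
    prior_variance: float = 1000.0

    def __post_init__(self):
        self.design = np.asarray(self.design, dtype=float)
        if self.design.ndim != 2:
            raise ValueError("linear design must be 2-D")
        col_var = self.design.var(axis=0)
        if np.any(col_var == 0):
            j = int(np.argmin(col_var))
            raise ValueError(
                f"constant column {self.coef_names[j]!r} in linear design: "
                "an intercept is not identifiable under the partial likelihood"
            )

    @property
    def dim(self) -> int:
        return self.design.shape[1]


@dataclass
class SmoothTerm:
    name: str
    covariate: np.ndarray         # N values of u
    n_knots: int
    prior: PriorSpec = field(default_factory=lambda: exponential_prior(median=1.0))
    jitter: float | None = None   # default: 1e-5 * mean diag of penalty

    def __post_init__(self):
        self.covariate = np.asarray(self.covariate, dtype=float)
        self.basis, self.knots = build_bspline_basis(self.covariate, self.n_knots)
        self.penalty = build_penalty(self.knots)
        if self.jitter is None:
            self.jitter = DEFAULT_JITTER_SCALE * float(np.mean(np.diag(self.penalty)))
        # eigendecomposition reused for fast log|Q| and trace terms
        self._evals, self._evecs = np.linalg.eigh(self.penalty)
        self._evals = np.clip(self._evals, 0.0, None)
        # sum-to-zero constraint row over observed values: column sums
        self.constraint = self.basis.sum(axis=0)

    @property
    def dim(self) -> int:
        return self.basis.shape[1]

    def evaluate(self, coef: np.ndarray, u=None) -> np.ndarray:
        """gamma(u) for given spline weights (defaults to observed u)."""
        if u is None:
            return self.basis @ coef
        x = np.clip(np.asarray(u, float), self.knots[0],
                    np.nextafter(self.knots[-1], self.knots[0]))
        return BSpline.design_matrix(x, self.knots, 3).toarray() @ coef


@dataclass
class FrailtyTerm:
    group_codes: np.ndarray       # N -> 0..n-1
    n_groups: int
    prior: PriorSpec = field(default_factory=lambda: exponential_prior(median=1.0))

    def __post_init__(self):
        present = np.unique(self.group_codes)
        if len(present) != self.n_groups or present.min() != 0:
            raise ValueError("every group index 0..n-1 must appear")

    @property
    def dim(self) -> int:
        return self.n_groups


@dataclass
class SpatialTerm:
    coords: np.ndarray            # N x 2 observation coordinates
    prior_sigma: PriorSpec = field(
        default_factory=lambda: exponential_prior(median=1.0, transformation="log_sigma"))
    prior_range: PriorSpec = field(
        default_factory=lambda: exponential_prior(median=20.0, transformation="log_range"))
    nu: float = 1.0

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords must be N x 2")
        uniq, inverse = np.unique(coords, axis=0, return_inverse=True)
        self.unique_locations = uniq
        self.incidence = inverse.ravel()
        diff = uniq[:, None, :] - uniq[None, :, :]
        self.distance_matrix = np.sqrt((diff**2).sum(axis=-1))

    @property
    def dim(self) -> int:
        return len(self.unique_locations)

    def covariance(self, sigma: float, rho: float) -> np.ndarray:
        return matern(self.distance_matrix, sigma, rho)


# ---------------------------------------------------------------------------
# full model specification


@dataclass
class ModelSpec:
    """Terms of the additive predictor plus the theta and latent layouts.

    Latent block order: smooths (in declaration order), then beta, then
    frailties, then spatial values.  Theta order: frailty first (if any),
    then one coordinate per smooth, then (log sigma, log rho) for the
    spatial term — matching the theta_0, theta_1, ... convention.
    """

    linear: LinearTerm | None = None
    smooths: list = field(default_factory=list)
    frailty: FrailtyTerm | None = None
    spatial: SpatialTerm | None = None

    def __post_init__(self):
        ns = [t.covariate.shape[0] if isinstance(t, SmoothTerm) else None
              for t in self.smooths]
        sizes = [s for s in ns if s is not None]
        if self.linear is not None:
            sizes.append(self.linear.design.shape[0])
        if self.frailty is not None:
            sizes.append(len(self.frailty.group_codes))
        if self.spatial is not None:
            sizes.append(len(self.spatial.incidence))
        if not sizes:
            raise ValueError("model has no terms")
        if len(set(sizes)) != 1:
            raise ValueError(f"terms disagree on N: {sorted(set(sizes))}")
        self.n_obs = sizes[0]
        self._build_layout()
        self._X = None

    def _build_layout(self):
        blocks = []
        start = 0
        names: list[str] = []
        for sm in self.smooths:
            blocks.append((f"smooth:{sm.name}", slice(start, start + sm.dim)))
            names += [f"{sm.name}[{j}]" for j in range(sm.dim)]
            start += sm.dim
        if self.linear is not None:
            blocks.append(("beta", slice(start, start + self.linear.dim)))
            names += list(self.linear.coef_names)
            start += self.linear.dim
        if self.frailty is not None:
            blocks.append(("frailty", slice(start, start + self.frailty.dim)))
            names += [f"xi[{i}]" for i in range(self.frailty.dim)]
            start += self.frailty.dim
        if self.spatial is not None:
            blocks.append(("spatial", slice(start, start + self.spatial.dim)))
            names += [f"spatial[{i}]" for i in range(self.spatial.dim)]
            start += self.spatial.dim
        self.latent_layout = blocks
        self.latent_names = names
        self.dim_W = start
        # theta layout
        th = []
        if self.frailty is not None:
            th.append(("frailty_sd", self.frailty.prior))
        for sm in self.smooths:
            th.append((f"smooth_sd:{sm.name}", sm.prior))
        if self.spatial is not None:
            th.append(("spatial_sd", self.spatial.prior_sigma))
            th.append(("spatial_range", self.spatial.prior_range))
        self.theta_names = [n for n, _ in th]
        self.theta_priors = [p for _, p in th]
        self.dim_theta = len(th)

    def block(self, name: str) -> slice:
        for n, sl in self.latent_layout:
            if n == name:
                return sl
        raise KeyError(name)

    # -- design map W -> eta ------------------------------------------------

    @property
    def design_matrix(self) -> np.ndarray:
        """Dense N x dim(W) matrix X with eta = X W."""
        if self._X is None:
            cols = []
            for sm in self.smooths:
                cols.append(sm.basis)
            if self.linear is not None:
                cols.append(self.linear.design)
            if self.frailty is not None:
                Z = np.zeros((self.n_obs, self.frailty.dim))
                Z[np.arange(self.n_obs), self.frailty.group_codes] = 1.0
                cols.append(Z)
            if self.spatial is not None:
                S = np.zeros((self.n_obs, self.spatial.dim))
                S[np.arange(self.n_obs), self.spatial.incidence] = 1.0
                cols.append(S)
            self._X = np.hstack(cols)
        return self._X

    def eta_from_W(self, W: np.ndarray) -> np.ndarray:
        W = np.asarray(W, dtype=float)
        if W.shape[-1] != self.dim_W:
            raise ValueError(f"W has dimension {W.shape[-1]}, expected {self.dim_W}")
        return W @ self.design_matrix.T

    # -- prior precision of W ----------------------------------------------

    def _split_theta(self, theta):
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        if theta.size != self.dim_theta:
            raise ValueError(
                f"theta has length {theta.size}, expected {self.dim_theta}")
        if not np.all(np.isfinite(theta)):
            raise ValueError("non-finite theta")
        out = {}
        k = 0
        if self.frailty is not None:
            out["frailty"] = theta[k]; k += 1
        for sm in self.smooths:
            out[f"smooth:{sm.name}"] = theta[k]; k += 1
        if self.spatial is not None:
            out["spatial"] = (theta[k], theta[k + 1]); k += 2
        return out

    def assemble_Q(self, theta) -> np.ndarray:
        """Block-diagonal prior precision Q_theta of W (symmetric PD)."""
        parts = self._split_theta(theta)
        Q = np.zeros((self.dim_W, self.dim_W))
        for sm in self.smooths:
            sl = self.block(f"smooth:{sm.name}")
            th = parts[f"smooth:{sm.name}"]
            Q[sl, sl] = np.exp(th) * sm.penalty + sm.jitter * np.eye(sm.dim)
        if self.linear is not None:
            sl = self.block("beta")
            Q[sl, sl] = np.eye(self.linear.dim) / self.linear.prior_variance
        if self.frailty is not None:
            sl = self.block("frailty")
            Q[sl, sl] = np.exp(parts["frailty"]) * np.eye(self.frailty.dim)
        if self.spatial is not None:
            sl = self.block("spatial")
            ls, lr = parts["spatial"]
            C = self.spatial.covariance(np.exp(ls), np.exp(lr))
            try:
                cf = linalg.cho_factor(C)
            except linalg.LinAlgError as exc:
                raise linalg.LinAlgError(
                    f"spatial covariance not positive definite at theta={theta}"
                ) from exc
            Q[sl, sl] = linalg.cho_solve(cf, np.eye(self.spatial.dim))
        return Q

    def log_det_Q(self, theta) -> float:
        """log |Q_theta| via per-block closed forms / factorizations."""
        parts = self._split_theta(theta)
        total = 0.0
        for sm in self.smooths:
            th = parts[f"smooth:{sm.name}"]
            total += float(np.sum(np.log(np.exp(th) * sm._evals + sm.jitter)))
        if self.linear is not None:
            total += -self.linear.dim * np.log(self.linear.prior_variance)
        if self.frailty is not None:
            total += self.frailty.dim * parts["frailty"]
        if self.spatial is not None:
            ls, lr = parts["spatial"]
            C = self.spatial.covariance(np.exp(ls), np.exp(lr))
            cf = linalg.cho_factor(C)
            total += -2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        return total

    # -- non-centered scale roots (used by the MCMC oracle) -----------------

    def scale_W(self, theta, V) -> np.ndarray:
        """W = T_theta V with T_theta a symmetric/triangular root of Q^-1.

        Blockwise: beta sqrt(prior variance); frailty e^{-theta/2};
        smooth U diag((e^theta lam_i + jitter)^{-1/2}) U'; spatial the
        Cholesky factor of the Matern covariance.
        """
        parts = self._split_theta(theta)
        V = np.asarray(V, dtype=float)
        W = np.empty_like(V)
        for sm in self.smooths:
            sl = self.block(f"smooth:{sm.name}")
            s = 1.0 / np.sqrt(np.exp(parts[f"smooth:{sm.name}"]) * sm._evals
                              + sm.jitter)
            W[sl] = sm._evecs @ (s * (sm._evecs.T @ V[sl]))
        if self.linear is not None:
            sl = self.block("beta")
            W[sl] = np.sqrt(self.linear.prior_variance) * V[sl]
        if self.frailty is not None:
            sl = self.block("frailty")
            W[sl] = np.exp(-parts["frailty"] / 2.0) * V[sl]
        if self.spatial is not None:
            sl = self.block("spatial")
            ls, lr = parts["spatial"]
            C = self.spatial.covariance(np.exp(ls), np.exp(lr))
            L = np.linalg.cholesky(C)
            W[sl] = L @ V[sl]
        return W

    def scale_rmatvec(self, theta, g) -> np.ndarray:
        """T_theta' g (adjoint of :meth:`scale_W` in V)."""
        parts = self._split_theta(theta)
        g = np.asarray(g, dtype=float)
        out = np.empty_like(g)
        for sm in self.smooths:
            sl = self.block(f"smooth:{sm.name}")
            s = 1.0 / np.sqrt(np.exp(parts[f"smooth:{sm.name}"]) * sm._evals
                              + sm.jitter)
            out[sl] = sm._evecs @ (s * (sm._evecs.T @ g[sl]))
        if self.linear is not None:
            sl = self.block("beta")
            out[sl] = np.sqrt(self.linear.prior_variance) * g[sl]
        if self.frailty is not None:
            sl = self.block("frailty")
            out[sl] = np.exp(-parts["frailty"] / 2.0) * g[sl]
        if self.spatial is not None:
            sl = self.block("spatial")
            ls, lr = parts["spatial"]
            C = self.spatial.covariance(np.exp(ls), np.exp(lr))
            L = np.linalg.cholesky(C)
            out[sl] = L.T @ g[sl]
        return out

    def scale_grad_theta(self, theta, V, grad_W) -> np.ndarray:
        """Per-theta-coordinate grad_W' (dT_theta/dtheta V).

        Analytic for every block; the spatial Cholesky derivative uses
        dL = L Phi(L^-1 dC L^-T) with Phi the lower-half operator.
        """
        parts = self._split_theta(theta)
        V = np.asarray(V, dtype=float)
        grad_W = np.asarray(grad_W, dtype=float)
        g = np.zeros(self.dim_theta)
        k = 0
        if self.frailty is not None:
            sl = self.block("frailty")
            th = parts["frailty"]
            g[k] = grad_W[sl] @ (-0.5 * np.exp(-th / 2.0) * V[sl])
            k += 1
        for sm in self.smooths:
            sl = self.block(f"smooth:{sm.name}")
            th = parts[f"smooth:{sm.name}"]
            lam = np.exp(th) * sm._evals
            s = 1.0 / np.sqrt(lam + sm.jitter)
            ds = -0.5 * lam * s**3
            g[k] = grad_W[sl] @ (sm._evecs @ (ds * (sm._evecs.T @ V[sl])))
            k += 1
        if self.spatial is not None:
            sl = self.block("spatial")
            ls, lr = parts["spatial"]
            sig, rho = np.exp(ls), np.exp(lr)
            C = self.spatial.covariance(sig, rho)
            L = np.linalg.cholesky(C)
            # d/dlog sigma: C ~ sigma^2 => L ~ sigma => dL = L
            g[k] = grad_W[sl] @ (L @ V[sl])
            dC = _matern_dlogrho(self.spatial.distance_matrix, sig, rho)
            M = linalg.solve_triangular(L, dC, lower=True)
            M = linalg.solve_triangular(L, M.T, lower=True)
            Phi = np.tril(M)
            np.fill_diagonal(Phi, 0.5 * np.diag(M))
            dL = L @ Phi
            g[k + 1] = grad_W[sl] @ (dL @ V[sl])
            k += 2
        return g

    def quad_form_grad_theta(self, theta, W) -> np.ndarray:
        """Per-theta-coordinate d/dtheta of [ 1/2 log|Q| - 1/2 W'QW ].

        Used by the MCMC oracle; analytic for every block type.
        """
        parts = self._split_theta(theta)
        W = np.asarray(W, dtype=float)
        g = np.zeros(self.dim_theta)
        k = 0
        if self.frailty is not None:
            th = parts["frailty"]
            xi = W[self.block("frailty")]
            g[k] = 0.5 * self.frailty.dim - 0.5 * np.exp(th) * xi @ xi
            k += 1
        for sm in self.smooths:
            th = parts[f"smooth:{sm.name}"]
            coef = W[self.block(f"smooth:{sm.name}")]
            lam = np.exp(th) * sm._evals
            g[k] = 0.5 * float(np.sum(lam / (lam + sm.jitter)))
            g[k] -= 0.5 * np.exp(th) * coef @ sm.penalty @ coef
            k += 1
        if self.spatial is not None:
            ls, lr = parts["spatial"]
            sig, rho = np.exp(ls), np.exp(lr)
            sl = self.block("spatial")
            w = W[sl]
            C = self.spatial.covariance(sig, rho)
            cf = linalg.cho_factor(C)
            Cinv_w = linalg.cho_solve(cf, w)
            for j, dC in enumerate((2.0 * C,
                                    _matern_dlogrho(self.spatial.distance_matrix, sig, rho))):
                # d/dth [1/2 log|Q|] = -1/2 tr(C^-1 dC); d/dth [-1/2 w'C^-1 w]
                # = +1/2 w'C^-1 dC C^-1 w
                tr = float(np.trace(linalg.cho_solve(cf, dC)))
                g[k + j] = -0.5 * tr + 0.5 * Cinv_w @ dC @ Cinv_w
            k += 2
        return g
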