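"""Spline basis/penalty, Matern covariance, precision assembly, predictor."""

import numpy as np
import pytest
from scipy import integrate, interpolate

from coxagq.design import (
    FrailtyTerm, LinearTerm, ModelSpec, SmoothTerm, SpatialTerm,
    build_bspline_basis, build_penalty, matern,
)
from coxagq.priors import exponential_prior


def cox_de_boor(t, j, k, x):
    """Independent textbook B-spline recursion (oracle)."""
    if k == 0:
        # half-open intervals; last basis takes the right endpoint
        return 1.0 if t[j] <= x < t[j + 1] else 0.0
    left = 0.0
    if t[j + k] > t[j]:
        left = (x - t[j]) / (t[j + k] - t[j]) * cox_de_boor(t, j, k - 1, x)
    right = 0.0
    if t[j + k + 1] > t[j + 1]:
        right = (t[j + k + 1] - x) / (t[j + k + 1] - t[j + 1]) * \
            cox_de_boor(t, j + 1, k - 1, x)
    return left + right


class TestBasis:
    def test_dimension_convention(self):
        u = np.linspace(0, 1, 30)
        B, _ = build_bspline_basis(u, 50)
        assert B.shape == (30, 52)
        B, _ = build_bspline_basis(u, 4)
        assert B.shape == (30, 6)

    def test_partition_of_unity(self, rng):
        u = rng.uniform(-3, 7, 200)
        B, _ = build_bspline_basis(u, 17)
        assert np.max(np.abs(B.sum(axis=1) - 1.0)) < 1e-12

    def test_matches_cox_de_boor_recursion(self):
        u = np.array([0.0, 0.37, 0.5, 0.81, 1.0])
        B, t = build_bspline_basis(u, 4)
        for i, x in enumerate(u):
            xx = min(x, np.nextafter(t[-1], 0.0))
            expected = [cox_de_boor(t, j, 3, xx) for j in range(B.shape[1])]
            np.testing.assert_allclose(B[i], expected, atol=1e-12)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            build_bspline_basis(np.ones(10), 8)


@pytest.fixture(scope="module")
def basis():
    u = np.linspace(-2.0, 3.0, 40)
    B, t = build_bspline_basis(u, 7)
    return B, t, build_penalty(t)


class TestPenalty:

    def test_annihilates_constants(self, basis):
        _, _, P = basis
        assert np.max(np.abs(P @ np.ones(P.shape[0]))) < 1e-10

    def test_annihilates_affine(self, basis):
        _, t, P = basis
        d = P.shape[0]
        # Greville abscissae: coefficients representing the identity function
        grev = np.array([t[j + 1:j + 4].mean() for j in range(d)])
        assert np.max(np.abs(P @ grev)) < 1e-9

    def test_rank_deficiency_is_two(self, basis):
        _, _, P = basis
        evals = np.linalg.eigvalsh(P)
        assert np.sum(evals < 1e-8 * evals.max()) == 2

    def test_matches_adaptive_quadrature(self, basis):
        _, t, P = basis
        d = P.shape[0]
        spl = interpolate.BSpline(t, np.eye(d), 3).derivative(2)
        for i, j in [(0, 0), (2, 5), (4, 4), (d - 1, d - 3)]:
            val, _ = integrate.quad(
                lambda x: spl(x)[i] * spl(x)[j], t[0], t[-1],
                points=np.unique(t), limit=200)
            assert P[i, j] == pytest.approx(val, abs=1e-8)


class TestMatern:
    def test_variance_at_zero_lag(self):
        assert matern(0.0, 2.0, 5.0) == pytest.approx(4.0)

    def test_practical_range_correlation(self):
        # closed form at h = rho: sqrt(8) K1(sqrt(8))
        from scipy.special import k1
        x = np.sqrt(8.0)
        assert matern(5.0, 1.0, 5.0) == pytest.approx(x * k1(x))
        assert matern(5.0, 1.0, 5.0) == pytest.approx(0.1397, abs=2e-4)

    def test_strictly_decreasing(self):
        h = np.linspace(0, 20, 100)
        v = matern(h, 1.3, 4.0)
        assert np.all(np.diff(v) < 0)

    def test_covariance_matrix_spd(self, rng):
        pts = rng.uniform(0, 10, size=(5, 2))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        C = matern(D, 1.0, 3.0)
        assert np.allclose(C, C.T)
        assert np.linalg.eigvalsh(C).min() > 0

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            matern(1.0, -1.0, 2.0)
        with pytest.raises(ValueError):
            matern(1.0, 1.0, 0.0)


def _toy_spec(rng, n=30):
    u = rng.uniform(0, 1, n)
    groups = rng.integers(0, 4, n)
    groups[:4] = [0, 1, 2, 3]
    coords = rng.uniform(0, 5, size=(n, 2))
    return ModelSpec(
        linear=LinearTerm(rng.normal(size=(n, 2)), ["a", "b"]),
        smooths=[SmoothTerm("u", u, n_knots=6)],
        frailty=FrailtyTerm(groups, 4),
        spatial=SpatialTerm(coords),
    )


class TestModelSpec:
    def test_latent_dimension(self, rng):
        spec = _toy_spec(rng)
        n_loc = spec.spatial.dim
        assert spec.dim_W == 8 + 2 + 4 + n_loc
        assert spec.dim_theta == 4  # frailty, smooth, spatial sd, spatial range

    def test_frailty_identity_precision_at_unit_sd(self):
        groups = np.array([0, 0, 1, 1, 2])
        spec = ModelSpec(frailty=FrailtyTerm(groups, 3))
        Q = spec.assemble_Q([-2.0 * np.log(1.0)])
        np.testing.assert_allclose(Q, np.eye(3))

    def test_smooth_precision_floor_is_jitter(self, rng):
        sm = SmoothTerm("u", rng.uniform(0, 1, 25), n_knots=6)
        spec = ModelSpec(smooths=[sm])
        Q = spec.assemble_Q([0.3])
        assert np.linalg.eigvalsh(Q).min() >= 0.99 * sm.jitter

    def test_spatial_precision_inverts_covariance(self, rng):
        coords = rng.uniform(0, 3, size=(6, 2))
        spec = ModelSpec(spatial=SpatialTerm(coords))
        theta = [np.log(1.2), np.log(2.0)]
        Q = spec.assemble_Q([0.0, 0.0, *theta][2:])  # only spatial coords
        C = spec.spatial.covariance(1.2, 2.0)
        np.testing.assert_allclose(Q @ C, np.eye(6), atol=1e-8)

    def test_Q_positive_definite_random_theta(self, rng):
        spec = _toy_spec(rng)
        for _ in range(5):
            th = rng.uniform(-3, 3, spec.dim_theta)
            assert np.linalg.eigvalsh(spec.assemble_Q(th)).min() > 0

    def test_log_det_matches_slogdet(self, rng):
        spec = _toy_spec(rng)
        th = rng.uniform(-1, 1, spec.dim_theta)
        sign, ld = np.linalg.slogdet(spec.assemble_Q(th))
        assert sign > 0
        assert spec.log_det_Q(th) == pytest.approx(ld, rel=1e-8)

    def test_eta_linear_and_matches_bruteforce(self, rng):
        spec = _toy_spec(rng)
        W1, W2 = rng.normal(size=(2, spec.dim_W))
        np.testing.assert_allclose(
            spec.eta_from_W(2.0 * W1 - 0.5 * W2),
            2.0 * spec.eta_from_W(W1) - 0.5 * spec.eta_from_W(W2), atol=1e-12)
        # brute-force loop evaluation
        eta = spec.eta_from_W(W1)
        X = spec.design_matrix
        for i in range(5):
            assert eta[i] == pytest.approx(sum(X[i, j] * W1[j]
                                               for j in range(spec.dim_W)))

    def test_frailty_indicator_mapping(self):
        spec = ModelSpec(frailty=FrailtyTerm(np.array([0, 0, 1]), 2))
        np.testing.assert_allclose(spec.eta_from_W([3.0, -2.0]), [3.0, 3.0, -2.0])
        np.testing.assert_allclose(spec.eta_from_W([0.0, 0.0]), 0.0)

    def test_intercept_column_rejected(self, rng):
        with pytest.raises(ValueError, match="intercept|constant"):
            LinearTerm(np.ones((10, 1)), ["one"])

    def test_constraint_projection_shifts_fit_by_constant(self, rng):
        # Conditioning a posterior draw on the sum-to-zero constraint only
        # relocates the fitted curve: the likelihood identifies every
        # direction except the constant, whose prior precision is the jitter
        # floor, so the kriging correction direction is (to O(jitter))
        # the constant function.
        sm = SmoothTerm("u", rng.uniform(0, 1, 40), n_knots=8)
        spec = ModelSpec(smooths=[sm])
        Q = spec.assemble_Q([0.0])
        B = sm.basis
        # any curvature that is shift-invariant in eta (like the partial
        # likelihood's): centred projection scaled by a PD weight
        Lam = np.eye(40) - np.ones((40, 40)) / 40
        H = Q + B.T @ Lam @ B
        Sigma = np.linalg.inv(H)
        A = sm.constraint
        g = rng.normal(size=sm.dim)
        corr = Sigma @ A * (A @ g) / (A @ Sigma @ A)
        shift = B @ corr
        spread = shift.max() - shift.min()
        # deviation from constancy is O(jitter / next-smallest eigenvalue)
        assert spread < 1e-2 * max(1.0, np.abs(shift).max())
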