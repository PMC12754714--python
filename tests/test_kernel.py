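"""Kernel evaluation, inducing points, Nyström decomposition, projections."""

import numpy as np
import pytest
from scipy import linalg
from sklearn.gaussian_process.kernels import Matern

from bisreg import (
    KernelSpec,
    LowRankBasis,
    SpatialDomain,
    build_projections,
    estimate_length_scale,
    gram_matrix,
    matern_correlation,
    nystrom_decompose,
    select_inducing_points,
)


def random_domain(V, d=2, seed=0):
    rng = np.random.default_rng(seed)
    return SpatialDomain.from_coords(rng.uniform(0, 1, (V, d)), normalize=False)


class TestMaternCorrelation:
    def test_zero_distance_is_one(self):
        for nu in (0.5, 1.5, 2.5, 0.8):
            assert matern_correlation(0.0, KernelSpec(length_scale=0.3, smoothness=nu)) == 1.0

    def test_exponential_special_case(self):
        # ν = 1/2 reduces to exp(−d/ρ) under the √(2ν) scaling
        spec = KernelSpec(length_scale=1.0, smoothness=0.5)
        assert matern_correlation(1.0, spec) == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_nu_three_halves_closed_form(self):
        spec = KernelSpec(length_scale=0.3, smoothness=1.5)
        u = np.sqrt(3.0) * 0.3 / 0.3
        assert matern_correlation(0.3, spec) == pytest.approx((1 + u) * np.exp(-u), abs=1e-12)

    @pytest.mark.parametrize("nu", [0.5, 1.5, 2.5, 0.8, 3.7])
    def test_matches_sklearn_matern(self, nu):
        """Independent oracle: sklearn's Matern kernel, same convention."""
        rho = 0.37
        d = np.linspace(0.01, 2.0, 50)
        ours = matern_correlation(d, KernelSpec(length_scale=rho, smoothness=nu))
        theirs = Matern(length_scale=rho, nu=nu)(np.zeros((1, 1)), d[:, None]).ravel()
        np.testing.assert_allclose(ours, theirs, atol=1e-10)

    def test_monotone_nonincreasing(self):
        spec = KernelSpec(length_scale=0.2, smoothness=1.5)
        vals = matern_correlation(np.linspace(0, 3, 200), spec)
        assert np.all(np.diff(vals) <= 1e-15)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            KernelSpec(length_scale=-1.0)
        with pytest.raises(ValueError):
            KernelSpec(length_scale=0.3, smoothness=0.0)
        with pytest.raises(ValueError):
            matern_correlation(-0.1, KernelSpec())


class TestGramMatrix:
    def test_single_point(self):
        K = gram_matrix(np.array([[0.2, 0.3]]), np.array([[0.2, 0.3]]), KernelSpec())
        np.testing.assert_allclose(K, [[1.0]])

    def test_coincident_points_rank_deficient(self):
        pts = np.zeros((2, 2))
        K = gram_matrix(pts, pts, KernelSpec())
        np.testing.assert_allclose(K, np.ones((2, 2)))

    def test_collinear_toeplitz(self):
        spec = KernelSpec(length_scale=0.5, smoothness=0.5)
        pts = np.array([[0.0], [0.1], [0.2]])
        K = gram_matrix(pts, pts, spec)
        r1 = np.exp(-0.1 / 0.5)
        r2 = np.exp(-0.2 / 0.5)
        expected = np.array([[1, r1, r2], [r1, 1, r1], [r2, r1, 1]])
        np.testing.assert_allclose(K, expected, atol=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension mismatch"):
            gram_matrix(np.zeros((3, 2)), np.zeros((3, 3)), KernelSpec())

    def test_random_small_domains_positive_definite(self):
        """Jittered Gram matrices stay factorizable across many random domains."""
        spec = KernelSpec(length_scale=0.3, jitter=1e-8)
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pts = rng.uniform(0, 1, (rng.integers(3, 15), 2))
            K = gram_matrix(pts, pts, spec, jitter_diagonal=True)
            linalg.cholesky(K)  # raises on failure


class TestInducingPoints:
    def test_full_set(self):
        d = random_domain(12)
        assert sorted(select_inducing_points(d, 12, seed=0)) == list(range(12))

    def test_single_point_near_centroid(self):
        # symmetric grid: the one k-means centroid is the domain centroid
        g = np.linspace(0, 1, 5)
        coords = np.array([(x, y) for x in g for y in g])
        d = SpatialDomain.from_coords(coords, normalize=False)
        idx = select_inducing_points(d, 1, seed=3)
        centroid = coords.mean(axis=0)
        dist = np.linalg.norm(coords[idx[0]] - centroid)
        assert dist <= np.linalg.norm(coords - centroid, axis=1).min() + 1e-9

    def test_deterministic_given_seed(self):
        d = random_domain(300, seed=5)
        a = select_inducing_points(d, 50, seed=9)
        b = select_inducing_points(d, 50, seed=9)
        np.testing.assert_array_equal(a, b)
        assert len(np.unique(a)) == 50

    def test_L_too_large(self):
        with pytest.raises(ValueError):
            select_inducing_points(random_domain(10), 11, seed=0)


class TestNystrom:
    def test_exact_at_full_rank(self):
        d = random_domain(30, seed=1)
        spec = KernelSpec(length_scale=0.3)
        Psi, lam = nystrom_decompose(d, spec, np.arange(30))
        K = gram_matrix(d.coords, d.coords, spec)
        assert np.abs(Psi @ np.diag(lam) @ Psi.T - K).max() < 1e-6

    def test_orthonormal_columns(self):
        d = random_domain(50, seed=2)
        ind = select_inducing_points(d, 10, seed=0)
        Psi, lam = nystrom_decompose(d, KernelSpec(), ind)
        np.testing.assert_allclose(Psi.T @ Psi, np.eye(lam.size), atol=1e-8)
        assert np.all(lam > 0)
        assert np.all(np.diff(lam) <= 1e-12)

    def test_near_best_rank_k_error(self):
        """Nyström error is within 10× of the optimal rank-5 truncation."""
        coords = np.linspace(0, 1, 20)[:, None]
        d = SpatialDomain.from_coords(coords, normalize=False)
        spec = KernelSpec(length_scale=0.3)
        K = gram_matrix(coords, coords, spec)
        ind = select_inducing_points(d, 5, seed=0)
        Psi, lam = nystrom_decompose(d, spec, ind)
        err = np.linalg.norm(K - Psi @ np.diag(lam) @ Psi.T, "fro")
        w, U = np.linalg.eigh(K)
        K5 = (U[:, -5:] * w[-5:]) @ U[:, -5:].T
        best = np.linalg.norm(K - K5, "fro")
        assert err <= 10 * best + 1e-12

    def test_monotone_error_in_L(self):
        d = random_domain(60, seed=3)
        spec = KernelSpec(length_scale=0.3)
        K = gram_matrix(d.coords, d.coords, spec)
        order = select_inducing_points(d, 60, seed=0, method="random")
        prev = np.inf
        for L in (5, 10, 20, 40, 60):
            Psi, lam = nystrom_decompose(d, spec, order[:L])
            err = np.linalg.norm(K - Psi @ np.diag(lam) @ Psi.T, "fro")
            assert err <= prev + 1e-8
            prev = err

    def test_invalid_inducing(self):
        d = random_domain(10)
        with pytest.raises(ValueError):
            nystrom_decompose(d, KernelSpec(), np.array([0, 0, 1]))


class TestProjections:
    def test_identity_basis(self):
        b = LowRankBasis(
            inducing_indices=np.arange(4), Psi=np.eye(4), eigenvalues=np.ones(4),
            inducing_indices_eta=np.arange(2), Psi_eta=np.eye(4)[:, :2],
            eigenvalues_eta=np.ones(2),
        )
        ops = build_projections(b)
        np.testing.assert_allclose(ops.Phi, np.eye(4))
        np.testing.assert_allclose(ops.ones_proj, np.ones(4))

    def test_nested_basis_block_structure(self):
        """If the Lη basis is the first Lη columns of the L basis,
        Φη = [diag(λη^{1/2} λ^{-1/2}) | 0]."""
        rng = np.random.default_rng(0)
        Q, _ = np.linalg.qr(rng.standard_normal((8, 4)))
        lam = np.array([4.0, 3.0, 2.0, 1.0])
        b = LowRankBasis(
            inducing_indices=np.arange(4), Psi=Q, eigenvalues=lam,
            inducing_indices_eta=np.arange(2), Psi_eta=Q[:, :2],
            eigenvalues_eta=lam[:2],
        )
        ops = build_projections(b)
        expected = np.zeros((2, 4))
        expected[0, 0] = 1.0  # sqrt(λ̃1)/sqrt(λ1)
        expected[1, 1] = 1.0
        np.testing.assert_allclose(ops.Phi_eta, expected, atol=1e-12)

    def test_whitening_identity(self):
        d = random_domain(40, seed=4)
        spec = KernelSpec(length_scale=0.3)
        b = LowRankBasis.build(d, spec, L=15, seed=0)
        ops = build_projections(b)
        K_approx = b.Psi @ np.diag(b.eigenvalues) @ b.Psi.T
        np.testing.assert_allclose(
            ops.Phi.T @ K_approx @ ops.Phi, np.eye(b.L), atol=1e-6
        )


class TestLengthScaleEstimate:
    def test_recovers_generating_scale(self):
        d = random_domain(150, d=2, seed=6)
        spec = KernelSpec(length_scale=0.3)
        K = gram_matrix(d.coords, d.coords, spec, jitter_diagonal=True)
        C = np.linalg.cholesky(K)
        rng = np.random.default_rng(8)
        Y = rng.standard_normal((400, 150)) @ C.T
        est = estimate_length_scale(Y, d, n_pairs=3000, seed=1)
        assert 0.15 <= est <= 0.6

    def test_white_noise_pins_lower_bound(self):
        d = random_domain(100, seed=7)
        Y = np.random.default_rng(9).standard_normal((200, 100))
        with pytest.warns(UserWarning, match="lower bound"):
            est = estimate_length_scale(Y, d, seed=2, bounds=(0.05, 1.0))
        assert est == 0.05

    def test_identical_images_degenerate(self):
        d = random_domain(50, seed=8)
        row = np.random.default_rng(10).standard_normal(50)
        Y = np.vstack([row, row])
        with pytest.raises(ValueError, match="constant across participants"):
            estimate_length_scale(Y, d, seed=0)
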