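"""Whitening, the ARD objective and the reweighted adaptive-lasso solver."""

import numpy as np
import pytest

from pathbayes.hier_model import HyperParams, MarginalModel
from pathbayes.snal import (
    WhitenedProblem,
    ard_objective,
    selection_scores,
    snal_fit,
    snal_path,
    whiten,
)


def _orthonormal_problem(rng, n=60, m=6, lam=1.0, scale=2.0):
    Q, _ = np.linalg.qr(rng.standard_normal((n, m)))
    y = scale * rng.standard_normal(n)
    return WhitenedProblem(y, Q, lam)


class TestWhiten:
    def test_zero_snp_prior_is_identity_map(self, rng):
        G = rng.integers(0, 3, size=(10, 8)).astype(float)
        P = (rng.random((8, 3)) < 0.5).astype(float)
        m = MarginalModel(rng.standard_normal(10), G, P, HyperParams(a=1e-15, b=1.0))
        p = whiten(m, lam=1.0)
        np.testing.assert_allclose(p.y_tilde, m.y, atol=1e-6)
        np.testing.assert_allclose(p.X_tilde, m.X, atol=1e-5)

    def test_factorization_identity(self, rng):
        G = rng.integers(0, 3, size=(10, 8)).astype(float)
        a = 0.3
        V = np.eye(10) + a * ((G - G.mean(0)) @ (G - G.mean(0)).T)
        R = np.linalg.cholesky(V)
        recon = np.linalg.solve(R, np.linalg.solve(R, V).T)
        np.testing.assert_allclose(recon, np.eye(10), atol=1e-10)

    def test_whitened_residual_covariance_is_spherical(self, rng):
        """Monte Carlo: cov(y~ - X~ beta) proportional to I under the model."""
        from pathbayes.hier_model import CenteringPolicy

        n, l = 12, 30
        G = rng.integers(0, 3, size=(n, l)).astype(float)
        G -= G.mean(axis=0)
        P = (rng.random((l, 2)) < 0.5).astype(float)
        a, sigma = 0.05, 1.0
        beta = np.array([0.3, -0.2])
        hp = HyperParams(a=a, b=1.0)
        off_policy = CenteringPolicy(center_y=False, center_G=False)
        X = G @ P
        reps = 10_000
        resid = np.empty((reps, n))
        R = Xt = None
        for r in range(reps):
            u = np.sqrt(a) * sigma * rng.standard_normal(l)
            y = X @ beta + G @ u + sigma * rng.standard_normal(n)
            if r == 0:
                # first replicate goes through whiten() itself ...
                p = whiten(MarginalModel(y, G, P, hp, off_policy), lam=1.0)
                V = np.eye(n) + a * (G @ G.T)
                R = np.linalg.cholesky(V)
                Xt = np.linalg.solve(R, X)
                np.testing.assert_allclose(p.X_tilde, Xt, atol=1e-10)
                np.testing.assert_allclose(p.y_tilde, np.linalg.solve(R, y), atol=1e-10)
            # ... later ones reuse the fixed whitening transform directly
            resid[r] = np.linalg.solve(R, y) - Xt @ beta
        cov = np.cov(resid.T)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 0.1
        assert np.allclose(np.diag(cov), sigma ** 2, atol=0.1)


class TestARDObjective:
    def test_zero_gamma_closed_form(self, rng):
        p = _orthonormal_problem(rng, lam=0.7)
        n = p.y_tilde.size
        expected = n * np.log(0.7) + (p.y_tilde @ p.y_tilde) / 0.7
        assert ard_objective(p, np.zeros(6)) == pytest.approx(expected, abs=1e-10)

    def test_single_predictor_determinant_lemma(self, rng):
        n, lam, g = 30, 0.5, 1.7
        x = rng.standard_normal(n)
        x /= np.linalg.norm(x)
        y = rng.standard_normal(n)
        p = WhitenedProblem(y, x[:, None], lam)
        z = float(x @ y)
        expected = (
            (n - 1) * np.log(lam)
            + np.log(lam + g)
            + ((y @ y) - z ** 2) / lam
            + z ** 2 / (lam + g)
        )
        assert ard_objective(p, np.array([g])) == pytest.approx(expected, abs=1e-10)

    def test_matches_dense_inverse_evaluation(self, rng):
        n, m, lam = 15, 8, 0.9
        X = rng.standard_normal((n, m))
        y = rng.standard_normal(n)
        gamma = np.abs(rng.standard_normal(m)) * (rng.random(m) < 0.6)
        p = WhitenedProblem(y, X, lam)
        Sigma = lam * np.eye(n) + X @ np.diag(gamma) @ X.T
        expected = np.log(np.linalg.det(Sigma)) + y @ np.linalg.inv(Sigma) @ y
        assert ard_objective(p, gamma) == pytest.approx(expected, abs=1e-10)

    def test_negative_gamma_rejected(self, rng):
        p = _orthonormal_problem(rng)
        with pytest.raises(ValueError):
            ard_objective(p, -np.ones(6))


class TestSnalFit:
    def test_orthonormal_closed_form(self, rng):
        """On an orthonormal design the type-II ML minimizer is
        gamma_j = max(0, z_j^2 - lam) with z_j = x_j' y~."""
        p = _orthonormal_problem(rng, lam=1.0)
        fit = snal_fit(p, tol=1e-9)
        z = p.X_tilde.T @ p.y_tilde
        np.testing.assert_allclose(fit.gamma, np.maximum(0.0, z ** 2 - 1.0), atol=1e-6)

    def test_large_lam_empties_the_selection(self, rng):
        p = _orthonormal_problem(rng, lam=1.0)
        z = p.X_tilde.T @ p.y_tilde
        big = float(np.max(z ** 2)) * 1.01
        fit = snal_fit(p.with_lam(big))
        assert fit.selected.size == 0
        np.testing.assert_allclose(fit.gamma, 0.0)

    def test_zero_response_is_immediately_sparse(self, rng):
        p = WhitenedProblem(np.zeros(20), rng.standard_normal((20, 5)), 1.0)
        fit = snal_fit(p)
        assert fit.converged and fit.n_iter == 1
        np.testing.assert_allclose(fit.gamma, 0.0)
        np.testing.assert_allclose(fit.beta_hat, 0.0)

    def test_objective_trace_non_increasing_on_random_instances(self, rng):
        """Each reweighting step minimizes a majorizer of the type-II ML
        objective, so the trace must never increase."""
        for _ in range(100):
            n, m = int(rng.integers(10, 40)), int(rng.integers(2, 12))
            X = rng.standard_normal((n, m)) * rng.uniform(0.5, 3)
            y = rng.standard_normal(n) * rng.uniform(0.5, 3)
            lam = float(rng.uniform(0.05, 5))
            fit = snal_fit(WhitenedProblem(y, X, lam))
            assert np.all(np.diff(fit.objective_trace) <= 1e-8)

    def test_homogeneity_of_single_predictor_solution(self, rng):
        n = 50
        x = rng.standard_normal(n)
        x /= np.linalg.norm(x)
        y = 3.0 * rng.standard_normal(n)
        lam, c = 0.8, 2.0
        g1 = snal_fit(WhitenedProblem(y, x[:, None], lam), tol=1e-10).gamma[0]
        g2 = snal_fit(WhitenedProblem(c * y, x[:, None], c ** 2 * lam), tol=1e-10).gamma[0]
        assert g2 == pytest.approx(c ** 2 * g1, rel=1e-4)


class TestSnalPath:
    def test_selection_shrinks_as_lam_grows_on_orthonormal_design(self, rng):
        p = _orthonormal_problem(rng, n=80, m=8, scale=3.0)
        z = p.X_tilde.T @ p.y_tilde
        lam_grid = np.sort(rng.uniform(0.1, np.max(z ** 2) * 1.2, size=12))
        fits = snal_path(p, lam_grid)
        sizes = [f.selected.size for f in fits]
        assert all(s1 >= s2 for s1, s2 in zip(sizes, sizes[1:]))
        for lam, f in zip(lam_grid, fits):
            expected = set(np.flatnonzero(z ** 2 > lam))
            assert set(f.selected) == expected

    def test_single_value_grid_equals_plain_fit(self, rng):
        p = _orthonormal_problem(rng, lam=1.0)
        (fit,) = snal_path(p, np.array([0.6]))
        ref = snal_fit(p.with_lam(0.6))
        np.testing.assert_allclose(fit.gamma, ref.gamma, atol=1e-8)

    def test_warm_and_cold_starts_agree(self, rng):
        X = rng.standard_normal((50, 20))
        y = X[:, :3] @ np.array([1.0, -0.8, 0.5]) + rng.standard_normal(50)
        p = WhitenedProblem(y, X, 1.0)
        lam_grid = np.logspace(-2, 1, 10)
        warm = snal_path(p, lam_grid, warm_start=True)
        cold = snal_path(p, lam_grid, warm_start=False)
        for w, c in zip(warm, cold):
            assert set(w.selected) == set(c.selected)
            np.testing.assert_allclose(w.gamma, c.gamma, atol=1e-4)

    def test_selection_scores_are_the_largest_surviving_lam(self, rng):
        p = _orthonormal_problem(rng, n=80, m=8, scale=3.0)
        z = p.X_tilde.T @ p.y_tilde
        lam_grid = np.linspace(0.2, np.max(z ** 2) * 1.1, 15)
        fits = snal_path(p, lam_grid)
        scores = selection_scores(fits, lam_grid, 8)
        for j in range(8):
            surviving = lam_grid[lam_grid < z[j] ** 2]
            expected = surviving.max() if surviving.size else 0.0
            assert scores[j] == pytest.approx(expected)

    def test_unsorted_grid_rejected(self, rng):
        p = _orthonormal_problem(rng)
        with pytest.raises(ValueError):
            snal_path(p, np.array([1.0, 0.5]))
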