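"""Gaussian/AR layer: fitting, Lyapunov, closed-form measures, oracles."""

import numpy as np
import pytest

from phitax import (
    Bipartition,
    GaussianSystem,
    ar_random,
    fit_ar,
    gaussian_kl,
    gaussian_mi,
    lyapunov_stationary,
    phi_gaussian,
)
from phitax.gaussian import GAUSSIAN_CODES, INFINITE_CODES, phi_M_tform


def stable_system(rng, n=4, rho=0.8):
    A = rng.standard_normal((n, n))
    A *= rho / np.abs(np.linalg.eigvals(A)).max()
    Sigma = rng.standard_normal((n, n))
    Sigma = Sigma @ Sigma.T / n + 0.5 * np.eye(n)
    return GaussianSystem.from_dynamics(A, Sigma), A, Sigma


def separable_system(rng, h=2):
    A = np.zeros((2 * h, 2 * h))
    A[:h, :h] = 0.4 * rng.standard_normal((h, h)) / h**0.5
    A[h:, h:] = 0.4 * rng.standard_normal((h, h)) / h**0.5
    return GaussianSystem.from_dynamics(A, np.eye(2 * h))


HALF_CUT = Bipartition((0, 1), (2, 3))


class TestLyapunov:
    def test_zero_dynamics_gives_noise_covariance(self):
        S = np.diag([1.0, 2.0, 3.0])
        np.testing.assert_allclose(lyapunov_stationary(np.zeros((3, 3)), S), S)

    def test_scalar_closed_form(self):
        c = lyapunov_stationary(np.array([[0.5]]), np.array([[1.0]]))
        assert c[0, 0] == pytest.approx(4 / 3, abs=1e-12)

    def test_random_stable_matches_fixed_point_iteration(self, rng):
        _, A, Sigma = stable_system(rng)
        C = lyapunov_stationary(A, Sigma)
        np.testing.assert_allclose(C, A @ C @ A.T + Sigma, atol=1e-10)
        # independent fixed-point oracle
        X = Sigma.copy()
        for _ in range(2000):
            X = A @ X @ A.T + Sigma
        np.testing.assert_allclose(C, X, atol=1e-9)

    def test_unstable_dynamics_rejected(self):
        with pytest.raises(ValueError, match="spectral radius"):
            lyapunov_stationary(np.array([[1.01]]), np.array([[1.0]]))


class TestFitAR:
    def test_parameter_recovery_improves_with_length(self, rng):
        _, A, Sigma = stable_system(rng, n=3)
        C = lyapunov_stationary(A, Sigma)
        L = np.linalg.cholesky(Sigma)
        errs = []
        for T in (2_000, 50_000):
            x = np.linalg.cholesky(C) @ rng.standard_normal(3)
            X = np.empty((T, 3))
            for t in range(T):
                X[t] = x
                x = A @ x + L @ rng.standard_normal(3)
            g = fit_ar(X)
            errs.append(np.abs(g.A - A).max())
        assert errs[1] < errs[0]
        assert errs[1] < 0.05

    def test_white_noise_gives_zero_dynamics(self, rng):
        X = rng.standard_normal((20_000, 3))
        g = fit_ar(X)
        assert np.abs(g.A).max() < 0.05
        np.testing.assert_allclose(g.Sigma, g.C, atol=0.05)

    def test_scalar_ar_half_variance(self, rng):
        a, T = 0.5, 200_000
        x, X = 0.0, np.empty((T, 1))
        noise = rng.standard_normal(T)
        for t in range(T):
            X[t, 0] = x = a * x + noise[t]
        g = fit_ar(X)
        assert g.C[0, 0] == pytest.approx(4 / 3, rel=0.05)

    def test_short_or_bad_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            fit_ar(np.zeros((3, 5)))
        with pytest.raises(ValueError, match="non-finite"):
            fit_ar(np.full((100, 2), np.nan))


class TestGaussianInformation:
    def test_block_diagonal_has_zero_mi(self):
        T = np.diag([1.0, 2.0, 3.0, 4.0])
        assert gaussian_mi(T, ((0, 1), (2, 3))) == pytest.approx(0.0, abs=1e-12)

    def test_bivariate_correlation_closed_form(self):
        rho = 0.6
        T = np.array([[1.0, rho], [rho, 1.0]])
        assert gaussian_mi(T, ((0,), (1,))) == pytest.approx(
            -0.5 * np.log(1 - rho**2), abs=1e-12
        )

    def test_mi_matches_monte_carlo_kl(self, rng):
        M = rng.standard_normal((6, 6))
        T = M @ M.T + np.eye(6)
        split = ((0, 1, 2), (3, 4, 5))
        analytic = gaussian_mi(T, split)
        # sampling oracle: E_p[log p(x) - log pA(xA) pB(xB)]
        X = rng.multivariate_normal(np.zeros(6), T, size=400_000)
        def logpdf(x, C):
            sign, ld = np.linalg.slogdet(C)
            return -0.5 * (np.einsum("ni,ij,nj->n", x, np.linalg.inv(C), x)
                           + ld + C.shape[0] * np.log(2 * np.pi))
        mc = np.mean(
            logpdf(X, T)
            - logpdf(X[:, :3], T[:3, :3])
            - logpdf(X[:, 3:], T[3:, 3:])
        )
        assert analytic == pytest.approx(mc, abs=0.02)

    def test_kl_identical_gaussians_zero(self, rng):
        M = rng.standard_normal((3, 3))
        C = M @ M.T + np.eye(3)
        m = rng.standard_normal(3)
        assert gaussian_kl(m, C, m, C) == pytest.approx(0.0, abs=1e-12)

    def test_kl_univariate_mean_shift(self):
        s2, dm = 2.0, 1.5
        assert gaussian_kl([dm], [[s2]], [0.0], [[s2]]) == pytest.approx(
            dm**2 / (2 * s2), abs=1e-12
        )

    def test_kl_matches_quadrature(self, rng):
        # 2-D grid quadrature oracle
        Cp = np.array([[1.0, 0.3], [0.3, 0.8]])
        Cq = np.array([[1.5, -0.2], [-0.2, 1.2]])
        mp, mq = np.array([0.3, -0.1]), np.array([0.0, 0.2])
        xs = np.linspace(-8, 8, 401)
        g = np.stack(np.meshgrid(xs, xs, indexing="ij"), -1).reshape(-1, 2)
        def logpdf(x, m, C):
            d = x - m
            return -0.5 * (np.einsum("ni,ij,nj->n", d, np.linalg.inv(C), d)
                           + np.linalg.slogdet(C)[1] + 2 * np.log(2 * np.pi))
        lp = logpdf(g, mp, Cp)
        w = np.exp(lp)
        w /= w.sum()
        quad = float((w * (lp - logpdf(g, mq, Cq))).sum())
        # remove the self-normalization offset of the discretized p
        quad -= float((w * (lp - np.log(w) - np.log((xs[1] - xs[0]) ** -2))).sum())
        assert gaussian_kl(mp, Cp, mq, Cq) == pytest.approx(quad, abs=1e-3)

    def test_kl_mean_covariance_decomposition(self, rng):
        M = rng.standard_normal((3, 3))
        Cp = M @ M.T + np.eye(3)
        N = rng.standard_normal((3, 3))
        Cq = N @ N.T + np.eye(3)
        m = rng.standard_normal(3)
        total = gaussian_kl(m, Cp, np.zeros(3), Cq)
        cov_part = gaussian_kl(np.zeros(3), Cp, np.zeros(3), Cq)
        mean_part = gaussian_kl(m, Cq, np.zeros(3), Cq)
        assert total == pytest.approx(cov_part + mean_part, abs=1e-10)


class TestGaussianMeasures:
    def test_forward_backward_determinants_match(self, rng):
        for _ in range(10):
            g, _, _ = stable_system(rng, n=5)
            ld_f = np.linalg.slogdet(g.Sigma)[1]
            ld_b = np.linalg.slogdet(g.Sigma_rev)[1]
            assert ld_f == pytest.approx(ld_b, rel=1e-8)

    def test_phi_M_two_printed_forms_agree(self, rng):
        for _ in range(5):
            g, _, _ = stable_system(rng)
            v1 = phi_gaussian(g, HALF_CUT, "M").value
            v2 = phi_M_tform(g, HALF_CUT)
            assert v1 == pytest.approx(v2, abs=1e-10)

    def test_separable_system_zero_for_every_finite_code(self, rng):
        g = separable_system(rng)
        state = np.array([1.0, -2.0, 0.5, 3.0])
        for code in GAUSSIAN_CODES:
            needs_state = code.endswith("k") and code != "xfk" or code.startswith("2.5")
            v = phi_gaussian(g, HALF_CUT, code, state=state if needs_state else None)
            assert abs(v.value) < 1e-9, code

    def test_nonnegative_codes(self, rng):
        for _ in range(5):
            g, _, _ = stable_system(rng)
            st = rng.standard_normal(4)
            for code in ("M", "MD", "ofu", "mas", "mps", "ofk", "oak", "opk",
                         "mak", "mpk", "xfk", "ots", "ofs"):
                v = phi_gaussian(g, HALF_CUT, code, state=st).value
                assert v >= -1e-10, code

    def test_barrett_seth_identity_in_nats(self, rng):
        for _ in range(5):
            g, _, _ = stable_system(rng)
            pm = phi_gaussian(g, HALF_CUT, "M").value
            pb = phi_gaussian(g, HALF_CUT, "B").value
            mi_future = gaussian_mi(g.C, HALF_CUT)
            assert pb == pytest.approx(pm - mi_future, abs=1e-10)

    def test_initial_correlation_discrimination(self, rng):
        # A and Sigma block-diagonal but C cross-correlated: the forward
        # prediction of A needs nothing from B (oak = 0) while the equal-time
        # dependence is real (ots > 0)
        A = np.zeros((4, 4))
        A[:2, :2] = [[0.5, 0.1], [0.0, 0.4]]
        A[2:, 2:] = [[0.3, 0.2], [0.1, 0.2]]
        C = np.eye(4) + 0.4 * (np.ones((4, 4)) - np.eye(4))
        g = GaussianSystem(C=C, B=C @ A.T)
        st = np.ones(4)
        assert phi_gaussian(g, HALF_CUT, "oak", state=st).value == pytest.approx(
            0.0, abs=1e-10
        )
        assert phi_gaussian(g, HALF_CUT, "ots").value > 0.01

    def test_infinite_codes_rejected(self, rng):
        g, _, _ = stable_system(rng)
        for code in INFINITE_CODES:
            with pytest.raises(ValueError, match="infinite"):
                phi_gaussian(g, HALF_CUT, code)

    def test_units_conversion(self, rng):
        g, _, _ = stable_system(rng)
        nats = phi_gaussian(g, HALF_CUT, "M", units="nats").value
        bits = phi_gaussian(g, HALF_CUT, "M", units="bits").value
        assert bits == pytest.approx(nats / np.log(2), abs=1e-12)

    def test_default_state_is_mean_with_warning(self, rng):
        g, _, _ = stable_system(rng)
        with pytest.warns(UserWarning, match="mean"):
            v = phi_gaussian(g, HALF_CUT, "oak")
        # zero state nulls the mean-mismatch term: pure covariance part
        st = np.zeros(4)
        assert v.value == pytest.approx(
            phi_gaussian(g, HALF_CUT, "oak", state=st).value, abs=1e-12
        )

    def test_25_family_minima(self, rng):
        g, _, _ = stable_system(rng)
        st = rng.standard_normal(4)
        for variant, pair in [("2.5'", ("mak", "mpk")), ("2.5''", ("oak", "opk"))]:
            v = phi_gaussian(g, HALF_CUT, variant, state=st)
            parts = [phi_gaussian(g, HALF_CUT, c, state=st).value for c in pair]
            assert v.value == pytest.approx(min(parts), abs=1e-12)


class TestDiscretizationCrossCheck:
    def build_grid_joint(self, g, L=40, lim=4.5):
        from phitax import validate_joint

        T4 = np.block([[g.C, g.B], [g.B.T, g.C]])
        xs = np.linspace(-lim, lim, L)
        grid = np.stack(np.meshgrid(xs, xs, xs, xs, indexing="ij"), -1).reshape(-1, 4)
        logp = -0.5 * np.einsum("ni,ij,nj->n", grid, np.linalg.inv(T4), grid)
        p = np.exp(logp)
        return validate_joint((p / p.sum()).reshape(L, L, L, L))

    def test_phi_M_matches_fine_grid_discretization(self):
        from phitax import phi_M

        A = np.array([[0.5, 0.3], [0.1, 0.4]])
        g = GaussianSystem.from_dynamics(A, np.eye(2))
        cut = Bipartition((0,), (1,))
        analytic = phi_gaussian(g, cut, "M").value
        jd = self.build_grid_joint(g)
        discretized = phi_M(jd).value * np.log(2)
        assert discretized == pytest.approx(analytic, rel=0.02)

    def test_phi_MD_matches_discretized_beta_one(self):
        from phitax import phi_MD

        A = np.array([[0.5, 0.3], [0.1, 0.4]])
        g = GaussianSystem.from_dynamics(A, np.eye(2))
        cut = Bipartition((0,), (1,))
        analytic = phi_gaussian(g, cut, "MD").value
        jd = self.build_grid_joint(g, L=24, lim=4.0)
        discretized = phi_MD(jd, 1.0).value * np.log(2)
        assert discretized == pytest.approx(analytic, abs=0.02)
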