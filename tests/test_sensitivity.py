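"""Sensitivity matrices: analytic oracles, PSD contracts, LIS identities,
nuisance exclusion and unit invariance."""

import numpy as np
import pytest

from sloppykit import (
    Dataset,
    ErrorSpec,
    FDConfig,
    MichaelisMentenModel,
    ParameterSet,
    drop_nuisance,
    hessian_H,
    levenberg_marquardt_L,
    lis_G,
    lis_K,
    load_matrix,
    pca_P,
    prior_log_covariance,
    save_matrix,
)
from sloppykit.inference import PosteriorEnsemble, fit_mle, posterior_log_moments
from sloppykit.models import MM_REFERENCE
from sloppykit.observation import generate_heteroscedastic
from sloppykit.priors import LogNormalComponent, Prior, UniformComponent
from sloppykit.sensitivity import SensitivityMatrix
from sloppykit.scenarios import mm_prior

from conftest import LogLinearModel


def _quadratic_setup(weights=(3, 1)):
    """Cost = 1/2 * sum_i a_i (log theta_i - c_i)^2 via repeated unit-sigma
    observations (a_i copies of output i), so H = diag(a_i) exactly."""
    d = len(weights)
    names = tuple(f"p{i}" for i in range(d))
    model = LogLinearModel(np.eye(d), names)
    rows, y = [], []
    c = np.linspace(0.2, 1.0, d)
    for i, a in enumerate(weights):
        rows += [i] * a
        y += [c[i]] * a
    data = Dataset(np.array(rows)[:, None], np.zeros(len(rows), int), np.array(y),
                   ErrorSpec("homoscedastic", sigma=1.0))
    theta = ParameterSet(names, np.exp(c))
    return model, data, theta, np.diag(weights).astype(float)


class TestHessian:
    def test_quadratic_log_likelihood_gives_diagonal_hessian(self):
        model, data, theta, expected = _quadratic_setup((3, 1, 5))
        H = hessian_H(model, data, theta)
        assert np.allclose(H.entries, expected, atol=1e-6)

    def test_agrees_with_richardson_extrapolated_oracle(self):
        # independent second-difference oracle at steps h and h/2
        model, data, theta, _ = _quadratic_setup((2, 4))
        from sloppykit.observation import log_likelihood

        def fd_hessian(h):
            phi0 = theta.log_values
            d = len(phi0)
            f = lambda p: -log_likelihood(model, data, dict(zip(theta.names, np.exp(p))))
            H = np.empty((d, d))
            for i in range(d):
                for j in range(d):
                    ei, ej = np.zeros(d), np.zeros(d)
                    ei[i], ej[j] = h, h
                    H[i, j] = (f(phi0 + ei + ej) - f(phi0 + ei - ej) - f(phi0 - ei + ej) + f(phi0 - ei - ej)) / (4 * h * h)
            return H

        oracle = (4.0 * fd_hessian(5e-4) - fd_hessian(1e-3)) / 3.0
        H = hessian_H(model, data, theta, FDConfig(delta=1e-3))
        assert np.allclose(H.entries, oracle, rtol=1e-4, atol=1e-8)

    def test_undefined_stencil_raises_with_parameter_names(self):
        # a model that predicts log(theta) goes non-positive inside the FD
        # stencil under heteroscedastic errors -> evaluation error
        model = LogLinearModel(np.eye(1), ("p0",))
        data = Dataset(np.zeros((1, 1)), [0], [0.5], ErrorSpec("heteroscedastic", eps=0.25))
        theta = ParameterSet(("p0",), np.array([1.0000001]))  # log ~ 1e-7, stencil crosses 0
        with pytest.raises(ValueError, match="p0"):
            hessian_H(model, data, theta)


class TestLevenbergMarquardt:
    def test_linear_model_matches_analytic_jacobian(self):
        rng = np.random.default_rng(2)
        A = rng.standard_normal((7, 3))
        names = ("a", "b", "c")
        model = LogLinearModel(A, names)
        data = Dataset(np.arange(7)[:, None], np.zeros(7, int), rng.standard_normal(7),
                       ErrorSpec("homoscedastic", sigma=1.0))
        theta = ParameterSet(names, np.array([1.3, 0.6, 2.0]))
        L = levenberg_marquardt_L(model, data, theta)
        assert np.allclose(L.entries, A.T @ A, atol=1e-8)

    def test_positive_semidefinite_on_all_fixtures(self, br_mle_fit):
        mats = []
        model, data, theta, _ = _quadratic_setup((2, 3))
        mats.append(levenberg_marquardt_L(model, data, theta).entries)
        mm = MichaelisMentenModel()
        ds = generate_heteroscedastic(mm, np.array([[10.0], [100.0], [1000.0]]), MM_REFERENCE, 0.25, 0)
        th = ParameterSet.from_dict({**MM_REFERENCE.as_dict(), "eps": 0.25})
        mats.append(levenberg_marquardt_L(mm, ds, th, nuisance=("eps",)).entries)
        mats.append(br_mle_fit["L"].entries)
        for M in mats:
            vals = np.linalg.eigvalsh(M)
            assert vals.min() >= -1e-10 * max(vals.max(), 1.0)

    def test_matches_hessian_eigenvectors_at_zero_residual_optimum(self):
        # Gauss-Newton equals the full Hessian when residuals vanish
        mm = MichaelisMentenModel()
        grid = np.geomspace(2.0, 6000.0, 10)[:, None]
        clean = generate_heteroscedastic(mm, grid, MM_REFERENCE, 1e-12, seed=0)
        data = Dataset(clean.X, clean.output_index, clean.y_obs, ErrorSpec("heteroscedastic", eps=0.25))
        prior = mm_prior(1)
        init = ParameterSet.from_dict({"k_cat": 120.0, "E_T": 4.0, "K_M": 160.0, "eps": 0.25})
        mle = fit_mle(mm, data, prior, init, polish=True)
        H = hessian_H(mm, data, mle.theta, nuisance=("eps",))
        L = levenberg_marquardt_L(mm, data, mle.theta, nuisance=("eps",))
        for col in range(3):
            vH = np.linalg.eigh(H.entries)[1][:, ::-1][:, col]
            vL = np.linalg.eigh(L.entries)[1][:, ::-1][:, col]
            assert abs(vH @ vL) >= 0.999


class TestPosteriorCovariancePCA:
    def test_identity_log_covariance_gives_identity_P(self):
        rng = np.random.default_rng(3)
        ens = PosteriorEnsemble(("a", "b", "c"), rng.standard_normal((50_000, 3)))
        P = pca_P(ens)
        assert np.allclose(P.entries, np.eye(3), atol=0.05)

    def test_correlated_2d_matches_analytic_inverse(self):
        # Sigma = [[1, .9], [.9, 1]] -> inverse [[5.263, -4.737], [...]]
        rng = np.random.default_rng(4)
        cov = np.array([[1.0, 0.9], [0.9, 1.0]])
        M = 100_000
        ens = PosteriorEnsemble(("a", "b"), rng.multivariate_normal([0, 0], cov, size=M))
        P = pca_P(ens)
        expected = np.array([[5.263, -4.737], [-4.737, 5.263]])
        # 3 Monte-Carlo standard errors on the inverse, ~ sqrt(2/M)*|P|
        tol = 3 * np.sqrt(2.0 / M) * np.abs(expected) * 3
        assert np.all(np.abs(P.entries - expected) < np.maximum(tol, 0.06))

    def test_singular_covariance_triggers_jitter_warning(self):
        logs = np.random.default_rng(5).standard_normal((200, 1))
        ens = PosteriorEnsemble(("a", "b"), np.hstack([logs, 2.0 * logs]))
        with pytest.warns(RuntimeWarning):
            P = pca_P(ens)
        assert np.all(np.isfinite(P.entries))


class TestLIS:
    def _gaussian_ensemble(self, rng, cov, M=2000, names=("a", "b")):
        return PosteriorEnsemble(names, rng.multivariate_normal(np.zeros(len(names)), cov, size=M))

    def test_identity_prior_reduces_G_to_mean_hessian(self):
        model, data, theta, _ = _quadratic_setup((2, 1))
        prior = Prior([LogNormalComponent("p0", 0.0, 1.0), LogNormalComponent("p1", 0.0, 1.0)])
        rng = np.random.default_rng(6)
        ens = PosteriorEnsemble(("p0", "p1"), rng.standard_normal((40, 2)) * 0.1)
        G = lis_G(ens, prior, model, data, subsample=None)
        acc = np.zeros((2, 2))
        for m in range(ens.M):
            th = ParameterSet(("p0", "p1"), np.exp(ens.log_samples[m]))
            acc += hessian_H(model, data, th).entries
        assert np.allclose(G.entries, acc / ens.M, atol=1e-10)

    def test_single_sample_ensemble_is_one_preconditioned_hessian(self):
        model, data, theta, _ = _quadratic_setup((1, 2))
        prior = Prior([LogNormalComponent("p0", 0.0, 0.5), LogNormalComponent("p1", 0.0, 2.0)])
        ens = PosteriorEnsemble(("p0", "p1"), np.array([[0.2, -0.1]]))
        G = lis_G(ens, prior, model, data, subsample=None)
        Lp = np.linalg.cholesky(prior.log_covariance())
        H1 = hessian_H(model, data, ParameterSet(("p0", "p1"), np.exp([0.2, -0.1]))).entries
        assert np.allclose(G.entries, Lp.T @ H1 @ Lp, atol=1e-12)

    def test_K_equals_P_for_identity_prior_covariance(self):
        rng = np.random.default_rng(7)
        cov = np.array([[0.3, 0.1], [0.1, 0.2]])
        ens = self._gaussian_ensemble(rng, cov)
        prior = Prior([LogNormalComponent("a", 0.0, 1.0), LogNormalComponent("b", 0.0, 1.0)])
        K = lis_K(ens, prior)
        P = pca_P(ens)
        assert np.allclose(K.entries, P.entries, rtol=1e-12)

    def test_K_is_identity_when_posterior_equals_prior(self):
        # Omega = Sigma-hat: no information gained from the data
        rng = np.random.default_rng(8)
        cov = np.array([[0.5, 0.2], [0.2, 0.8]])
        ens = self._gaussian_ensemble(rng, cov)
        from sloppykit.priors import MultivariateLogNormalBlock

        _, sig = posterior_log_moments(ens)
        prior = Prior([MultivariateLogNormalBlock(("a", "b"), np.zeros(2), sig)])
        K = lis_K(sig, prior, names=("a", "b"))
        assert np.allclose(K.entries, np.eye(2), atol=1e-8)

    def test_K_matches_dense_algebra_oracle(self):
        rng = np.random.default_rng(9)
        A = rng.standard_normal((4, 4))
        sig = A @ A.T + 4 * np.eye(4)
        B = rng.standard_normal((4, 4))
        omega = B @ B.T + 4 * np.eye(4)
        names = ("a", "b", "c", "d")
        from sloppykit.priors import MultivariateLogNormalBlock

        prior = Prior([MultivariateLogNormalBlock(names, np.zeros(4), omega)])
        K = lis_K(sig, prior, names=names)
        Lp = np.linalg.cholesky(omega)
        oracle = Lp.T @ np.linalg.solve(sig, Lp)
        assert np.allclose(K.entries, 0.5 * (oracle + oracle.T), atol=1e-10)

    def test_G_and_K_share_eigenvectors_for_gaussian_posterior(self):
        # exactly-Gaussian posterior in log space: the Hessian of -log L is
        # constant, so G's eigenvectors equal K's
        rng = np.random.default_rng(10)
        names = ("p0", "p1")
        A = np.array([[1.0, 0.4], [0.0, 1.0], [0.7, 0.2]])
        model = LogLinearModel(A, names)
        y = np.array([0.1, -0.2, 0.3])
        data = Dataset(np.arange(3)[:, None], np.zeros(3, int), y, ErrorSpec("homoscedastic", sigma=0.5))
        prior = Prior([LogNormalComponent("p0", 0.0, 1.2), LogNormalComponent("p1", 0.0, 0.7)])
        # posterior: precision = prior^-1 + A^T A / sigma^2
        prec = np.linalg.inv(prior.log_covariance()) + A.T @ A / 0.25
        cov = np.linalg.inv(prec)
        mean = cov @ (A.T @ y / 0.25)
        ens = PosteriorEnsemble(names, rng.multivariate_normal(mean, cov, size=300))
        G = lis_G(ens, prior, model, data, subsample=None)
        K = lis_K(cov, prior, names=names)
        for col in range(2):
            vG = np.linalg.eigh(G.entries)[1][:, ::-1][:, col]
            vK = np.linalg.eigh(K.entries)[1][:, ::-1][:, col]
            assert abs(vG @ vK) >= 0.99


class TestPriorLogCovariance:
    def test_matches_prior_method_and_blocks(self):
        prior = mm_prior(2)
        omega = prior_log_covariance(prior)
        assert omega.shape == (4, 4)
        assert omega[2, 2] == pytest.approx(0.05**2)
        sub = prior_log_covariance(prior, ["k_cat", "E_T", "K_M"])
        assert sub.shape == (3, 3) and sub[2, 2] == pytest.approx(0.05**2)


class TestNuisanceExclusion:
    def test_mm_matrices_are_3x3_with_inferred_eps(self):
        mm = MichaelisMentenModel()
        ds = generate_heteroscedastic(mm, np.array([[50.0], [500.0], [5000.0]]), MM_REFERENCE, 0.25, 1)
        th = ParameterSet.from_dict({**MM_REFERENCE.as_dict(), "eps": 0.25})
        H = hessian_H(mm, ds, th, nuisance=("eps",))
        assert H.dim == 3 and "eps" not in H.names

    def test_br_matrix_is_9x9_with_inferred_sigma(self, br_mle_fit):
        assert br_mle_fit["L"].dim == 9 and "sigma" not in br_mle_fit["L"].names

    def test_drop_nuisance_pass_through_and_errors(self):
        mat = SensitivityMatrix("P", np.eye(3), ("a", "b", "eps"))
        assert drop_nuisance(mat, ()) is mat
        red = drop_nuisance(mat, ("eps",))
        assert red.names == ("a", "b") and red.entries.shape == (2, 2)
        with pytest.raises(KeyError):
            drop_nuisance(mat, ("zz",))


class TestInvariances:
    def test_unit_change_leaves_matrices_unchanged(self):
        """Expressing E_T in different units (nM instead of uM) must leave
        every log-space sensitivity matrix exactly unchanged."""

        class NanomolarMM(MichaelisMentenModel):
            def predict(self, X, theta):
                t = {
                    "k_cat": self._value(theta, "k_cat"),
                    "E_T": self._value(theta, "E_T") / 1000.0,
                    "K_M": self._value(theta, "K_M"),
                }
                return super().predict(X, t)

        mm = MichaelisMentenModel()
        ds = generate_heteroscedastic(mm, np.array([[20.0], [200.0], [2000.0]]), MM_REFERENCE, 0.25, 2)
        th = ParameterSet.from_dict({**MM_REFERENCE.as_dict(), "eps": 0.25})
        th_nm = th.updated(E_T=5000.0)
        for build in (hessian_H, levenberg_marquardt_L):
            a = build(mm, ds, th, nuisance=("eps",)).entries
            b = build(NanomolarMM(), ds, th_nm, nuisance=("eps",)).entries
            assert np.allclose(a, b, rtol=1e-7, atol=1e-9)

    def test_fd_step_stability_of_eigenvectors(self):
        mm = MichaelisMentenModel()
        ds = generate_heteroscedastic(mm, np.array([[2e4], [3e4], [4e4], [5e4], [6e4]]), MM_REFERENCE, 0.25, 3)
        th = ParameterSet.from_dict({**MM_REFERENCE.as_dict(), "eps": 0.25})
        vs = []
        for delta in (1e-3, 1e-4):
            H = hessian_H(mm, ds, th, FDConfig(delta=delta), nuisance=("eps",))
            vs.append(np.linalg.eigh(H.entries)[1][:, -1])
        assert abs(vs[0] @ vs[1]) >= 0.999


def test_matrix_round_trip_and_validation(tmp_path):
    mat = SensitivityMatrix("H", np.array([[2.0, 0.5], [0.5, 1.0]]), ("a", "b"), {"delta": 1e-3})
    save_matrix(mat, tmp_path / "H.csv")
    back = load_matrix(tmp_path / "H.csv")
    assert back.kind == "H" and back.names == ("a", "b")
    assert np.array_equal(back.entries, mat.entries)
    with pytest.raises(ValueError):
        SensitivityMatrix("H", np.array([[1.0, 0.5], [0.0, 1.0]]), ("a", "b"))
    with pytest.raises(ValueError):
        SensitivityMatrix("Q", np.eye(2), ("a", "b"))
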