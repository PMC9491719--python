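"""MLE and SMC: analytic optima, conjugate posteriors, ridge behaviour, and
sampler invariants."""

import numpy as np
import pytest

from sloppykit import (
    Dataset,
    ErrorSpec,
    MichaelisMentenModel,
    ParameterSet,
    SMCSettings,
    fit_mle,
    fit_mle_multistart,
    posterior_log_moments,
    smc_sample,
)
from sloppykit.inference import PosteriorEnsemble, load_ensemble, save_ensemble
from sloppykit.models import MM_REFERENCE
from sloppykit.observation import generate_heteroscedastic
from sloppykit.priors import LogNormalComponent, Prior, UniformComponent
from sloppykit.scenarios import mm_dataset, mm_prior

from conftest import LogLinearModel


def _quadratic_toy(c):
    """Gaussian likelihood whose cost is 1/2 ||log theta - c||^2 + const."""
    d = len(c)
    model = LogLinearModel(np.eye(d), tuple(f"p{i}" for i in range(d)))
    data = Dataset(np.arange(d)[:, None], np.zeros(d, int), np.asarray(c, float),
                   ErrorSpec("homoscedastic", sigma=1.0))
    prior = Prior([LogNormalComponent(f"p{i}", 0.0, 10.0) for i in range(d)])
    return model, data, prior


class TestFitMLE:
    def test_quadratic_toy_recovers_analytic_minimum(self):
        c = np.array([0.3, -1.2, 2.0])
        model, data, prior = _quadratic_toy(c)
        init = ParameterSet(("p0", "p1", "p2"), np.ones(3))
        res = fit_mle(model, data, prior, init)
        assert np.allclose(res.theta.log_values, c, atol=1e-6)
        assert res.converged

    def test_cost_never_exceeds_start(self):
        model, data, prior = _quadratic_toy(np.array([1.0, 1.0]))
        init = ParameterSet(("p0", "p1"), np.array([5.0, 0.1]))
        res = fit_mle(model, data, prior, init, maxfev=10)
        f0 = 0.5 * np.sum((init.log_values - np.array([1.0, 1.0])) ** 2)
        assert res.cost <= f0 + 0.5 * 2 * np.log(2 * np.pi) + 1e-9

    def test_noiseless_two_regime_data_recovers_reference(self):
        model = MichaelisMentenModel()
        grid = np.geomspace(2.0, 6000.0, 10)[:, None]
        data = generate_heteroscedastic(model, grid, MM_REFERENCE, 1e-12, seed=0)
        data = Dataset(data.X, data.output_index, data.y_obs, ErrorSpec("heteroscedastic", eps=0.25))
        prior = mm_prior(1)
        init = ParameterSet.from_dict({"k_cat": 300.0, "E_T": 2.0, "K_M": 50.0, "eps": 0.25})
        res = fit_mle(model, data, prior, init, polish=True)
        # the zero-residual optimum identifies K_M and the product k_cat*E_T;
        # the factors themselves are structurally unidentifiable (any split
        # of the product fits equally well)
        assert res.theta["K_M"] == pytest.approx(146.7, rel=1e-3)
        assert res.theta["k_cat"] * res.theta["E_T"] == pytest.approx(500.0, rel=1e-3)

    def test_low_substrate_ridge_constrains_only_the_ratio(self):
        # two different starts on first-order-regime data: parameter values
        # disagree wildly but k_cat*E_T/K_M agrees to better than 1%
        model = MichaelisMentenModel()
        data = mm_dataset("B", seed=1)
        prior = mm_prior(1)
        starts = [
            ParameterSet.from_dict({"k_cat": 30.0, "E_T": 2.0, "K_M": 30.0, "eps": 0.3}),
            ParameterSet.from_dict({"k_cat": 500.0, "E_T": 20.0, "K_M": 600.0, "eps": 0.2}),
        ]
        ratios, kcats = [], []
        for s in starts:
            r = fit_mle(model, data, prior, s, polish=True)
            ratios.append(r.theta["k_cat"] * r.theta["E_T"] / r.theta["K_M"])
            kcats.append(r.theta["k_cat"])
        assert abs(ratios[0] - ratios[1]) / ratios[0] < 0.01
        assert not np.isclose(kcats[0], kcats[1], rtol=0.2)  # the bare parameters differ

    def test_multistart_sorted_by_cost(self):
        model, data, prior = _quadratic_toy(np.array([0.5, -0.5]))
        results = fit_mle_multistart(model, data, prior, n_starts=3, seed=0, maxfev=200)
        costs = [r.cost for r in results]
        assert costs == sorted(costs)

    def test_unit_rescaling_shifts_mle_in_log_space(self):
        # expressing a parameter in different units only shifts its log; the
        # optimizer must find the correspondingly shifted optimum
        c = np.array([0.2, 1.0])
        model, data, prior = _quadratic_toy(c)
        res = fit_mle(model, data, prior, ParameterSet(("p0", "p1"), np.ones(2)))
        shifted = fit_mle(model, data, prior, ParameterSet(("p0", "p1"), np.exp(c) * 1.7))
        assert np.allclose(res.theta.log_values, shifted.theta.log_values, atol=1e-5)

    def test_invalid_start_raises(self):
        model, data, prior = _quadratic_toy(np.array([0.0]))
        prior = Prior([UniformComponent("p0", 1.0, 2.0)])
        with pytest.raises(ValueError):
            fit_mle(model, data, prior, ParameterSet(("p0",), np.array([5.0])))


class TestSMC:
    def test_constant_likelihood_returns_prior(self):
        # a model with zero rows: predictions are 0 for every theta, so the
        # likelihood is constant and the posterior equals the prior
        from scipy.stats import ks_2samp

        model = LogLinearModel(np.zeros((1, 2)), ("p0", "p1"))
        data = Dataset(np.zeros((1, 1)), [0], [0.0], ErrorSpec("homoscedastic", sigma=1.0))
        prior = Prior([UniformComponent("p0", 1.0, 50.0), LogNormalComponent("p1", 0.5, 0.8)])
        ens = smc_sample(model, data, prior, SMCSettings(M=2000, seed=3))
        rng = np.random.default_rng(4)
        ref = prior.sample_log(2000, rng)
        for j in range(2):
            assert ks_2samp(ens.log_samples[:, j], ref[:, j]).pvalue > 0.01

    def test_conjugate_gaussian_update_matches_closed_form(self):
        # log-normal prior + Gaussian likelihood in log theta: the posterior
        # for log theta is the standard Gaussian-Gaussian update
        mu0, s0 = 1.0, 0.8
        sigma, n = 0.5, 4
        y = np.array([0.2, 0.5, -0.1, 0.4])
        model = LogLinearModel(np.ones((n, 1)), ("p0",))
        data = Dataset(np.arange(n)[:, None], np.zeros(n, int), y, ErrorSpec("homoscedastic", sigma=sigma))
        prior = Prior([LogNormalComponent("p0", mu0, s0)])
        prec = 1 / s0**2 + n / sigma**2
        post_mean = (mu0 / s0**2 + y.sum() / sigma**2) / prec
        post_var = 1 / prec
        ens = smc_sample(model, data, prior, SMCSettings(M=4000, seed=5))
        mean, cov = posterior_log_moments(ens)
        se_mean = np.sqrt(post_var / ens.M)
        se_var = post_var * np.sqrt(2.0 / ens.M)
        # 3x Monte-Carlo standard errors, inflated for resampling ties
        assert mean[0] == pytest.approx(post_mean, abs=9 * se_mean)
        assert cov[0, 0] == pytest.approx(post_var, abs=9 * se_var)

    def test_temperature_ladder_monotone_zero_to_one(self, scenario_results):
        ladder = scenario_results(1).ensemble.provenance["temperature_ladder"]
        assert ladder[0] == 0.0 and ladder[-1] == 1.0
        assert np.all(np.diff(ladder) > 0)

    def test_saturating_data_constrain_product_not_km(self, scenario_results):
        res = scenario_results(1)
        logs = res.ensemble.log_samples
        i = {n: k for k, n in enumerate(res.ensemble.names)}
        sd_prod = (logs[:, i["k_cat"]] + logs[:, i["E_T"]]).std()
        sd_kcat = logs[:, i["k_cat"]].std()
        assert sd_prod * 10.0 <= sd_kcat
        # K_M marginal spans its prior: SD comparable to the prior SD
        prior_sd = np.sqrt(res.prior.log_covariance(["K_M"])[0, 0])
        assert logs[:, i["K_M"]].std() > 0.5 * prior_sd

    def test_underflow_everywhere_raises(self):
        model = LogLinearModel(np.ones((1, 1)), ("p0",))
        data = Dataset(np.zeros((1, 1)), [0], [1e8], ErrorSpec("homoscedastic", sigma=1e-300))
        prior = Prior([UniformComponent("p0", 1.0, 2.0)])
        with pytest.raises(RuntimeError):
            smc_sample(model, data, prior, SMCSettings(M=100, seed=0))


class TestPosteriorMoments:
    def test_identical_samples_give_zero_covariance(self):
        ens = PosteriorEnsemble(("a", "b"), np.tile([0.3, 1.1], (50, 1)))
        _, cov = posterior_log_moments(ens)
        assert np.allclose(cov, 0.0)

    def test_known_lognormal_covariance_recovered(self):
        rng = np.random.default_rng(8)
        true_cov = np.array([[0.5, 0.3], [0.3, 0.4]])
        M = 20_000
        logs = rng.multivariate_normal([0.0, 1.0], true_cov, size=M)
        _, cov = posterior_log_moments(PosteriorEnsemble(("a", "b"), logs))
        se = np.sqrt((true_cov**2 + np.outer(np.diag(true_cov), np.diag(true_cov))) / M)
        assert np.all(np.abs(cov - true_cov) < 3 * se)

    def test_invariant_to_sample_reordering(self):
        rng = np.random.default_rng(9)
        logs = rng.standard_normal((500, 3))
        m1, c1 = posterior_log_moments(PosteriorEnsemble(("a", "b", "c"), logs))
        perm = rng.permutation(500)
        m2, c2 = posterior_log_moments(PosteriorEnsemble(("a", "b", "c"), logs[perm]))
        assert np.allclose(m1, m2) and np.allclose(c1, c2)


def test_ensemble_round_trip_and_drop(tmp_path):
    rng = np.random.default_rng(10)
    ens = PosteriorEnsemble(("a", "b", "eps"), rng.standard_normal((100, 3)), {"seed": 7})
    save_ensemble(ens, tmp_path / "ens.csv")
    back = load_ensemble(tmp_path / "ens.csv")
    assert back.names == ens.names
    assert np.allclose(back.log_samples, ens.log_samples, atol=1e-14)
    assert back.provenance["seed"] == 7
    reduced = ens.drop(["eps"])
    assert reduced.names == ("a", "b") and reduced.log_samples.shape == (100, 2)
    with pytest.raises(KeyError):
        ens.drop(["zz"])
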