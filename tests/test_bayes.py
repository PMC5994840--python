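import numpy as np
import pytest

import funbayes as fb
from funbayes import bayes, design, synthetic
from funbayes.exceptions import ContractError, DataError, DimensionError, ParameterError


def _ridge_problem(seed=1, n=80, p=8, noise=0.5):
    rng = np.random.default_rng(seed)
    Z = rng.normal(size=(n, p))
    Z -= Z.mean(axis=0)
    y = 1.0 + Z @ rng.normal(size=p) + rng.normal(0, noise, n)
    return y, Z


def _batch_mcse(draws, n_batches=50):
    """Monte-Carlo SE of a posterior mean via batch means."""
    n = (draws.shape[0] // n_batches) * n_batches
    batches = draws[:n].reshape(n_batches, -1, *draws.shape[1:]).mean(axis=1)
    return batches.std(axis=0, ddof=1) / np.sqrt(n_batches)


LONG_CHAIN = bayes.McmcConfig(n_iter=21000, burn_in=1000, thin=1, seed=3)


class TestConjugateOracle:
    @pytest.mark.parametrize("family", bayes.FAMILIES)
    def test_fixed_hierarchy_reduces_to_ridge(self, family):
        # with variances pinned, every family's coefficient conditional is the
        # BRR Gaussian, whose posterior mean is the closed-form ridge solution
        y, Z = _ridge_problem()
        s2, vb = 0.25, 1.0
        prior = bayes.PriorSpec(
            family=family, fixed_resid_var=s2, fixed_coef_var=vb, fixed_pi=1.0
        )
        fit = bayes.fit(y, Z, prior, LONG_CHAIN)
        p = Z.shape[1]
        ridge = np.linalg.solve(
            Z.T @ Z + (s2 / vb) * np.eye(p), Z.T @ (y - y.mean())
        )
        mcse = _batch_mcse(fit.theta_draws)
        assert np.all(np.abs(fit.theta - ridge) <= 3 * mcse)


class TestSamplerBasics:
    def test_zero_response_gives_null_coefficients(self, rng):
        Z = rng.normal(size=(60, 5))
        fit = bayes.fit(np.zeros(60), Z, bayes.PriorSpec("BRR"),
                        bayes.McmcConfig(n_iter=4000, burn_in=1000, thin=1, seed=4))
        mcse = _batch_mcse(fit.theta_draws)
        assert np.all(np.abs(fit.theta) <= 3 * np.maximum(mcse, 1e-12))

    def test_identical_seeds_are_bitwise_reproducible(self, rng):
        y, Z = _ridge_problem(seed=7)
        mc = bayes.McmcConfig(n_iter=500, burn_in=100, thin=2, seed=42)
        fits = [bayes.fit(y, Z, bayes.PriorSpec("BayesB"), mc) for _ in range(2)]
        np.testing.assert_array_equal(fits[0].theta_draws, fits[1].theta_draws)
        np.testing.assert_array_equal(fits[0].sigma2_draws, fits[1].sigma2_draws)

    @pytest.mark.parametrize("family", bayes.FAMILIES)
    def test_draw_count_and_positive_variances(self, family):
        y, Z = _ridge_problem(seed=11, n=40, p=4)
        mc = bayes.McmcConfig(n_iter=700, burn_in=200, thin=5, seed=1)
        fit = bayes.fit(y, Z, bayes.PriorSpec(family), mc)
        assert fit.theta_draws.shape == (mc.n_draws, 4)
        assert np.all(fit.sigma2_draws > 0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ParameterError):
            bayes.McmcConfig(n_iter=100, burn_in=100)
        y, Z = _ridge_problem()
        with pytest.raises(DataError):
            bayes.fit(np.r_[y[:-1], np.nan], Z, bayes.PriorSpec())
        with pytest.raises(ParameterError):
            bayes.PriorSpec(family="BayesZ")


class TestPrediction:
    def test_prediction_is_posterior_mean_linear_form(self, rng):
        y, Z = _ridge_problem(seed=2)
        fit = bayes.fit(y, Z, bayes.PriorSpec("BRR"),
                        bayes.McmcConfig(n_iter=600, burn_in=100, thin=1, seed=5))
        Z_new = rng.normal(size=(7, Z.shape[1]))
        np.testing.assert_array_equal(
            fit.predict(Z_new), fit.mu + Z_new @ fit.theta
        )

    def test_interpolation_regime_near_perfect(self, rng):
        Z = rng.normal(size=(100, 10))
        y = Z @ rng.normal(size=10) * 5.0  # strong noiseless signal
        fit = bayes.fit(y, Z, bayes.PriorSpec("BRR", r2=0.99),
                        bayes.McmcConfig(n_iter=3000, burn_in=1000, thin=1, seed=6))
        r = np.corrcoef(fit.predict(Z), y)[0, 1]
        assert r > 0.999

    def test_no_signal_predicts_response_mean(self, rng):
        Z = rng.normal(size=(80, 5))
        y = 3.0 + rng.normal(0, 1.0, 80)
        fit = bayes.fit(y, Z, bayes.PriorSpec("BRR"),
                        bayes.McmcConfig(n_iter=2000, burn_in=500, thin=1, seed=7))
        pred = fit.predict(Z)
        assert np.abs(pred - y.mean()).max() < 1.0
        assert pred.std() < y.std()

    def test_column_mismatch_rejected(self, rng):
        y, Z = _ridge_problem()
        fit = bayes.fit(y, Z, bayes.PriorSpec("BRR"),
                        bayes.McmcConfig(n_iter=200, burn_in=50, thin=1, seed=8))
        with pytest.raises(DimensionError):
            fit.predict(rng.normal(size=(3, Z.shape[1] + 1)))


class TestRecovery:
    def test_m6_coefficients_recovered(self):
        # curves rich enough to span the fitted basis; 3:1 signal-to-noise
        truth_basis = synthetic.default_truth_basis(L=30)
        data, _ = synthetic.simulate_curves(
            n=500, m=250, truth_basis=truth_basis, seed=11
        )
        bundle = design.build_method_design("M6", data, design.DesignConfig(L=23))
        d_true = np.random.default_rng(12).normal(size=23)
        signal = bundle.Z @ d_true
        y = signal + np.random.default_rng(13).normal(0, signal.std() / 3, 500)
        fit = bayes.fit(y, bundle.Z, bayes.PriorSpec("BRR"),
                        bayes.McmcConfig(seed=14), bundle=bundle)
        assert np.corrcoef(fit.theta, d_true)[0, 1] > 0.9

    def test_m7_beta_curve_recovered(self):
        beta = lambda t: np.sin(2 * np.pi * t / 459.0)  # noqa: E731
        data, truth = synthetic.simulate_curves(n=500, m=250, seed=21)
        t = data.grid.points
        signal_sd = float(np.trapezoid(truth.curves * beta(t), t, axis=1).std())
        data, truth = synthetic.simulate_phenotypes(
            data, truth, beta, residual_sd=signal_sd / 3, seed=22
        )
        bundle = design.build_method_design("M7", data, design.DesignConfig(L=23))
        fit = bayes.fit(data.y, bundle.Z, bayes.PriorSpec("BRR"),
                        bayes.McmcConfig(seed=23), bundle=bundle)
        curve = bayes.beta_function(fit, data.grid)
        assert np.corrcoef(curve.estimate, beta(t))[0, 1] > 0.9


class TestBetaFunction:
    def _m6_fit(self, rng, L=7):
        data, _ = synthetic.simulate_curves(n=50, m=60, domain=(0.0, 1.0), seed=3)
        bundle = design.build_method_design("M6", data, design.DesignConfig(L=L))
        y = rng.normal(size=50)
        return bayes.fit(y, bundle.Z, bayes.PriorSpec("BRR"),
                         bayes.McmcConfig(n_iter=400, burn_in=100, thin=1, seed=9),
                         bundle=bundle)

    def test_constant_basis_gives_flat_curve(self, rng):
        data, _ = synthetic.simulate_curves(n=30, m=40, domain=(0.0, 1.0), seed=4)
        phi = fb.make_fourier_system((0.0, 1.0), 1, 1.0)
        bundle = design.build_Xstarstar(data, phi)
        fit = bayes.fit(rng.normal(size=30), bundle.Z, bayes.PriorSpec("BRR"),
                        bayes.McmcConfig(n_iter=400, burn_in=100, thin=1, seed=10),
                        bundle=bundle)
        curve = bayes.beta_function(fit, np.linspace(0, 1, 11))
        np.testing.assert_allclose(curve.estimate, fit.theta[0], atol=1e-12)

    def test_nested_grids_agree_pointwise(self, rng):
        fit = self._m6_fit(rng)
        coarse = np.linspace(0.0, 1.0, 11)
        dense = np.linspace(0.0, 1.0, 21)  # contains the coarse points
        c1 = bayes.beta_function(fit, coarse)
        c2 = bayes.beta_function(fit, dense)
        np.testing.assert_array_equal(c1.estimate, c2.estimate[::2])

    def test_raw_band_fits_refuse_beta_curve(self, rng):
        data, _ = synthetic.simulate_curves(n=30, m=40, domain=(0.0, 1.0), seed=5)
        bundle = design.build_method_design("M1", data, design.DesignConfig())
        fit = bayes.fit(rng.normal(size=30), bundle.Z, bayes.PriorSpec("BRR"),
                        bayes.McmcConfig(n_iter=300, burn_in=100, thin=1, seed=11),
                        bundle=bundle)
        with pytest.raises(ContractError):
            bayes.beta_function(fit, np.linspace(0, 1, 5))


class TestPriorBehaviour:
    @pytest.mark.parametrize("family", ["BayesB", "BayesC"])
    def test_null_data_inclusion_probability_near_or_below_prior(self, family):
        rng = np.random.default_rng(5)
        Z = rng.normal(size=(100, 30))
        y = rng.normal(size=100)
        fit = bayes.fit(y, Z, bayes.PriorSpec(family),
                        bayes.McmcConfig(n_iter=3000, burn_in=1000, thin=2, seed=6))
        per_draw = fit.extras["delta"].mean(axis=1)
        mcse = _batch_mcse(per_draw, n_batches=20)
        assert per_draw.mean() < 0.5 + 3 * mcse

    def test_spike_prior_beats_ridge_on_sparse_truth(self):
        # with 5 of 100 coefficients nonzero, the point-mass prior should win
        # on coefficient RMSE in most replicates
        wins = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            Z = rng.normal(size=(150, 100))
            theta = np.zeros(100)
            theta[rng.choice(100, 5, replace=False)] = 2 * rng.normal(size=5)
            y = Z @ theta + rng.normal(0, 1.0, 150)
            mc = bayes.McmcConfig(n_iter=800, burn_in=300, thin=2, seed=rep)
            rmse = {
                fam: float(np.sqrt(np.mean(
                    (bayes.fit(y, Z, bayes.PriorSpec(fam), mc).theta - theta) ** 2
                )))
                for fam in ("BayesB", "BRR")
            }
            wins += rmse["BayesB"] < rmse["BRR"]
        assert wins >= 14
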