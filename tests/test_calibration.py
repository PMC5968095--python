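"""Likelihoods, Metropolis-Hastings, posterior summaries and bands."""

import math

import numpy as np
import pandas as pd
import pytest

from qivive.calibration import (
    ObservedDataset,
    PosteriorSampleSet,
    PriorSpec,
    TruncatedNormal,
    Uniform,
    default_priors,
    log_likelihood,
    posterior_summary,
    predictive_band,
    run_mcmc,
)
from qivive.pbpk import ExposureScenario
from qivive.synthetic import default_oral_timecourse_spec, gen_timecourse


@pytest.fixture
def toy_data(oral_scenario):
    times = np.array([1.0, 1.0, 4.0, 12.0])
    conc = np.array([0.5, 0.6, 1.2, 0.8])
    return ObservedDataset(times, conc, np.array([0, 1, 0, 0]), oral_scenario)


class TestLogLikelihood:
    def test_lognormal_closed_form_at_exact_fit(self, baseline, toy_data):
        """With obs == pred the residual term vanishes; what remains is the
        log-normal normalising constant summed over points."""
        pred = toy_data.concentrations.copy()
        s = 0.2
        ll = log_likelihood(baseline, s, toy_data, "lognormal", predictions=pred)
        expected = sum(-math.log(o * s * math.sqrt(2 * math.pi))
                       for o in toy_data.concentrations)
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_doubling_sigma_changes_loglik_by_density_algebra(self, baseline, toy_data):
        pred = toy_data.concentrations * 1.3
        s = 0.15
        ll1 = log_likelihood(baseline, s, toy_data, "lognormal", predictions=pred)
        ll2 = log_likelihood(baseline, 2 * s, toy_data, "lognormal", predictions=pred)
        n = len(toy_data)
        z2 = np.sum((np.log(toy_data.concentrations) - np.log(pred)) ** 2)
        expected_delta = -n * math.log(2.0) + 0.5 * z2 * (1 / s**2 - 1 / (2 * s) ** 2)
        assert ll2 - ll1 == pytest.approx(expected_delta, rel=1e-10)

    def test_gaussian_standard_normal_at_zero(self, baseline, oral_scenario):
        data = ObservedDataset(np.array([1.0]), np.array([0.7]),
                               np.array([0]), oral_scenario)
        ll = log_likelihood(baseline, 1.0, data, "gaussian",
                            predictions=np.array([0.7]))
        assert ll == pytest.approx(-0.5 * math.log(2 * math.pi), rel=1e-12)

    def test_lognormal_rejects_nonpositive_observation(self, baseline, oral_scenario):
        data = ObservedDataset(np.array([1.0]), np.array([0.0]),
                               np.array([0]), oral_scenario)
        with pytest.raises(ValueError):
            log_likelihood(baseline, 0.1, data, "lognormal",
                           predictions=np.array([0.5]))

    def test_error_models_agree_in_small_noise_limit(self, baseline, toy_data):
        """Second-order agreement: for small relative residuals the
        log-normal model with scale s matches the Gaussian model with
        per-point scale s*pred, up to O(delta^3) in the residual."""
        delta = 1e-3
        pred = toy_data.concentrations / (1.0 + delta)
        s = 0.05
        ll_ln = log_likelihood(baseline, s, toy_data, "lognormal", predictions=pred)
        ll_ln0 = log_likelihood(baseline, s, toy_data, "lognormal",
                                predictions=toy_data.concentrations)
        # Gaussian with matched per-point scale; compare residual terms only
        d_ln = ll_ln - ll_ln0
        d_g = sum(-0.5 * ((o - p) / (s * o)) ** 2
                  for o, p in zip(toy_data.concentrations, pred))
        assert d_ln == pytest.approx(d_g, rel=5e-3)


class TestMCMC:
    def test_prior_recovery_without_data(self, baseline):
        """A flat likelihood leaves the posterior equal to the prior."""
        priors = PriorSpec({"PS2": Uniform(0.68, 0.92),
                            "BW": TruncatedNormal(0.25, 0.01, 0.22, 0.28)})
        post = run_mcmc(priors, None, baseline, n_iter=6000, burn_in=1000,
                        n_chains=2, seed=5)
        x = post.draws["PS2"].to_numpy()
        mcse = x.std() / math.sqrt(200)  # conservative ESS estimate
        assert x.mean() == pytest.approx(0.80, abs=2 * max(mcse, 1e-3))
        bw = post.draws["BW"].to_numpy()
        assert bw.mean() == pytest.approx(0.25, abs=0.005)

    def test_bivariate_gaussian_detailed_balance(self, baseline):
        """MH targeting a correlated bivariate Gaussian recovers its mean
        and covariance (detailed-balance smoke test)."""
        mu = np.array([0.3, -0.2])
        cov = np.array([[1.0, 0.6], [0.6, 1.0]])
        prec = np.linalg.inv(cov)

        def loglik(theta):
            z = theta[:2] - mu
            return -0.5 * z @ prec @ z

        priors = PriorSpec({"x": Uniform(-10, 10), "y": Uniform(-10, 10)})
        post = run_mcmc(priors, None, baseline, n_iter=22000, burn_in=2000,
                        n_chains=2, seed=9, loglik_fn=loglik)
        X = post.draws[["x", "y"]].to_numpy()
        ess = 300.0  # conservative for a 40k-draw correlated chain
        se_mean = math.sqrt(cov[0, 0] / ess)
        assert X[:, 0].mean() == pytest.approx(mu[0], abs=3 * se_mean)
        assert X[:, 1].mean() == pytest.approx(mu[1], abs=3 * se_mean)
        c_hat = np.corrcoef(X.T)[0, 1]
        assert c_hat == pytest.approx(0.6, abs=0.12)

    def test_requires_two_chains(self, baseline):
        with pytest.raises(ValueError):
            run_mcmc(default_priors("oral"), None, baseline, n_iter=100,
                     burn_in=10, n_chains=1)

    def test_posterior_within_prior_support(self, baseline):
        spec = default_oral_timecourse_spec(seed=3)
        data, _ = gen_timecourse(spec)
        priors = default_priors("oral")
        post = run_mcmc(priors, data, baseline, n_iter=400, burn_in=100,
                        n_chains=2, seed=2)
        for (name, prior) in priors.all_items():
            lo, hi = prior.support()
            x = post.draws[name].to_numpy()
            assert np.all((x >= lo) & (x <= hi))

    def test_calibration_shrinks_prior_intervals(self, baseline):
        """Conditioning on concentration data narrows PS2 and KEX relative
        to their wide priors."""
        truth = baseline.replace(BW=0.250, PS2=0.80, KEX=0.0045)
        spec = default_oral_timecourse_spec(truth, sigma=0.10, seed=21)
        data, _ = gen_timecourse(spec)
        priors = default_priors("oral")
        post = run_mcmc(priors, data, baseline, n_iter=2500, burn_in=800,
                        n_chains=2, seed=31)
        summ = posterior_summary(post).set_index("parameter")
        for name in ("PS2", "KEX"):
            prior = priors.parameters[name]
            width_prior = prior.hi - prior.lo
            width_post = summ.loc[name, "hi97.5"] - summ.loc[name, "lo2.5"]
            assert width_post < width_prior


class TestPosteriorSummary:
    @staticmethod
    def _sample_set(values, n_chains=2):
        values = np.asarray(values, float)
        n = len(values)
        df = pd.DataFrame({"theta": values,
                           "chain": np.repeat(np.arange(n_chains), n // n_chains),
                           "iteration": np.tile(np.arange(n // n_chains), n_chains)})
        return PosteriorSampleSet(df, ("theta",), (0.3, 0.3), seed=0)

    def test_constant_samples(self):
        s = self._sample_set(np.full(200, 4.2))
        row = posterior_summary(s).iloc[0]
        assert row["median"] == 4.2
        assert row["lo2.5"] == row["hi97.5"] == 4.2

    def test_standard_normal_quantiles(self):
        rng = np.random.default_rng(8)
        s = self._sample_set(rng.standard_normal(100_000))
        row = posterior_summary(s).iloc[0]
        assert row["median"] == pytest.approx(0.0, abs=0.02)
        assert row["lo2.5"] == pytest.approx(-1.96, abs=0.03)
        assert row["hi97.5"] == pytest.approx(1.96, abs=0.03)
        assert row["rhat"] == pytest.approx(1.0, abs=0.01)

    def test_divergent_chains_warn(self):
        vals = np.concatenate([np.random.default_rng(0).normal(0, 1, 500),
                               np.random.default_rng(1).normal(10, 1, 500)])
        s = self._sample_set(vals)
        with pytest.warns(UserWarning, match="R-hat"):
            posterior_summary(s)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            posterior_summary(self._sample_set(np.ones(50)))


class TestPredictiveBand:
    @staticmethod
    def _draws(ps2_values, n_copies):
        rows = []
        for i, v in enumerate(np.repeat(ps2_values, n_copies)):
            rows.append({"PS2": v, "sigma": 0.1, "chain": i % 2, "iteration": i})
        return PosteriorSampleSet(pd.DataFrame(rows), ("PS2", "sigma"), (0.3, 0.3), 0)

    def test_single_draw_gives_degenerate_band(self, baseline):
        s = self._draws([0.8], 100)
        band = predictive_band(s, ExposureScenario.oral(1.0, t_end=10.0,
                                                        output_step=0.5), baseline)
        np.testing.assert_allclose(band.values[0], band.values[2], rtol=1e-12)

    def test_band_brackets_middle_curve(self, baseline):
        """cv_maa depends monotonically on PS2, so draws {0.7, 0.8, 0.9}
        produce a band whose edges bracket the middle-valued curve."""
        s = self._draws([0.7, 0.8, 0.9], 34)
        sc = ExposureScenario.oral(1.0, t_end=20.0, output_step=1.0)
        band = predictive_band(s, sc, baseline)
        from qivive.pbpk import simulate
        mid = simulate(baseline.replace(PS2=0.8), sc).cv_maa
        lo, hi = band.values[0], band.values[2]
        interior = slice(2, None)  # all curves start at ~0
        assert np.all(lo[interior] <= mid[interior] + 1e-12)
        assert np.all(mid[interior] <= hi[interior] + 1e-12)

    def test_percentiles_are_ordered(self, baseline):
        s = self._draws([0.7, 0.75, 0.85, 0.9], 30)
        band = predictive_band(s, ExposureScenario.oral(1.0, t_end=10.0,
                                                        output_step=1.0), baseline)
        assert np.all(band.values[0] <= band.values[1] + 1e-15)
        assert np.all(band.values[1] <= band.values[2] + 1e-15)
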