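"""Two-phase ABC machinery: surrogate-model oracles and PBPK smoke runs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from qivive.calibration import PriorSpec, Uniform
from qivive.reverse_dosimetry import (
    ABCConfig,
    TargetSpec,
    abc_mcmc,
    abc_scenario,
    build_proposal,
    dose_response_curves,
    filter_by_ranges,
    rejection_phase,
    relative_error,
    run_two_phase_abc,
    summarize_dose,
)
from qivive.synthetic import fixtures


# --- cheap analytic surrogate: cmax = dose * PS2-like scaling -------------

SURROGATE_PRIORS = PriorSpec({"dose": Uniform(0.2, 3.0), "scale": Uniform(0.5, 1.5)})


def surrogate_cmax(theta, names):
    v = dict(zip(names, theta))
    return v["dose"] * v["scale"]


def surrogate_target(target=1.0):
    return TargetSpec(target_cmax=target, route="oral",
                      scenario=abc_scenario("oral"))


class TestRelativeError:
    @pytest.mark.parametrize("cmax,target,expected", [
        (1.0, 1.0, 0.0),
        (1.05, 1.0, 0.05),
        (0.0, 2.0, 1.0),
    ])
    def test_definition(self, cmax, target, expected):
        assert relative_error(cmax, target) == pytest.approx(expected)

    def test_nonpositive_target(self):
        with pytest.raises(ValueError):
            relative_error(1.0, 0.0)


class TestRejectionPhase:
    def test_infinite_tolerance_accepts_everything(self):
        cfg = ABCConfig(n_reject=50, tol_reject=np.inf, tol_mcmc=1.0, seed=0)
        retained, frac = rejection_phase(surrogate_target(), SURROGATE_PRIORS,
                                         cfg, None, cmax_fn=surrogate_cmax)
        assert frac == 1.0
        assert len(retained) == 50

    def test_zero_tolerance_retains_nothing(self):
        cfg = ABCConfig(n_reject=50, tol_reject=0.0, tol_mcmc=0.0, seed=0)
        with pytest.raises(RuntimeError, match="retained 0"):
            rejection_phase(surrogate_target(), SURROGATE_PRIORS, cfg, None,
                            cmax_fn=surrogate_cmax)

    def test_reproducible_under_seed(self):
        cfg = ABCConfig(n_reject=80, seed=4)
        r1, f1 = rejection_phase(surrogate_target(), SURROGATE_PRIORS, cfg,
                                 None, cmax_fn=surrogate_cmax)
        r2, f2 = rejection_phase(surrogate_target(), SURROGATE_PRIORS, cfg,
                                 None, cmax_fn=surrogate_cmax)
        assert f1 == f2
        pd.testing.assert_frame_equal(r1, r2)


class TestBuildProposal:
    def test_mvn_recovery(self):
        rng = np.random.default_rng(3)
        mu = np.array([1.0, -2.0])
        cov = np.array([[0.5, 0.2], [0.2, 0.8]])
        X = rng.multivariate_normal(mu, cov, size=10_000)
        df = pd.DataFrame(X, columns=["dose", "scale"])
        m, C = build_proposal(df, ("dose", "scale"))
        np.testing.assert_allclose(m, mu, atol=0.03)
        np.testing.assert_allclose(C, cov, atol=0.05)

    def test_degenerate_samples_get_jitter(self):
        df = pd.DataFrame({"dose": np.ones(20), "scale": np.ones(20)})
        with pytest.warns(UserWarning):
            _, C = build_proposal(df, ("dose", "scale"))
        np.linalg.cholesky(C)  # positive definite after jitter

    def test_too_few_samples(self):
        df = pd.DataFrame({"dose": [1.0, 2.0], "scale": [1.0, 2.0]})
        with pytest.raises(RuntimeError, match="at least"):
            build_proposal(df, ("dose", "scale"))


class TestAbcMcmc:
    def _rejection(self, cfg):
        return rejection_phase(surrogate_target(), SURROGATE_PRIORS, cfg, None,
                               cmax_fn=surrogate_cmax)

    def test_zero_proposal_scale_freezes_chain(self):
        cfg = ABCConfig(n_reject=100, retained_per_chain=30, n_chains=2,
                        proposal_scale=0.0, seed=1)
        retained, _ = self._rejection(cfg)
        proposal = build_proposal(retained, SURROGATE_PRIORS.names)
        pooled, _ = abc_mcmc(surrogate_target(), SURROGATE_PRIORS, proposal,
                             cfg, None, retained, cmax_fn=surrogate_cmax)
        for _, chain in pooled.groupby("chain"):
            assert chain["dose"].nunique() == 1

    def test_matches_plain_rejection_sampling(self):
        """Distributional oracle: pooled ABC-MCMC draws at 5% tolerance are
        indistinguishable (two-sample KS per margin) from direct rejection
        sampling at the same tolerance on the analytic surrogate."""
        cfg = ABCConfig(n_reject=400, retained_per_chain=1500, n_chains=2,
                        tol_mcmc=0.05, seed=12)
        retained, _ = self._rejection(cfg)
        proposal = build_proposal(retained, SURROGATE_PRIORS.names)
        pooled, acc = abc_mcmc(surrogate_target(), SURROGATE_PRIORS, proposal,
                               cfg, None, retained, cmax_fn=surrogate_cmax)
        # oracle: direct rejection sampling at tol_mcmc
        rng = np.random.default_rng(99)
        oracle = {"dose": [], "scale": []}
        while len(oracle["dose"]) < 3000:
            dose = rng.uniform(0.2, 3.0)
            scale = rng.uniform(0.5, 1.5)
            if abs(dose * scale - 1.0) <= 0.05:
                oracle["dose"].append(dose)
                oracle["scale"].append(scale)
        for margin in ("dose", "scale"):
            x = pooled[margin].to_numpy()[::5]  # thin to reduce autocorrelation
            ks = stats.ks_2samp(x, np.asarray(oracle[margin]))
            assert ks.pvalue > 0.01, f"{margin}: KS p={ks.pvalue}"

    def test_tightening_tolerance_nests_dose_interval(self):
        cfg5 = ABCConfig(n_reject=400, retained_per_chain=800, tol_mcmc=0.05, seed=3)
        cfg25 = ABCConfig(n_reject=400, retained_per_chain=800, tol_mcmc=0.025, seed=3)
        out = {}
        for cfg in (cfg5, cfg25):
            retained, _ = self._rejection(cfg)
            proposal = build_proposal(retained, SURROGATE_PRIORS.names)
            pooled, _ = abc_mcmc(surrogate_target(), SURROGATE_PRIORS, proposal,
                                 cfg, None, retained, cmax_fn=surrogate_cmax)
            s = summarize_dose(pooled)
            out[cfg.tol_mcmc] = s["dose_hi"] - s["dose_lo"]
        assert out[0.025] <= out[0.05] * 1.05

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            ABCConfig(tol_reject=0.05, tol_mcmc=0.075)
        with pytest.raises(ValueError):
            ABCConfig(thin=0)


class TestFiltering:
    @pytest.fixture
    def samples(self):
        rng = np.random.default_rng(0)
        return pd.DataFrame({
            "dose": rng.uniform(0, 1, 500),
            "PS2": rng.uniform(0.30, 1.35, 500),
            "KEX": rng.uniform(0.0015, 0.0075, 500),
        })

    def test_prior_support_is_identity(self, samples):
        out = filter_by_ranges(samples, {"PS2": (0.30, 1.35), "KEX": (0.0015, 0.0075)})
        assert len(out) == len(samples)

    def test_out_of_range_sample_excluded(self, samples):
        f = fixtures()
        oral = {k: v for k, v in f.calibrated_ranges["oral"].items()
                if k in ("PS2", "KEX")}
        row = pd.DataFrame([{"dose": 0.5, "PS2": 0.90, "KEX": 0.0040}])
        out = filter_by_ranges(row, oral)
        assert len(out) == 0  # PS2 = 0.90 outside the oral interval

    def test_empty_result_warns_and_summary_refuses(self, samples):
        with pytest.warns(UserWarning, match="every sample"):
            out = filter_by_ranges(samples, {"PS2": (2.0, 3.0)})
        assert len(out) == 0
        with pytest.raises(ValueError):
            summarize_dose(out)

    def test_missing_column_raises(self, samples):
        with pytest.raises(KeyError):
            filter_by_ranges(samples, {"QPC": (10, 20)})


class TestSummaries:
    def test_equal_doses(self):
        df = pd.DataFrame({"dose": np.full(10, 2.5)})
        s = summarize_dose(df)
        assert s["dose_median"] == s["dose_lo"] == s["dose_hi"] == 2.5

    def test_uniform_quantiles(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"dose": rng.uniform(0, 1, 100_000)})
        s = summarize_dose(df)
        assert s["dose_median"] == pytest.approx(0.5, abs=0.01)
        assert s["dose_lo"] == pytest.approx(0.025, abs=0.01)
        assert s["dose_hi"] == pytest.approx(0.975, abs=0.01)


class TestDoseResponseCurves:
    def test_single_sample_per_target(self):
        pooled = {0.28: pd.DataFrame({"dose": [0.2]}),
                  0.55: pd.DataFrame({"dose": [0.5]})}
        df = dose_response_curves(pooled)
        assert df.loc[df.target_mM == 0.28, "p50"].item() == 0.2

    def test_rank_pairing_preserves_marginals(self):
        rng = np.random.default_rng(5)
        pooled = {t: pd.DataFrame({"dose": rng.gamma(2.0, t, 400)})
                  for t in (0.28, 0.55, 1.11)}
        df = dose_response_curves(pooled)
        for t in pooled:
            doses = pooled[t]["dose"].to_numpy()
            row = df[df.target_mM == t].iloc[0]
            assert row["p50"] == pytest.approx(np.quantile(doses, 0.5), rel=1e-12)
            assert row["p2.5"] == pytest.approx(np.quantile(doses, 0.025), rel=1e-12)

    def test_unequal_counts_warn_and_subsample(self):
        pooled = {0.28: pd.DataFrame({"dose": np.arange(10.0)}),
                  0.55: pd.DataFrame({"dose": np.arange(20.0)})}
        with pytest.warns(UserWarning, match="unequal"):
            df = dose_response_curves(pooled)
        assert len(df) == 2


class TestPbpkEndToEnd:
    """Scaled-down two-phase ABC against the real PBPK model."""

    @pytest.fixture(scope="class")
    def small_run(self, baseline):
        cfg = ABCConfig(n_reject=80, retained_per_chain=120, seed=17)
        return run_two_phase_abc(0.28, "oral", cfg, baseline)

    def test_all_samples_within_tolerance(self, small_run):
        pooled = small_run["pooled"]
        assert np.all(pooled["rel_error"] <= 0.05 + 1e-12)
        assert np.all(pooled["dose"] > 0)

    def test_round_trip_audit(self, small_run, baseline):
        """Re-simulating stored parameter vectors reproduces the stored
        Cmax to solver precision."""
        from qivive.reverse_dosimetry import _simulate_cmax
        pooled = small_run["pooled"]
        names = tuple(small_run["priors"].names)
        sc = abc_scenario("oral")
        for _, row in pooled.sample(4, random_state=1).iterrows():
            theta = row[list(names)].to_numpy(float)
            cmax = _simulate_cmax(baseline, sc, theta, names)
            assert cmax == pytest.approx(row["cmax_mM"], rel=1e-6)

    def test_posterior_dose_near_forward_inversion(self, small_run):
        """The posterior dose for the lowest target concentrates around the
        deterministic forward-dosimetry dose d0."""
        s = summarize_dose(small_run["pooled"])
        d0 = small_run["d0"]
        assert 0.7 * d0 < s["dose_median"] < 1.5 * d0
        assert s["dose_lo"] < d0 < s["dose_hi"]
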