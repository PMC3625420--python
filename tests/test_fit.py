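"""Bayesian fitting: likelihood/prior composition, sampler vs grid oracle."""

import numpy as np
import pytest

import beepsych as bp
from beepsych.fit import GridResolutionError, PriorSpec

# 50-digit term-by-term summation oracle for the log posterior on the
# small_dataset fixture (records (0.2,30,50),(0.4,44,50),(0.6,47,50)),
# study priors, full normal/beta density constants:
LP_AT_A = -69.5236328354136787  # params (m=0.25, s=5, pi=0.15)
LP_AT_B = -76.7242638291553240  # params (m=0.40, s=3, pi=0.30)


def _mc_se(summary):
    """Monte-Carlo standard error per parameter from draws and ESS."""
    ess = summary.diagnostics["ess"]
    draws = summary.draws
    return {
        name: draws[:, i].std() / np.sqrt(max(ess[name], 1.0))
        for i, name in enumerate(("threshold", "slope", "lapse"))
    }


class TestLogPosterior:
    def test_matches_high_precision_summation(self, small_dataset):
        priors = PriorSpec()
        a = bp.log_posterior(bp.PsychometricParams(0.25, 5.0, 0.15), small_dataset, priors)
        b = bp.log_posterior(bp.PsychometricParams(0.40, 3.0, 0.30), small_dataset, priors)
        assert a == pytest.approx(LP_AT_A, abs=1e-9)
        assert b == pytest.approx(LP_AT_B, abs=1e-9)
        assert a - b == pytest.approx(LP_AT_A - LP_AT_B, abs=1e-9)

    def test_single_trial_binomial_term(self):
        # one miss at x = m: the data contribute ln(1 - 0.75) = ln 0.25
        data = [bp.ResponseRecord(1.0, 0, 1)]
        priors = PriorSpec(lapse_a=1.0)  # beta(1,20) has support at pi -> 0
        params = (1.0, 2.0, 1e-12)
        with_like = bp.log_posterior(params, data, priors)
        prior_only = bp.log_posterior(params, data, priors, likelihood_weight=0.0)
        assert with_like - prior_only == pytest.approx(np.log(0.25), abs=1e-6)

    def test_outside_support_is_minus_inf_not_exception(self, small_dataset):
        priors = PriorSpec()
        assert bp.log_posterior((0.25, 5.0, 1.0), small_dataset, priors) == -np.inf
        assert bp.log_posterior((-0.1, 5.0, 0.1), small_dataset, priors) == -np.inf
        assert bp.log_posterior((0.25, -2.0, 0.1), small_dataset, priors) == -np.inf

    def test_flat_slope_prior_truncates_at_maximum(self, small_dataset):
        priors = PriorSpec(slope_flat=True, slope_max=50.0)
        assert np.isfinite(bp.log_posterior((0.25, 49.0, 0.1), small_dataset, priors))
        assert bp.log_posterior((0.25, 51.0, 0.1), small_dataset, priors) == -np.inf

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            bp.log_posterior((0.25, 5.0, 0.1), [], PriorSpec())


class TestFitPsychometric:
    def test_seed_determinism(self, small_dataset, fast_mcmc):
        a = bp.fit_psychometric(small_dataset, config=fast_mcmc)
        b = bp.fit_psychometric(small_dataset, config=fast_mcmc)
        assert np.array_equal(a.draws, b.draws)
        assert a.threshold == b.threshold

    def test_different_seeds_differ(self, small_dataset):
        a = bp.fit_psychometric(small_dataset, config=bp.McmcConfig(n_draws=1000, seed=1))
        b = bp.fit_psychometric(small_dataset, config=bp.McmcConfig(n_draws=1000, seed=2))
        assert not np.array_equal(a.draws, b.draws)

    def test_summary_structure(self, small_dataset, fast_mcmc):
        s = bp.fit_psychometric(small_dataset, config=fast_mcmc)
        assert s.draws.shape == (fast_mcmc.n_draws, 3)
        for est in (s.threshold, s.slope, s.lapse):
            assert est.ci_low <= est.mean <= est.ci_high
        assert np.all(s.draws[:, 0] > 0)
        assert np.all(s.draws[:, 1] > 0)
        assert np.all((s.draws[:, 2] > 0) & (s.draws[:, 2] < 1))
        assert 0.05 < s.diagnostics["acceptance_fraction"] < 0.95

    def test_parameter_recovery_within_credible_intervals(self):
        true = bp.PsychometricParams(0.25, 5.0, 0.15)
        xs = [0.05, 0.15, 0.25, 0.3, 0.4, 0.5, 0.6]
        hits = np.zeros(3)
        n_rep = 5
        for rep in range(n_rep):
            data = bp.generate_binomial_responses(true, xs, 2000, seed=rep)
            s = bp.fit_psychometric(data, config=bp.McmcConfig(n_draws=1500, seed=rep))
            for i, (est, tv) in enumerate(
                zip((s.threshold, s.slope, s.lapse), (0.25, 5.0, 0.15))
            ):
                hits[i] += est.ci_low <= tv <= est.ci_high
        # majority coverage on a handful of replicates; the full calibration
        # runs in the acceptance suite
        assert np.all(hits >= n_rep - 1)

    def test_uninformative_responses_leave_prior_in_charge(self):
        data = [bp.ResponseRecord(x, 50, 100) for x in (0.1, 0.2, 0.3, 0.4, 0.6)]
        s = bp.fit_psychometric(data, config=bp.McmcConfig(n_draws=2000, seed=5))
        assert 0.6 < s.threshold.mean < 2.2
        assert s.threshold.ci_high - s.threshold.ci_low > 0.4

    def test_prior_recovery_with_likelihood_disabled(self, small_dataset):
        s = bp.fit_psychometric(
            small_dataset,
            config=bp.McmcConfig(n_draws=4000, seed=6),
            likelihood_weight=0.0,
        )
        se = _mc_se(s)
        # truncated-normal and beta prior means
        assert abs(s.threshold.mean - 1.0276) < max(4 * se["threshold"], 0.08)
        assert abs(s.slope.mean - 2.0552) < max(4 * se["slope"], 0.16)
        assert abs(s.lapse.mean - 2.0 / 22.0) < max(4 * se["lapse"], 0.01)

    def test_single_intensity_flags_prior_dominated(self):
        data = [bp.ResponseRecord(0.3, 40, 50)]
        with pytest.warns(UserWarning, match="distinct intensity"):
            s = bp.fit_psychometric(data, config=bp.McmcConfig(n_draws=800, seed=7))
        assert s.diagnostics.get("prior_dominated") is True

    def test_csv_round_trip(self, small_dataset, tmp_path):
        path = tmp_path / "responses.csv"
        bp.write_response_csv(small_dataset, path)
        assert bp.read_response_csv(path) == small_dataset


class TestGridOracle:
    def test_grid_is_deterministic(self, small_dataset):
        a = bp.grid_posterior(small_dataset)
        b = bp.grid_posterior(small_dataset)
        assert a.threshold == b.threshold and a.slope == b.slope

    def test_mcmc_matches_grid_within_monte_carlo_error(self, small_dataset):
        g = bp.grid_posterior(small_dataset)
        for seed in (1, 2):
            s = bp.fit_psychometric(small_dataset, config=bp.McmcConfig(n_draws=2500, seed=seed))
            se = _mc_se(s)
            assert abs(s.threshold.mean - g.threshold.mean) < 3 * se["threshold"] + 0.01
            assert abs(s.slope.mean - g.slope.mean) < 3 * se["slope"] + 0.03
            assert abs(s.lapse.mean - g.lapse.mean) < 3 * se["lapse"] + 0.005

    def test_flat_slope_prior_agreement(self, small_dataset):
        priors = PriorSpec(slope_flat=True, slope_max=20.0)
        g = bp.grid_posterior(small_dataset, priors)
        # the flat-prior slope posterior is heavy-tailed; the chain needs
        # more draws than the informative-prior fits to pin its mean
        s = bp.fit_psychometric(small_dataset, priors, bp.McmcConfig(n_draws=8000, seed=9))
        se = _mc_se(s)
        assert abs(s.slope.mean - g.slope.mean) < 3 * se["slope"] + 0.05

    def test_sharply_peaked_prior_returns_prior_mean(self):
        data = [bp.ResponseRecord(0.3, 1, 2)]
        priors = PriorSpec(threshold_sd=0.01, slope_sd=0.01)
        g = bp.grid_posterior(
            data,
            priors,
            grid={
                "threshold": (0.8, 1.2, 160),
                "slope": (1.8, 2.2, 160),
                "lapse": (1e-5, 0.999, 120),
            },
        )
        assert g.threshold.mean == pytest.approx(1.0, abs=0.005)
        assert g.slope.mean == pytest.approx(2.0, abs=0.005)

    def test_coarse_grid_raises_resolution_error(self):
        data = [
            bp.ResponseRecord(0.25, 7200, 10000),
            bp.ResponseRecord(0.5, 8700, 10000),
            bp.ResponseRecord(0.1, 5300, 10000),
        ]
        with pytest.raises(GridResolutionError):
            bp.grid_posterior(
                data,
                grid={
                    "threshold": (1e-4, 3.5, 12),
                    "slope": (1e-3, 7.0, 12),
                    "lapse": (1e-5, 0.999, 10),
                },
            )
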