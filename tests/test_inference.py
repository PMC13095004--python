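"""Posterior inference: conjugate oracle, MH sampler, summaries, diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from otocost import (
    BetaPseudoCounts,
    BinomialObservation,
    EvidenceRecord,
    MCMCConfig,
    ProbabilitySamples,
    beta_quantile,
    conjugate_posterior,
    derive_subseed,
    mcmc_diagnostics,
    mh_sample,
    summarize_samples,
)


class TestConjugatePosterior:
    @pytest.mark.parametrize(
        "prior, obs, expected",
        [
            ((58, 91), (26, 63), (84, 154)),
            ((1, 1), (0, 0), (1, 1)),
            ((10, 91), (1, 16), (11, 107)),
            ((4, 176), (2, 89), (6, 265)),
        ],
    )
    def test_adds_pseudo_counts(self, prior, obs, expected):
        post = conjugate_posterior(BetaPseudoCounts(*prior), BinomialObservation(*obs))
        assert (post.alpha, post.beta) == expected

    def test_rejects_nonpositive_prior(self):
        with pytest.raises(ValueError):
            BetaPseudoCounts(0.0, 1.0)
        with pytest.raises(ValueError):
            BetaPseudoCounts(1.0, -2.0)

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            BinomialObservation(-1, 5)


class TestBetaQuantile:
    @pytest.mark.parametrize(
        "params, q, expected, tol",
        [
            ((1, 1), 0.5, 0.5, 1e-12),  # uniform median
            ((84, 154), 0.5, 0.3525, 5e-4),
            ((11, 107), 0.5, 0.0909, 5e-4),
        ],
    )
    def test_known_quantiles(self, params, q, expected, tol):
        assert beta_quantile(BetaPseudoCounts(*params), q) == pytest.approx(
            expected, abs=tol
        )

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.1, 1.5])
    def test_rejects_out_of_range_level(self, q):
        with pytest.raises(ValueError):
            beta_quantile(BetaPseudoCounts(2, 3), q)


class TestMHSampler:
    def test_deterministic_for_fixed_seed(self, evidence):
        cfg = MCMCConfig(seed=42)
        a = mh_sample(evidence["P4"], cfg)
        b = mh_sample(evidence["P4"], cfg)
        np.testing.assert_array_equal(a.values, b.values)

    def test_sample_count_and_range(self, evidence):
        cfg = MCMCConfig(iterations=4000, burn_in=1000, seed=7)
        s = mh_sample(evidence["P6"], cfg)
        assert len(s) == 3000
        assert np.all(s.values > 0) and np.all(s.values < 1)

    def test_uniform_posterior_with_no_data(self):
        rec = EvidenceRecord("flat", BinomialObservation(0, 0), BetaPseudoCounts(1, 1))
        summary = summarize_samples(mh_sample(rec, MCMCConfig(seed=3)))
        assert summary.median == pytest.approx(0.5, abs=0.02)

    def test_rejects_bad_config(self):
        with pytest.raises(ValueError):
            MCMCConfig(proposal_sd=0.0)
        with pytest.raises(ValueError):
            MCMCConfig(iterations=100, burn_in=100)

    @pytest.mark.parametrize("seed", range(10))
    def test_median_matches_conjugate_oracle_across_seeds(self, evidence, seed):
        """MH sample median tracks the closed-form beta median to < 0.005."""
        rec = evidence["P4"]
        oracle = beta_quantile(
            conjugate_posterior(rec.prior, rec.obs), 0.5
        )
        s = mh_sample(rec, MCMCConfig(seed=derive_subseed(seed, "P4")))
        assert abs(float(np.median(s.values)) - oracle) < 0.005

    @pytest.mark.parametrize(
        "label", ["P1", "P2", "P3", "P4", "P5", "P5_noninformative", "P6"]
    )
    def test_distribution_matches_conjugate(self, evidence, label):
        """Two-sample KS distance between the chain and i.i.d. conjugate draws < 0.05."""
        rec = evidence[label]
        post = conjugate_posterior(rec.resolve_prior(), rec.obs)
        s = mh_sample(rec, MCMCConfig(seed=derive_subseed(11, label)))
        iid = stats.beta.rvs(
            post.alpha, post.beta, size=len(s), random_state=np.random.default_rng(99)
        )
        ks = stats.ks_2samp(s.values, iid).statistic
        assert ks < 0.05

    @pytest.mark.parametrize(
        "label", ["P1", "P2", "P3", "P4", "P5", "P5_noninformative", "P6"]
    )
    def test_acceptance_rate_in_working_band(self, evidence, label):
        s = mh_sample(evidence[label], MCMCConfig(seed=derive_subseed(5, label)))
        assert 0.1 < s.acceptance_rate < 0.9


class TestNoninformativePriors:
    def test_jeffreys_default_and_uniform_option(self, evidence):
        rec = evidence["P5_noninformative"]
        assert rec.resolve_prior() == BetaPseudoCounts(0.5, 0.5)
        assert rec.resolve_prior("uniform") == BetaPseudoCounts(1, 1)

    def test_low_risk_medians_under_both_priors(self, evidence):
        """Jeffreys gives ~0.178, uniform ~0.186 for the low-risk record."""
        rec = evidence["P5_noninformative"]
        jef = beta_quantile(conjugate_posterior(rec.resolve_prior("jeffreys"), rec.obs), 0.5)
        uni = beta_quantile(conjugate_posterior(rec.resolve_prior("uniform"), rec.obs), 0.5)
        assert round(jef, 2) == 0.18
        assert jef < uni


class TestSummaries:
    def test_degenerate_constant_samples(self):
        s = ProbabilitySamples(values=np.full(100, 0.3), acceptance_rate=0.0)
        summary = summarize_samples(s)
        assert (summary.median, summary.ci_low, summary.ci_high) == (0.3, 0.3, 0.3)

    def test_equal_tailed_interval_from_conjugate_draws(self):
        rng = np.random.default_rng(0)
        draws = stats.beta.rvs(84, 154, size=20_000, random_state=rng)
        summary = summarize_samples(ProbabilitySamples(draws, 1.0))
        assert summary.median == pytest.approx(0.3525, abs=0.005)
        assert summary.ci_low == pytest.approx(beta_quantile(BetaPseudoCounts(84, 154), 0.025), abs=0.01)
        assert summary.ci_high == pytest.approx(beta_quantile(BetaPseudoCounts(84, 154), 0.975), abs=0.01)

    def test_informative_low_risk_median(self):
        rng = np.random.default_rng(1)
        draws = stats.beta.rvs(11, 53, size=20_000, random_state=rng)
        assert summarize_samples(ProbabilitySamples(draws, 1.0)).median == pytest.approx(
            0.17, abs=0.01
        )

    def test_empty_samples_raise(self):
        with pytest.raises(RuntimeError):
            summarize_samples(ProbabilitySamples(np.array([]), 0.0))

    @given(st.lists(st.floats(0.01, 0.99), min_size=2, max_size=200))
    @settings(deadline=None, max_examples=50)
    def test_ordering_invariant(self, values):
        s = summarize_samples(ProbabilitySamples(np.array(values), 0.5))
        assert s.ci_low <= s.median <= s.ci_high


class TestDiagnostics:
    def test_iid_samples_have_no_autocorrelation(self):
        rng = np.random.default_rng(2)
        s = ProbabilitySamples(rng.uniform(0.2, 0.8, size=5000), 1.0)
        d = mcmc_diagnostics(s)
        assert abs(d.autocorrelation[1]) < 0.05
        assert not d.degenerate
        assert d.ess <= d.n_samples

    def test_all_rejected_chain_flagged_degenerate(self):
        s = ProbabilitySamples(np.full(500, 0.4), 0.0)
        d = mcmc_diagnostics(s)
        assert d.degenerate
        assert d.acceptance_rate == 0.0
        assert d.ess == 0.0

    def test_default_run_has_usable_ess(self, evidence):
        s = mh_sample(evidence["P4"], MCMCConfig(seed=derive_subseed(1, "P4")))
        d = mcmc_diagnostics(s)
        assert d.ess > 500


class TestParameterRecovery:
    def test_large_synthetic_trial_recovers_truth(self):
        """With n = 10,000 observations, the posterior median lands within 0.02."""
        from otocost import SyntheticTrialSpec, simulate_trial_counts

        true_p = 0.35
        obs = simulate_trial_counts(SyntheticTrialSpec(true_p, 10_000, seed=8))
        rec = EvidenceRecord("synthetic", obs, None)
        summary = summarize_samples(mh_sample(rec, MCMCConfig(seed=9)))
        assert abs(summary.median - true_p) < 0.02
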