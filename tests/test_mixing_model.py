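"""Concentration-dependent mixing model: means, variances, posterior, MCMC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleowean.mixing_model import (
    MixingConfig,
    fit_mixing,
    kde_mode,
    log_posterior,
    mixture_mean,
    mixture_variance,
    posterior_mode_ci,
)
from paleowean.source_model import SourceSpec
from paleowean.synthetic_data import simulate_mixture_consumers


def _source(name="s", mu_N=5.0, mu_C=-20.0, sd=1.0, conc_N=2.0, conc_C=40.0,
            frac_N=3.0, frac_C=4.0, sd_frac=0.2):
    return SourceSpec(name, mu_N, sd, mu_C, sd, conc_N, 0.1, conc_C, 1.0,
                      frac_N, sd_frac, frac_C, sd_frac)


class TestMixtureMean:
    def test_pure_milk_nitrogen(self, all_sources):
        # single-source mixture: mean is just μ + Δ for the milk row
        m = mixture_mean([1, 0, 0, 0], all_sources, "N")
        milk = all_sources[0]
        assert m == pytest.approx(milk.mu_N + milk.frac_N)
        assert m == pytest.approx(11.81, abs=0.01)

    def test_pure_root_cultigens_carbon(self, all_sources):
        m = mixture_mean([0, 1, 0, 0], all_sources, "C")
        assert m == pytest.approx(-22.45 + 4.40)

    def test_equal_concentrations_reduce_to_plain_average(self):
        sources = [_source(mu_N=a, conc_N=3.0) for a in (2.0, 6.0, 10.0)]
        m = mixture_mean([1 / 3] * 3, sources, "N")
        assert m == pytest.approx(np.mean([2.0, 6.0, 10.0]) + 3.0)

    @settings(derandomize=True, max_examples=40)
    @given(
        p0=st.floats(0.05, 0.9), scale=st.floats(0.1, 10.0),
    )
    def test_invariant_to_common_concentration_rescaling(self, all_sources, p0, scale):
        p = [p0, (1 - p0) * 0.5, (1 - p0) * 0.3, (1 - p0) * 0.2]
        scaled = [
            SourceSpec(
                s.name, s.mu_N, s.sd_N, s.mu_C, s.sd_C,
                min(s.conc_N * scale, 100.0), s.sd_conc_N,
                min(s.conc_C * scale, 100.0) if scale <= 1 else s.conc_C,
                s.sd_conc_C, s.frac_N, s.sd_frac_N, s.frac_C, s.sd_frac_C,
            )
            for s in all_sources
        ]
        if scale <= 1:  # rescaling both isotopes only stays in-range downward
            assert mixture_mean(p, scaled, "N") == pytest.approx(
                mixture_mean(p, all_sources, "N")
            )

    def test_off_simplex_rejected(self, all_sources):
        with pytest.raises(ValueError):
            mixture_mean([0.5, 0.5, 0.5, -0.5], all_sources, "N")
        with pytest.raises(ValueError):
            mixture_mean([0.5, 0.1, 0.1, 0.1], all_sources, "N")


class TestMixtureVariance:
    def test_pure_milk_nitrogen(self, all_sources):
        v = mixture_variance([1, 0, 0, 0], all_sources, "N", residual_sd=0.0)
        milk = all_sources[0]
        assert v == pytest.approx(milk.sd_N**2 + milk.sd_frac_N**2)
        assert v == pytest.approx(1.4282, abs=0.01)

    def test_zero_source_sds_leave_only_residual(self):
        sources = [_source(sd=0.0, sd_frac=0.0) for _ in range(2)]
        v = mixture_variance([0.5, 0.5], sources, "N", residual_sd=1.3)
        assert v == pytest.approx(1.3**2)

    def test_splitting_mass_between_identical_sources_halves_source_term(self):
        s = _source(sd=1.0, sd_frac=0.0)
        single = mixture_variance([1.0, 0.0], [s, s], "N")
        split = mixture_variance([0.5, 0.5], [s, s], "N")
        assert split == pytest.approx(0.5 * single)


class TestLogPosterior:
    def test_matches_term_by_term_oracle(self, all_sources):
        """Independent re-evaluation: normal densities + Dirichlet and
        half-normal priors with the sampling-coordinate Jacobians."""
        p = np.array([0.4, 0.3, 0.2, 0.1])
        sig = (0.8, 1.2)
        data = [(11.0, -16.0), (9.5, -18.5), (12.2, -15.1)]
        cfg = MixingConfig(dirichlet_alpha=1.0, residual_sd_prior_scale=5.0)

        expected = 0.0
        for j, iso in enumerate(("N", "C")):
            m = mixture_mean(p, all_sources, iso)
            v = mixture_variance(p, all_sources, iso, residual_sd=sig[j])
            for row in data:
                expected += -0.5 * math.log(2 * math.pi * v) - (row[j] - m) ** 2 / (2 * v)
        expected += float(np.sum(np.log(p)))  # ALR Jacobian (Dirichlet(1) kernel is flat)
        for s in sig:
            expected += -0.5 * (s / 5.0) ** 2 + math.log(s)  # half-normal + log-σ Jacobian

        assert log_posterior(p, sig, data, all_sources, cfg) == pytest.approx(expected)

    def test_symmetric_two_source_problem(self):
        a = _source(mu_N=4.0, mu_C=-22.0, frac_N=0.0, frac_C=0.0, sd_frac=0.0)
        b = _source(mu_N=8.0, mu_C=-18.0, frac_N=0.0, frac_C=0.0, sd_frac=0.0)
        data = [(6.0, -20.0)]  # exactly at the midpoint
        lp1 = log_posterior([0.3, 0.7], (1.0, 1.0), data, [a, b])
        lp2 = log_posterior([0.7, 0.3], (1.0, 1.0), data, [a, b])
        assert lp1 == pytest.approx(lp2)

    def test_invalid_inputs_rejected(self, all_sources):
        with pytest.raises(ValueError):
            log_posterior([0.5, 0.5, 0.0, -0.0001], (1, 1), [(10, -18)], all_sources)
        with pytest.raises(ValueError):
            log_posterior([0.25] * 4, (0.0, 1.0), [(10, -18)], all_sources)
        with pytest.raises(ValueError):
            log_posterior([0.25] * 4, (1.0, 1.0), [], all_sources)


class TestFitMixing:
    def test_draws_stay_on_simplex(self, all_sources, small_mixing_config, groups):
        post = fit_mixing(groups["G3"], all_sources, small_mixing_config, "G3")
        assert np.all(post.draws >= 0)
        assert np.allclose(post.draws.sum(axis=1), 1.0, atol=1e-8)
        assert np.all(post.lci_pct <= post.hci_pct)

    def test_deterministic_given_seed(self, all_sources, small_mixing_config):
        data = [(11.0, -16.0), (9.5, -18.5), (12.2, -15.1), (10.1, -17.0)]
        a = fit_mixing(data, all_sources, small_mixing_config)
        b = fit_mixing(data, all_sources, small_mixing_config)
        assert np.array_equal(a.draws, b.draws)
        assert np.array_equal(a.mode_pct, b.mode_pct)

    def test_parameter_recovery_posterior_mean(self, all_sources):
        truth = np.array([0.7, 0.1, 0.1, 0.1])
        data = simulate_mixture_consumers(truth, all_sources, 50, (0.5, 0.5), seed=5)
        cfg = MixingConfig(n_iterations=12000, n_burn=6000, thin=3, n_chains=4, rng_seed=11)
        post = fit_mixing(data, all_sources, cfg)
        assert np.all(np.abs(post.draws.mean(axis=0) - truth) < 0.1)

    def test_identical_sources_sum_constrained(self, small_mixing_config):
        s = _source(mu_N=8.0, mu_C=-16.0, sd=0.5, sd_frac=0.0)
        t = _source(name="t", mu_N=2.0, mu_C=-24.0, sd=0.5, sd_frac=0.0)
        rng = np.random.default_rng(3)
        data = np.column_stack([rng.normal(9.5, 0.3, 25), rng.normal(-17.2, 0.3, 25)])
        post = fit_mixing(data, [s, s, t], small_mixing_config)
        pair_sum = post.draws[:, 0] + post.draws[:, 1]
        # individual proportions are unidentifiable but their sum is pinned
        assert post.draws[:, 0].std() > 0.5 * pair_sum.std()
        assert pair_sum.std() < 0.15

    def test_needs_two_sources(self, all_sources):
        with pytest.raises(ValueError):
            fit_mixing([(10.0, -18.0)], all_sources[:1])


class TestPosteriorModeCI:
    def test_constant_draws(self):
        mode, lo, hi = posterior_mode_ci(np.full(500, 0.4))
        assert (mode, lo, hi) == (40, 40, 40)

    def test_beta_draws_match_analytic_mode(self):
        rng = np.random.default_rng(12345)
        draws = rng.beta(2, 5, size=100_000)
        mode, lo, hi = posterior_mode_ci(draws)
        assert abs(mode / 100 - 0.2) <= 0.02
        assert lo / 100 == pytest.approx(float(np.percentile(draws, 2.5)), abs=0.01)
        assert hi / 100 == pytest.approx(float(np.percentile(draws, 97.5)), abs=0.01)

    def test_boundary_piling_reports_zero_lci(self):
        rng = np.random.default_rng(6)
        draws = np.abs(rng.normal(0, 0.05, size=5000)).clip(0, 1)
        mode, lo, hi = posterior_mode_ci(draws)
        assert lo == 0 and 0 <= mode <= 10

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            posterior_mode_ci(np.linspace(0, 1, 50))

    def test_kde_mode_interior_peak(self):
        rng = np.random.default_rng(9)
        draws = rng.normal(0.6, 0.05, size=20_000).clip(0, 1)
        assert kde_mode(draws) == pytest.approx(0.6, abs=0.02)
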