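"""Weaning trajectory model, turnover ODE and rejection-ABC inversion."""

import numpy as np
import pytest

from paleowean.synthetic_data import SyntheticCohortSpec, simulate_juvenile_cohort
from paleowean.warn_model import (
    ABCConfig,
    TurnoverModel,
    WeaningParams,
    collagen_trajectory,
    diet_d15N,
    fit_warn_abc,
    posterior_density_mde,
    warn_distance,
)

MDE_PARAMS = WeaningParams(1.7, 2.8, 1.0, 7.4, 10.91)


class TestDietSignal:
    def test_exclusive_breastfeeding_plateau(self):
        assert diet_d15N(MDE_PARAMS, 0.0) == pytest.approx(11.91)
        assert diet_d15N(MDE_PARAMS, 1.7) == pytest.approx(11.91)

    def test_weaned_plateau(self):
        assert diet_d15N(MDE_PARAMS, 2.8) == pytest.approx(7.4)
        assert diet_d15N(MDE_PARAMS, 5.0) == pytest.approx(7.4)

    def test_linear_midpoint(self):
        mid = (1.7 + 2.8) / 2
        assert diet_d15N(MDE_PARAMS, mid) == pytest.approx((11.91 + 7.4) / 2)

    def test_inverted_interval_rejected(self):
        with pytest.raises(ValueError):
            WeaningParams(3.0, 2.0, 1.0, 7.4, 10.91)


class TestTrajectory:
    def test_constant_diet_constant_rate_matches_closed_form(self):
        """With r(t)=r and flat diet D the ODE has the exact solution
        D + (δ0 − D)·exp(−rt); RK4 at the default step must agree to 1e-6."""
        r = 1.7
        turn = TurnoverModel(r0=r, r_inf=r, tau=1.0)
        # weaning starts far beyond the age span, so the diet is the constant
        # breastfeeding plateau female + enrich = 14 throughout
        params = WeaningParams(10.0, 11.0, 4.0, 6.0, 10.0)
        ages = np.array([0.25, 0.5, 1.0])
        got = collagen_trajectory(params, turn, ages)
        expected = 14.0 + (10.0 - 14.0) * np.exp(-r * ages)
        assert np.allclose(got, expected, atol=1e-6)

    def test_fast_turnover_tracks_diet(self):
        turn = TurnoverModel(r0=1000.0, r_inf=1000.0, tau=1.0)
        ages = np.array([0.1, 0.5, 1.0, 2.0, 3.5])
        got = collagen_trajectory(MDE_PARAMS, turn, ages, ode_step=0.001)
        diet = diet_d15N(MDE_PARAMS, ages)
        assert np.allclose(got, diet, atol=1e-2)

    def test_rise_then_fall_shape(self):
        """Trajectory climbs above the female mean during infancy and drops
        below it after weaning completes onto depleted foods."""
        ages = np.linspace(0.0, 5.5, 111)
        traj = collagen_trajectory(MDE_PARAMS, TurnoverModel(), ages)
        female = MDE_PARAMS.d15N_female
        assert traj[0] == pytest.approx(female)
        peak = ages[np.argmax(traj)]
        assert traj.max() > female + 0.5
        assert 0.5 < peak < MDE_PARAMS.t2
        assert traj[-1] < female

    def test_no_overshoot(self):
        """First-order relaxation stays inside the envelope of start + diet."""
        ages = np.linspace(0.0, 6.0, 61)
        traj = collagen_trajectory(MDE_PARAMS, TurnoverModel(), ages)
        diets = diet_d15N(MDE_PARAMS, ages)
        lo = min(MDE_PARAMS.d15N_female, diets.min()) - 1e-9
        hi = max(MDE_PARAMS.d15N_female, diets.max()) + 1e-9
        assert np.all((traj >= lo) & (traj <= hi))

    def test_step_halving_convergence(self):
        ages = np.array([0.5, 1.5, 2.5, 4.0])
        a = collagen_trajectory(MDE_PARAMS, TurnoverModel(), ages, ode_step=0.02)
        b = collagen_trajectory(MDE_PARAMS, TurnoverModel(), ages, ode_step=0.01)
        assert np.max(np.abs(a - b)) < 1e-4

    def test_unsorted_ages_rejected(self):
        with pytest.raises(ValueError):
            collagen_trajectory(MDE_PARAMS, TurnoverModel(), [2.0, 1.0])


class TestDistance:
    def test_identical_vectors(self):
        assert warn_distance([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_arithmetic(self):
        assert warn_distance([1.0, 1.0], [0.0, 2.0]) == pytest.approx(1.0)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=9), rng.normal(size=9)
        perm = rng.permutation(9)
        assert warn_distance(a, b) == pytest.approx(warn_distance(a[perm], b[perm]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            warn_distance([1.0], [1.0, 2.0])


def _abc_config(**kw):
    base = dict(n_sims=30_000, accept_fraction=0.01, rng_seed=5)
    base.update(kw)
    return ABCConfig(**base)


class TestFitWarnABC:
    def test_bitwise_reproducible(self):
        spec = SyntheticCohortSpec(rng_seed=1)
        juv = [(s.age.midpoint, s.d15N) for s in simulate_juvenile_cohort(spec)]
        a = fit_warn_abc(juv, 10.91, TurnoverModel(), _abc_config())
        b = fit_warn_abc(juv, 10.91, TurnoverModel(), _abc_config())
        assert np.array_equal(a.accepted, b.accepted)
        assert a.mde.t1 == b.mde.t1 and a.mde.d15N_wnfood == b.mde.d15N_wnfood

    def test_recovers_known_weaning_window(self):
        truth = WeaningParams(1.5, 3.0, 1.5, 6.5, 10.91)
        spec = SyntheticCohortSpec(true_params=truth, obs_noise_sd=0.4, rng_seed=2)
        juv = [(s.age.midpoint, s.d15N) for s in simulate_juvenile_cohort(spec)]
        post = fit_warn_abc(juv, 10.91, TurnoverModel(), _abc_config(n_sims=100_000))
        assert post.mde.t2 == pytest.approx(truth.t2, abs=0.75)
        assert post.ci95["t2"][0] <= truth.t2 <= post.ci95["t2"][1]

    def test_flat_signal_concentrates_enrichment_near_zero(self):
        rng = np.random.default_rng(7)
        ages = np.linspace(0.05, 5.0, 31)
        juv = [(a, 10.91 + rng.normal(0, 0.05)) for a in ages]
        post = fit_warn_abc(juv, 10.91, TurnoverModel(), _abc_config())
        assert np.median(post.accepted[:, 2]) < 0.5

    def test_too_few_juveniles_rejected(self):
        with pytest.raises(ValueError):
            fit_warn_abc([(1.0, 10.0)] * 4, 10.91, TurnoverModel(), _abc_config())

    def test_degenerate_prior_rejected(self):
        with pytest.raises(ValueError):
            _abc_config(enrich_prior=(1.0, 1.0))


class TestPosteriorDensityMDE:
    def test_identical_draws(self):
        accepted = np.tile([1.2, 2.4, 1.0, 7.0], (300, 1))
        mde, ci95, grid = posterior_density_mde(accepted)
        assert (mde.t1, mde.t2) == (1.2, 2.4)
        assert ci95["t1"] == (1.2, 1.2)

    def test_truncated_bivariate_normal_mode(self):
        """Grid argmax sits within one cell of the analytic mode of a
        bivariate normal truncated to t1 <= t2."""
        rng = np.random.default_rng(11)
        mean = np.array([1.5, 3.0])
        cov = np.array([[0.09, 0.0], [0.0, 0.09]])
        draws = rng.multivariate_normal(mean, cov, size=200_000)
        draws = draws[draws[:, 0] <= draws[:, 1]][:100_000]
        accepted = np.column_stack([draws, np.ones(len(draws)), np.full(len(draws), 7.0)])
        mde, _, grid = posterior_density_mde(accepted)
        cell = (grid["t1_axis"][1] - grid["t1_axis"][0], grid["t2_axis"][1] - grid["t2_axis"][0])
        # truncation barely binds at 5 sigma: mode stays at the normal's mean
        assert abs(mde.t1 - 1.5) <= 3 * cell[0] + 0.05
        assert abs(mde.t2 - 3.0) <= 3 * cell[1] + 0.05

    def test_ci_monotone_in_level(self):
        rng = np.random.default_rng(4)
        accepted = np.column_stack([
            rng.uniform(0, 2, 1000), rng.uniform(2, 4, 1000),
            rng.uniform(0, 2, 1000), rng.uniform(5, 9, 1000),
        ])
        _, ci95, _ = posterior_density_mde(accepted)
        for lo, hi in ci95.values():
            assert lo <= hi
        inner = np.percentile(accepted[:, 0], [10, 90])
        assert ci95["t1"][0] <= inner[0] and inner[1] <= ci95["t1"][1]

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            posterior_density_mde(np.zeros((50, 4)))
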