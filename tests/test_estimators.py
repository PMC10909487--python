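"""Fixed-slope regression, lag scan, bootstrap and per-individual diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isolag import (
    FixedSlopeRegression,
    IsoScape,
    LagBootstrap,
    LagScanEstimator,
    bootstrap_lag,
    fixed_slope_fit,
    fixed_slope_fit_general,
    free_fit,
    lag_scan,
    per_individual_intercepts,
)
from isolag.sampling import SegmentObservation
from conftest import true_rates


def brute_force_intercept(env, hair, slope=1.0, span=50.0, levels=6):
    """Independent oracle: nested grid search minimising SS_res over c."""
    env, hair = np.asarray(env), np.asarray(hair)
    lo, hi = -span, span
    best = 0.0
    for _ in range(levels):
        grid = np.linspace(lo, hi, 2001)
        ss = ((hair[None, :] - slope * env[None, :] - grid[:, None]) ** 2).sum(axis=1)
        best = grid[np.argmin(ss)]
        step = grid[1] - grid[0]
        lo, hi = best - 2 * step, best + 2 * step
    return float(best)


class TestFixedSlopeFit:
    def test_perfect_offset_recovers_exactly(self):
        env = np.array([1.0, 4.0, 9.0])
        c, r2 = fixed_slope_fit(env, env + 2.1)
        assert c == pytest.approx(2.1)
        assert r2 == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # residuals about c=3 are (-1,-1,2): SS_res=6; SS_tot about mean 4 is 14
        c, r2 = fixed_slope_fit([0, 1, 2], [2, 3, 7])
        assert c == pytest.approx(3.0)
        assert r2 == pytest.approx(1 - 6 / 14)

    def test_constant_hair_flags_undefined_fit(self):
        c, r2 = fixed_slope_fit([0.0, 1.0, 2.0], [5.0, 5.0, 5.0])
        assert np.isnan(r2)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fixed_slope_fit([1.0], [1.0])

    def test_intercept_matches_brute_force_oracle(self, rng):
        env = rng.normal(8, 3, size=12)
        hair = env + rng.normal(2, 1, size=12)
        c, _ = fixed_slope_fit(env, hair)
        assert c == pytest.approx(brute_force_intercept(env, hair), abs=1e-6)

    @given(
        n=st.integers(2, 15),
        seed=st.integers(0, 10_000),
        slope=st.sampled_from([0.75, 1.0, 1.25]),
    )
    @settings(max_examples=40, deadline=None)
    def test_intercept_is_the_ss_res_minimiser(self, n, seed, slope):
        r = np.random.default_rng(seed)
        env = r.normal(5, 4, size=n)
        hair = slope * env + r.normal(2, 2, size=n)
        c, r2 = fixed_slope_fit_general(env, hair, slope)
        assert c == pytest.approx(brute_force_intercept(env, hair, slope), abs=1e-6)
        assert r2 <= 1.0 or np.isnan(r2)

    def test_r2_is_one_iff_residuals_vanish(self, rng):
        env = rng.normal(size=8)
        _, r2 = fixed_slope_fit(env, env + 1.0)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        _, r2_noisy = fixed_slope_fit(env, env + 1.0 + rng.normal(0, 0.5, 8))
        assert r2_noisy < 1.0

    def test_sklearn_estimator_api(self):
        est = FixedSlopeRegression(slope=1.0)
        assert est.get_params() == {"slope": 1.0}
        est.set_params(slope=0.5).fit([[0.0], [2.0]], [1.0, 2.0])
        assert est.intercept_ == pytest.approx(1.0)  # mean(hair - 0.5*env)
        assert est.r2_ == pytest.approx(1.0)
        np.testing.assert_allclose(est.predict([[4.0]]), [3.0])


class TestGeneralAndFreeFits:
    def test_slope_one_reduces_to_unit_slope_fit(self, rng):
        env = rng.normal(size=10)
        hair = env + rng.normal(size=10)
        assert fixed_slope_fit_general(env, hair, 1.0) == fixed_slope_fit(env, hair)

    def test_exact_three_quarter_slope(self):
        env = np.array([0.0, 2.0, 4.0])
        c, r2 = fixed_slope_fit_general(env, 0.75 * env + 1.0, 0.75)
        assert (c, r2) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_half_slope_hand_example(self):
        c, r2 = fixed_slope_fit_general([0.0, 2.0], [1.0, 2.0], 0.5)
        assert (c, r2) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_free_fit_exact_line(self):
        env = np.array([0.0, 1.0, 2.0, 3.0])
        c, m, r2 = free_fit(env, 2 * env + 1)
        assert (c, m, r2) == (pytest.approx(1.0), pytest.approx(2.0), pytest.approx(1.0))

    def test_free_fit_orthogonal_noise_has_near_zero_slope(self, rng):
        env = rng.normal(size=4000)
        _, m, r2 = free_fit(env, rng.normal(size=4000))
        assert abs(m) < 0.1
        assert r2 < 0.01

    def test_free_fit_duplicate_x_is_finite(self):
        c, m, r2 = free_fit([1.0, 1.0, 2.0], [0.0, 1.0, 1.0])
        assert np.isfinite([c, m, r2]).all()
        assert r2 < 1.0

    def test_free_fit_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            free_fit([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])


class TestLagScan:
    def test_noiseless_cohort_recovers_true_lag_exactly(self, noiseless_cohort):
        co = noiseless_cohort
        res = lag_scan(co.hairs, co.trajectories, co.scape, rates=true_rates(co))
        assert res.best_lag == co.truth["true_lag_days"] == 80.0
        assert res.r2_at_best == pytest.approx(1.0, abs=1e-9)
        assert res.intercept_at_best == pytest.approx(
            co.truth["true_fractionation_permil"], abs=1e-9
        )

    def test_true_lag_zero_recovered_with_intercept(self):
        from isolag import SimConfig, simulate_cohort

        co = simulate_cohort(SimConfig(seed=0, movement_mode="migratory",
                                       true_lag_days=0.0, grass_sd_permil=0.0,
                                       analytical_sd_permil=0.0))
        res = lag_scan(co.hairs, co.trajectories, co.scape, rates=true_rates(co))
        assert res.best_lag == 0.0
        assert res.intercept_at_best == pytest.approx(2.1, abs=1e-9)

    def test_constant_isoscape_ties_break_to_smallest_lag(self):
        from isolag import SimConfig, simulate_cohort

        # warmup long enough that every lag keeps every segment: the r2
        # values then tie exactly and the smallest lag must win
        co = simulate_cohort(SimConfig(seed=0, movement_mode="migratory",
                                       grass_sd_permil=0.0,
                                       analytical_sd_permil=0.0,
                                       warmup_days=300.0))
        flat = IsoScape(grid=np.full((2, 2), 7.0), origin_x=-5e6, origin_y=-5e6,
                        cell_size=5e6)
        res = lag_scan(co.hairs, co.trajectories, flat, rates=true_rates(co))
        assert (res.n_obs_per_lag == res.n_obs_per_lag[0]).all()
        assert (res.r2 == res.r2[0]).all()
        assert res.best_lag == 0.0

    def test_r2_maximum_is_attained_at_best_lag(self, standard_cohort):
        co = standard_cohort
        est = LagScanEstimator().fit(co.hairs, co.trajectories, co.scape)
        assert est.best_lag_ in est.result_.lags
        assert est.r2_ == np.nanmax(est.result_.r2)

    def test_undersupported_lags_are_invalid_not_winning(self, standard_cohort):
        co = standard_cohort
        one = {k: co.hairs[k] for k in list(co.hairs)[:1]}
        # huge lags push all windows before the GPS record -> too few obs
        res = lag_scan(one, co.trajectories, co.scape,
                       lag_grid=[0, 10, 5000])
        assert np.isnan(res.r2[-1])
        assert res.n_obs_per_lag[-1] == 0
        assert res.best_lag in (0.0, 10.0)


class TestBootstrap:
    def test_single_replicate_equals_single_scan(self, standard_cohort):
        co = standard_cohort
        rates = true_rates(co)
        mean_rate = float(np.mean(list(rates.values())))
        boot = LagBootstrap(B=1, seed=7, rate_mean=mean_rate, rate_sd=0.0).fit(
            co.hairs, co.trajectories, co.scape
        )
        scan = lag_scan(co.hairs, co.trajectories, co.scape,
                        rates={a: mean_rate for a in co.hairs})
        assert boot.lag_mean_ == scan.best_lag
        assert boot.lag_pi_ == (scan.best_lag, scan.best_lag)
        assert boot.frac_mean_ == pytest.approx(scan.intercept_at_best)

    def test_zero_rate_sd_degenerates_the_interval(self, standard_cohort):
        co = standard_cohort
        boot = LagBootstrap(B=25, seed=7, rate_mean=0.511, rate_sd=0.0).fit(
            co.hairs, co.trajectories, co.scape
        )
        assert boot.lag_pi_[0] == boot.lag_pi_[1] == boot.lag_mean_
        assert boot.frac_pi_[0] == pytest.approx(boot.frac_pi_[1])

    def test_bitwise_reproducible_for_fixed_seed(self, standard_cohort):
        co = standard_cohort
        runs = [
            LagBootstrap(B=40, seed=123).fit(co.hairs, co.trajectories, co.scape)
            for _ in range(2)
        ]
        pd.testing.assert_frame_equal(runs[0].replicates_, runs[1].replicates_)
        assert runs[0].summary_.to_dict() == runs[1].summary_.to_dict()

    def test_percentile_interval_is_ordered_and_equal_tailed(self, standard_cohort):
        co = standard_cohort
        boot = LagBootstrap(B=60, seed=5, percentiles=(5.0, 95.0)).fit(
            co.hairs, co.trajectories, co.scape
        )
        assert boot.lag_pi_[0] <= boot.lag_pi_[1]
        assert boot.summary_.percentiles == (5.0, 95.0)

    def test_invalid_b_rejected(self, standard_cohort):
        co = standard_cohort
        with pytest.raises(ValueError):
            LagBootstrap(B=0).fit(co.hairs, co.trajectories, co.scape)

    def test_functional_wrapper_matches_estimator(self, standard_cohort):
        co = standard_cohort
        s1 = bootstrap_lag(co.hairs, co.trajectories, co.scape, B=10, seed=9)
        s2 = LagBootstrap(B=10, seed=9).fit(
            co.hairs, co.trajectories, co.scape
        ).summary_
        assert s1.to_dict() == s2.to_dict()


class TestPerIndividualIntercepts:
    @staticmethod
    def _obs(deltas, per=3):
        out = []
        for a, d in deltas.items():
            for i in range(per):
                env = float(i)
                out.append(SegmentObservation(a, i, env + d, env, 1))
        return out

    def test_shared_offset_has_zero_sd(self):
        _, sd = per_individual_intercepts(self._obs({"a": 2.1, "b": 2.1}))
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_two_animals_hand_computed(self):
        intercepts, sd = per_individual_intercepts(self._obs({"a": 1.0, "b": 3.0}))
        assert intercepts["a"] == pytest.approx(1.0)
        assert intercepts["b"] == pytest.approx(3.0)
        assert sd == pytest.approx(np.sqrt(2.0), abs=1e-9)

    def test_single_animal_rejected(self):
        with pytest.raises(ValueError):
            per_individual_intercepts(self._obs({"a": 1.0}))
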