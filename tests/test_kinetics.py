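"""Unit and property tests for the three-stage proteolysis chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from casekin import (
    EnzymeSetting,
    RateConstants,
    TmaxObservation,
    fit_k2,
    ode_oracle,
    predict_secondary_structure,
    product_lag_time,
    species_closed_form,
    tmax_from_constants,
    y_concentration,
)
from casekin.errors import (
    DegenerateRatesError,
    InvalidGridError,
    InvalidParameterError,
)
from casekin.kinetics import dy_dt_expression, interior_local_max_time

from conftest import REF_E0, REF_K2


class TestClosedForm:
    def test_initial_conditions(self, ref_rates, ref_env):
        traj = species_closed_form(ref_rates, ref_env, [0.0, 1.0])
        assert traj.S[0] == pytest.approx(1.0)
        assert traj.X[0] == traj.Y[0] == traj.N[0] == pytest.approx(0.0)

    def test_matches_ode_oracle_reference_constants(
        self, ref_rates, ref_env, time_grid
    ):
        closed = species_closed_form(ref_rates, ref_env, time_grid)
        oracle = ode_oracle(ref_rates, ref_env, time_grid)
        for name in ("S", "X", "Y", "N"):
            err = np.abs(getattr(closed, name) - getattr(oracle, name)).max()
            assert err < 1e-8, f"{name} deviates by {err}"

    def test_all_mass_exits_the_chain(self, ref_rates, ref_env):
        traj = species_closed_form(ref_rates, ref_env, [0.0, 1e7])
        assert traj.S[-1] < 1e-6
        assert traj.X[-1] < 1e-6
        assert traj.Y[-1] < 1e-6
        assert traj.N[-1] > 1 - 1e-5

    def test_species_bounded_and_monotone(self, ref_trajectory):
        traj = ref_trajectory
        for name in ("S", "X", "Y", "N"):
            v = getattr(traj, name)
            assert np.all(v >= -1e-12) and np.all(v <= 1 + 1e-12)
        assert np.all(np.diff(traj.S) < 0)  # strictly decreasing
        assert np.all(np.diff(traj.N) >= 0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_conservation_random_rates(self, seed):
        """|S+X+Y+N-1| < 1e-9 on the whole grid for random distinct rates."""
        from conftest import random_distinct_rates

        rng = np.random.default_rng(seed)
        a, b, c = random_distinct_rates(rng)
        rc = RateConstants(k1=a, k2=b, k3=c)  # E0=1 makes effective rates a,b,c
        traj = species_closed_form(rc, EnzymeSetting(E0=1.0), np.linspace(0, 5 / min(a, b, c), 300))
        assert np.abs(traj.total() - 1.0).max() < 1e-9

    def test_invalid_enzyme_concentration(self, ref_rates):
        with pytest.raises(InvalidParameterError):
            EnzymeSetting(E0=0.0)
        with pytest.raises(InvalidParameterError):
            EnzymeSetting(E0=-1.0)

    @pytest.mark.parametrize("bad", [[0.0, np.nan], [-1.0, 5.0], [3.0, 2.0]])
    def test_invalid_time_grid(self, ref_rates, ref_env, bad):
        with pytest.raises(InvalidGridError):
            species_closed_form(ref_rates, ref_env, bad)

    def test_degenerate_rates_fall_back_to_integrator(self):
        # k1*E0 exactly equals k2: the closed-form denominators vanish
        rc = RateConstants(k1=0.0015, k2=0.0015, k3=0.0008)
        traj = species_closed_form(rc, EnzymeSetting(E0=1.0), np.linspace(0, 5e3, 200))
        assert np.all(np.isfinite(traj.X))
        assert np.abs(traj.total() - 1.0).max() < 1e-9


class TestYConcentration:
    def test_zero_at_start(self, ref_rates, ref_env):
        assert y_concentration(ref_rates, ref_env, 0.0) == pytest.approx(0.0)

    def test_peak_matches_dense_grid_argmax(self, ref_rates, ref_env):
        t_max = tmax_from_constants(ref_rates, ref_env)
        dense = np.arange(0.0, 2e4, 1.0)
        y_dense = y_concentration(ref_rates, ref_env, dense)
        y_at_tmax = y_concentration(ref_rates, ref_env, t_max)
        assert y_at_tmax >= y_dense.max() - 1e-12

    def test_fast_rearrangement_limit_is_two_step_chain(self, ref_env):
        """k2 -> infinity collapses the chain to S -> Y -> N with rates
        k1*E0 and k3*E0 (the hydrolyzed-micelle stage becomes instantaneous)."""
        rc = RateConstants.from_effective(k1E0=0.0066, k2=1e6, k3E0=0.0002, E0=REF_E0)
        t = np.linspace(0.0, 1e4, 500)
        y = y_concentration(rc, ref_env, t)
        a, c = 0.0066, 0.0002
        y_two_step = a / (c - a) * (np.exp(-a * t) - np.exp(-c * t))
        assert np.abs(y - y_two_step).max() < 1e-4

    def test_degenerate_rates_rejected(self, ref_env):
        rc = RateConstants(k1=0.0015 / REF_E0, k2=0.0015, k3=0.0008)
        with pytest.raises(DegenerateRatesError):
            y_concentration(rc, ref_env, 100.0)

    def test_unimodal_rise_then_fall(self, ref_rates, ref_env):
        dense = np.arange(1.0, 2e4, 1.0)
        y = y_concentration(ref_rates, ref_env, dense)
        k = int(np.argmax(y))
        assert 0 < k < len(y) - 1
        assert np.all(np.diff(y[: k + 1]) > 0)
        assert np.all(np.diff(y[k:]) < 0)


class TestTmax:
    def test_root_is_stationary_point(self, ref_rates, ref_env):
        t_max = tmax_from_constants(ref_rates, ref_env)
        assert abs(dy_dt_expression(ref_rates, ref_env, t_max)) < 1e-10

    def test_matches_grid_argmax_within_1s(self, ref_rates, ref_env):
        t_max = tmax_from_constants(ref_rates, ref_env)
        dense = np.arange(0.0, 2e4, 1.0)
        y = y_concentration(ref_rates, ref_env, dense)
        assert abs(t_max - dense[np.argmax(y)]) <= 1.0

    def test_all_rates_proportional_gives_hyperbola(self):
        """When every stage scales with enzyme, doubling E0 exactly halves
        the peak time (t_max ~ 1/E0)."""
        rc = RateConstants(k1=0.0066 / REF_E0, k2=REF_K2 / REF_E0, k3=0.0002 / REF_E0)

        def tm(e0):
            rce = RateConstants(k1=rc.k1, k2=rc.k2 * e0, k3=rc.k3)
            return tmax_from_constants(rce, EnzymeSetting(E0=e0))

        assert tm(0.5) == pytest.approx(2.0 * tm(1.0), rel=1e-9)

    def test_time_rescaling_symmetry(self, ref_rates, ref_env):
        """Scaling all rates by c scales t_max by 1/c (linear-ODE symmetry)."""
        t1 = tmax_from_constants(ref_rates, ref_env)
        c = 3.7
        scaled = RateConstants(
            k1=ref_rates.k1 * c, k2=ref_rates.k2 * c, k3=ref_rates.k3 * c
        )
        t2 = tmax_from_constants(scaled, ref_env)
        assert t2 == pytest.approx(t1 / c, rel=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_root_equals_argmax_random_rates(self, seed):
        from conftest import random_distinct_rates

        rng = np.random.default_rng(seed)
        a, b, c = random_distinct_rates(rng)
        rc = RateConstants(k1=a, k2=b, k3=c)
        env = EnzymeSetting(E0=1.0)
        t_max = tmax_from_constants(rc, env)
        # dense grid around the root, 1 s resolution equivalent scaled
        step = min(1.0, t_max / 1e3)
        dense = np.arange(max(step, t_max / 5), t_max * 5, step)
        y = y_concentration(rc, env, dense)
        assert abs(t_max - dense[np.argmax(y)]) <= step

    def test_degenerate_rates_rejected(self):
        rc = RateConstants(k1=0.0015, k2=0.0015, k3=0.0002)
        with pytest.raises(DegenerateRatesError):
            tmax_from_constants(rc, EnzymeSetting(E0=1.0))


class TestFitK2:
    def test_single_observation_exact_inversion(self, ref_rates):
        env = EnzymeSetting(E0=0.5)
        t_true = tmax_from_constants(ref_rates, env)
        fit = fit_k2(
            [TmaxObservation(E0=0.5, tmax=t_true)], k1=ref_rates.k1, k3=ref_rates.k3
        )
        assert fit.k2 == pytest.approx(REF_K2, rel=1e-6)
        assert abs(fit.residuals[0]) < 1e-3  # essentially zero on a ~2000 s peak time

    def test_noiseless_four_levels(self, ref_rates):
        obs = [
            TmaxObservation(E0=e0, tmax=tmax_from_constants(ref_rates, EnzymeSetting(E0=e0)))
            for e0 in (0.125, 0.25, 0.5, 1.0)
        ]
        fit = fit_k2(obs, k1=ref_rates.k1, k3=ref_rates.k3)
        assert fit.k2 == pytest.approx(REF_K2, rel=1e-3)

    def test_degenerate_data_warns_but_fits(self, ref_rates):
        t_true = tmax_from_constants(ref_rates, EnzymeSetting(E0=0.25))
        obs = [
            TmaxObservation(E0=0.25, tmax=t_true * 0.9),
            TmaxObservation(E0=0.25, tmax=t_true * 1.1),
        ]
        with pytest.warns(UserWarning, match="inconsistent"):
            fit = fit_k2(obs, k1=ref_rates.k1, k3=ref_rates.k3)
        assert np.isfinite(fit.k2)

    def test_requires_observations_and_positive_constants(self, ref_rates):
        with pytest.raises(InvalidParameterError):
            fit_k2([], k1=ref_rates.k1, k3=ref_rates.k3)
        with pytest.raises(InvalidParameterError):
            fit_k2(
                [TmaxObservation(E0=1.0, tmax=100.0)], k1=0.0, k3=ref_rates.k3
            )


class TestSecondaryStructure:
    def test_starts_at_one_both_modes(self, ref_trajectory):
        for mode in ("S_plus_Y", "S_plus_halfX_plus_Y"):
            ss = predict_secondary_structure(ref_trajectory, mode=mode)
            assert ss[0] == pytest.approx(1.0)

    def test_decays_to_zero(self, ref_rates, ref_env):
        traj = species_closed_form(ref_rates, ref_env, [0.0, 1e7])
        for mode in ("S_plus_Y", "S_plus_halfX_plus_Y"):
            assert predict_secondary_structure(traj, mode=mode)[-1] < 1e-5

    def test_mode_identity_against_oracle(self, ref_rates, ref_env, time_grid):
        traj = ode_oracle(ref_rates, ref_env, time_grid)
        a = predict_secondary_structure(traj, mode="S_plus_Y")
        b = predict_secondary_structure(traj, mode="S_plus_halfX_plus_Y")
        assert np.allclose(b, a + traj.X / 2.0, atol=1e-12)

    def test_unknown_mode_rejected(self, ref_trajectory):
        with pytest.raises(InvalidParameterError):
            predict_secondary_structure(ref_trajectory, mode="everything")

    def test_local_maximum_shifts_earlier_with_more_enzyme(self, ref_rates):
        t = np.linspace(0.0, 3e4, 30001)
        peaks = []
        for e0 in (0.25, 1.0, 4.0):
            traj = species_closed_form(ref_rates, EnzymeSetting(E0=e0), t)
            ss = predict_secondary_structure(traj, mode="S_plus_halfX_plus_Y")
            peak = interior_local_max_time(traj.times, ss)
            assert peak is not None
            peaks.append(peak)
        assert peaks[0] > peaks[1] > peaks[2]


class TestOdeOracle:
    def test_aggregation_branch_conserves_mass(self, ref_env, time_grid):
        rc = RateConstants(k1=0.0264, k2=0.0015, k3=0.0008, ka=0.0004)
        traj = ode_oracle(rc, ref_env, time_grid)
        assert traj.Z is not None
        assert np.all(np.diff(traj.Z) >= -1e-12)
        assert np.abs(traj.total() - 1.0).max() < 1e-9

    def test_equal_rates_match_confluent_form(self):
        """With k1*E0 = k2 = r exactly, X(t) = r t exp(-r t)."""
        r = 0.002
        rc = RateConstants(k1=r, k2=r, k3=0.0001)
        t = np.linspace(0.0, 5e3, 500)
        traj = ode_oracle(rc, EnzymeSetting(E0=1.0), t)
        assert np.all(np.isfinite(traj.X))
        assert np.abs(traj.X - r * t * np.exp(-r * t)).max() < 1e-8

    def test_ka_enzyme_scaling_flag(self, time_grid):
        """ka can be enzyme-proportional (default) or enzyme-independent."""
        prop = RateConstants(k1=0.0264, k2=0.0015, k3=0.0008, ka=0.001)
        fixed = RateConstants(
            k1=0.0264, k2=0.0015, k3=0.0008, ka=0.001, ka_enzyme_proportional=False
        )
        env = EnzymeSetting(E0=2.0)
        z_prop = ode_oracle(prop, env, time_grid).Z[-1]
        z_fixed = ode_oracle(fixed, env, time_grid).Z[-1]
        assert z_prop > z_fixed  # effective ka doubles under proportional scaling


class TestLagTime:
    def test_zero_threshold(self, ref_trajectory):
        assert product_lag_time(ref_trajectory, threshold=0.0) == 0.0

    def test_matches_brute_force_crossing(self, ref_rates, ref_env):
        traj = species_closed_form(ref_rates, ref_env, np.linspace(0, 1e4, 2001))
        lag = product_lag_time(traj, threshold=0.05)
        fine = np.arange(0.0, 1e4, 0.1)
        fine_traj = species_closed_form(ref_rates, ref_env, fine)
        brute = fine[np.nonzero(fine_traj.N >= 0.05)[0][0]]
        assert abs(lag - brute) <= 0.1

    def test_lag_grows_as_enzyme_drops(self, ref_rates):
        t = np.linspace(0.0, 3e4, 30001)
        lags = [
            product_lag_time(
                species_closed_form(ref_rates, EnzymeSetting(E0=e0), t)
            )
            for e0 in (4.0, 1.0, 0.25)
        ]
        assert lags[0] < lags[1] < lags[2]

    def test_beyond_grid_returns_sentinel(self, ref_rates, ref_env):
        traj = species_closed_form(ref_rates, ref_env, np.linspace(0, 10.0, 50))
        with pytest.warns(UserWarning, match="beyond the grid"):
            assert product_lag_time(traj, threshold=0.9) == float("inf")
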