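"""Closed-form cascade kinetics against an independent ODE oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ntpsleep.cascade import (
    EpisodeModel,
    ModeOccupancy,
    PhasePlan,
    TransitionProbabilities,
    monte_carlo_phase,
    occupancy_to_power,
    phase_occupancy,
    sigma_peak_time,
    simulate_episode,
)

from conftest import rk4_cascade


class TestPhaseOccupancy:
    def test_identity_at_t_zero(self):
        occ = phase_occupancy(ModeOccupancy(1, 0, 0), 0.5, 0.7, 0.0)
        assert occ.as_tuple() == (1.0, 0.0, 0.0)

    def test_towards_matches_ode_oracle(self):
        occ = phase_occupancy(ModeOccupancy(1, 0, 0), 0.13, 0.131, 10.0)
        oracle = rk4_cascade([1, 0, 0], 0.13, 0.131, 10.0)
        assert occ.as_tuple() == pytest.approx(tuple(oracle), abs=1e-9)
        # frozen values from the oracle
        assert occ.as_tuple() == pytest.approx((0.27253, 0.35253, 0.37494), abs=5e-5)

    def test_away_phase_swaps_beta_and_delta(self):
        occ = phase_occupancy(ModeOccupancy(0, 0, 1), 0.2, 0.6, 5.0, phase="away")
        oracle = rk4_cascade([1, 0, 0], 0.2, 0.6, 5.0)
        assert occ.n_delta == pytest.approx(oracle[0], abs=1e-9)
        assert occ.n_sigma == pytest.approx(oracle[1], abs=1e-9)
        assert occ.n_beta == pytest.approx(oracle[2], abs=1e-9)
        assert occ.n_delta == pytest.approx(math.exp(-1.0), abs=1e-9)
        assert (occ.n_delta, occ.n_sigma, occ.n_beta) == pytest.approx(
            (0.36788, 0.15905, 0.47308), abs=5e-5)

    @given(
        p1=st.floats(0.01, 0.9),
        p2=st.floats(0.01, 0.9),
        t=st.floats(0.0, 60.0),
        n2=st.floats(0.0, 1.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_closed_form_agrees_with_oracle_and_conserves(self, p1, p2, t, n2):
        occ0 = ModeOccupancy(1.0 - n2 * 0.5, n2 * 0.5, 0.0)
        occ = phase_occupancy(occ0, p1, p2, t)
        oracle = rk4_cascade(occ0.as_tuple(), p1, p2, t) if t > 0 else occ0.as_tuple()
        assert occ.as_tuple() == pytest.approx(tuple(oracle), abs=1e-6)
        assert occ.total == pytest.approx(occ0.total, abs=1e-9)
        assert all(v >= 0 for v in occ.as_tuple())

    def test_equal_rate_limit_form(self):
        p = 0.2
        # continuity: the near-degenerate branch matches the generic branch
        near = phase_occupancy(ModeOccupancy(0.7, 0.3, 0), p, p * (1 + 1e-10), 7.0)
        exact = (0.3 + 0.7 * p * 7.0) * math.exp(-p * 7.0)
        assert near.n_sigma == pytest.approx(exact, rel=1e-9)
        generic = phase_occupancy(ModeOccupancy(0.7, 0.3, 0), p, p * (1 + 1e-6), 7.0)
        assert generic.n_sigma == pytest.approx(exact, rel=1e-5)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            phase_occupancy(ModeOccupancy(1, 0, 0), 0.1, 0.2, -1.0)
        with pytest.raises(ValueError):
            phase_occupancy(ModeOccupancy(1, 0, 0), 0.0, 0.2, 1.0)


class TestSigmaPeak:
    def test_no_source_declines_from_start(self):
        assert sigma_peak_time(ModeOccupancy(0, 0.5, 0), 0.13, 0.131) is None

    def test_default_towards_rates(self):
        t = sigma_peak_time(ModeOccupancy(1, 0, 0), 0.13, 0.131)
        # brute-force maximization of the closed form
        grid = np.linspace(0, 40, 400001)
        occ = [phase_occupancy(ModeOccupancy(1, 0, 0), 0.13, 0.131, g).n_sigma
               for g in grid[:: 4000]]
        assert t == pytest.approx(math.log(0.131 / 0.13) / 0.001, rel=1e-9)
        assert t == pytest.approx(7.663, abs=1e-3)
        assert max(occ) <= phase_occupancy(ModeOccupancy(1, 0, 0), 0.13, 0.131, t).n_sigma + 1e-9

    def test_away_rates_closed_form(self):
        t = sigma_peak_time(ModeOccupancy(1, 0, 0), 0.2, 0.6)
        assert t == pytest.approx(math.log(3.0) / 0.4, rel=1e-12)

    def test_mixed_start_interior_maximum(self):
        # nonzero middle occupancy: peak still where inflow equals outflow
        occ0 = ModeOccupancy(0.8, 0.1, 0.1)
        t = sigma_peak_time(occ0, 0.3, 0.5)
        grid = np.linspace(0, 20, 20001)
        values = [phase_occupancy(occ0, 0.3, 0.5, g).n_sigma for g in grid]
        assert t == pytest.approx(grid[int(np.argmax(values))], abs=2e-3)

    def test_sigma_peaks_while_delta_rises(self):
        # at the middle-mode maximum the last mode is still strictly rising
        t = sigma_peak_time(ModeOccupancy(1, 0, 0), 0.13, 0.131)
        before = phase_occupancy(ModeOccupancy(1, 0, 0), 0.13, 0.131, t).n_delta
        after = phase_occupancy(ModeOccupancy(1, 0, 0), 0.13, 0.131, t + 1e-3).n_delta
        assert after > before


class TestSimulateEpisode:
    def test_monotone_shapes_in_pure_towards_phase(self):
        model = EpisodeModel(plan=PhasePlan())
        traj = simulate_episode(model, np.linspace(0, 100, 201))
        assert traj.n_delta[0] == 0.0
        assert np.all(np.diff(traj.n_beta) < 0)
        assert np.all(np.diff(traj.n_delta) > 0)
        sigma = traj.n_sigma
        peak = int(np.argmax(sigma))
        assert np.all(np.diff(sigma[: peak + 1]) > 0)
        assert np.all(np.diff(sigma[peak:]) < 0)

    def test_continuity_at_switchover(self):
        model = EpisodeModel(plan=PhasePlan(switchover_times=(40.0,)))
        eps = 1e-7
        left = simulate_episode(model, [40.0 - eps])
        right = simulate_episode(model, [40.0 + eps])
        for band in ("beta", "sigma", "delta"):
            assert left.component(band)[0] == pytest.approx(
                right.component(band)[0], abs=1e-5)

    def test_three_cycle_delta_has_three_local_maxima(self, three_cycle_model):
        traj = simulate_episode(three_cycle_model, np.linspace(0, 100, 1001))
        d = traj.n_delta
        interior_max = np.sum((d[1:-1] > d[:-2]) & (d[1:-1] > d[2:]))
        # one delta peak per towards-away cycle
        assert interior_max == 3
        assert three_cycle_model.plan.n_towards == 3

    def test_conservation_along_trajectory(self, three_cycle_model):
        traj = simulate_episode(three_cycle_model, np.linspace(0, 100, 501))
        assert np.allclose(traj.total, 1.0, atol=1e-9)

    def test_grid_outside_plan_rejected(self, three_cycle_model):
        with pytest.raises(ValueError):
            simulate_episode(three_cycle_model, [0.0, 101.0])


class TestOccupancyToPower:
    def test_unit_scales_identity_and_bias(self, three_cycle_model):
        traj = simulate_episode(three_cycle_model, np.linspace(0, 100, 51))
        powers = occupancy_to_power(traj, {"delta": 1, "sigma": 1, "beta": 1}, 0.0)
        assert np.allclose(powers["delta"], traj.n_delta)
        biased = occupancy_to_power(traj, {"delta": 1, "sigma": 1, "beta": 1}, 2.0)
        assert np.allclose(biased["beta"] - powers["beta"], 2.0)

    def test_bias_on_empty_beta_mode(self):
        model = EpisodeModel(plan=PhasePlan(), initial_occupancy=ModeOccupancy(0, 1, 0))
        traj = simulate_episode(model, [0.0])
        powers = occupancy_to_power(traj, {"delta": 1, "sigma": 1, "beta": 1}, 2.0)
        assert powers["beta"][0] == pytest.approx(2.0)


class TestMonteCarlo:
    def test_zero_rate_keeps_population_frozen(self):
        times, counts = monte_carlo_phase((500, 0, 0), 1e-12, 0.5, 0.01, 2.0, seed=1)
        assert np.all(counts[:, 0] == 500)

    def test_total_count_conserved_exactly(self):
        _, counts = monte_carlo_phase((300, 200, 100), 0.2, 0.6, 0.01, 5.0, seed=3)
        assert np.all(counts.sum(axis=1) == 600)

    def test_seeded_runs_reproducible(self):
        a = monte_carlo_phase((100, 0, 0), 0.2, 0.6, 0.01, 2.0, seed=42)[1]
        b = monte_carlo_phase((100, 0, 0), 0.2, 0.6, 0.01, 2.0, seed=42)[1]
        assert np.array_equal(a, b)

    def test_first_mode_matches_exponential_within_binomial_error(self):
        n = 10_000
        _, counts = monte_carlo_phase((n, 0, 0), 0.2, 0.6, 0.01, 5.0, seed=7)
        frac = counts[-1, 0] / n
        # discrete thinning survival (1 - p dt)^steps, within 4 binomial SE
        expected = (1 - 0.2 * 0.01) ** 500
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 4 * se
        assert expected == pytest.approx(math.exp(-1.0), rel=5e-3)

    def test_mean_over_replicates_converges_to_closed_form(self):
        n, reps = 400, 200
        rng = np.random.default_rng(11)
        finals = np.array([
            monte_carlo_phase((n, 0, 0), 0.2, 0.6, 0.005, 5.0, seed=rng)[1][-1]
            for _ in range(reps)
        ]) / n
        closed = phase_occupancy(ModeOccupancy(1, 0, 0), 0.2, 0.6, 5.0)
        assert np.max(np.abs(finals.mean(axis=0) - closed.as_tuple())) < 0.01

    def test_pdt_too_large_rejected(self):
        with pytest.raises(ValueError):
            monte_carlo_phase((10, 0, 0), 0.5, 0.5, 3.0, 10.0)


class TestTypes:
    @pytest.mark.parametrize("vector", [(0.13, 0.131, 0.2, 0.6), (0.5, 0.5, 0.5, 0.5)])
    def test_probability_vector_round_trip(self, vector):
        p = TransitionProbabilities.from_vector(vector)
        assert p.as_vector() == vector
        assert TransitionProbabilities.from_vector(p.as_vector()) == p

    @pytest.mark.parametrize("bad", [(0, 0.1, 0.1, 0.1), (0.1, 0.1, 0.1, 1.0)])
    def test_probabilities_outside_unit_interval_rejected(self, bad):
        with pytest.raises(ValueError):
            TransitionProbabilities.from_vector(bad)

    def test_phase_plan_validation(self):
        with pytest.raises(ValueError):
            PhasePlan(switchover_times=(30.0, 20.0))
        with pytest.raises(ValueError):
            PhasePlan(switchover_times=(120.0,))
        plan = PhasePlan(switchover_times=(20.0, 50.0, 70.0))
        kinds = [k for _, _, k in plan.phases]
        assert kinds == ["towards", "away", "towards", "away"]
        assert plan.n_towards == 2
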