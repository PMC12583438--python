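"""Two-state Arrhenius kinetics: rates, lifetimes, propagators, trajectories."""

import numpy as np
import pytest
from scipy import stats

from alexfret.kinetics import (
    StateTrajectory,
    TwoStateModel,
    energies_from_lifetimes,
    lifetimes_and_K,
    rates_from_energies,
    sample_initial_state,
    simulate_state_trajectory,
    transition_matrix,
)


class TestRatesFromEnergies:
    @pytest.mark.parametrize(
        "dG, dGd, k12_exp, k21_exp",
        [
            # printed rate pairs for G_barrier = 9 and 3 kBT (dG = 1.5)
            (1.5, 7.5, 1.2e2, 5.5e2),
            (1.5, 1.5, 5.0e4, 2.2e5),
            (0.0, 0.0, 1.0e6, 1.0e6),
        ],
    )
    def test_printed_rates(self, dG, dGd, k12_exp, k21_exp):
        k12, k21 = rates_from_energies(dG, dGd, 1e6)
        assert k12 == pytest.approx(k12_exp, rel=0.05)
        assert k21 == pytest.approx(k21_exp, rel=0.05)

    def test_invalid_ks(self):
        with pytest.raises(ValueError):
            rates_from_energies(1.0, 1.0, 0.0)


class TestEnergiesFromLifetimes:
    def test_measured_nucleosome_lifetimes(self):
        # tau = (20.3, 4.4) ms maps to G_barrier = 9.92, dG = 1.53 kBT
        gb, dg = energies_from_lifetimes(20.3e-3, 4.4e-3, 1e6)
        assert gb == pytest.approx(9.92, abs=0.01)
        assert dg == pytest.approx(1.53, abs=0.01)

    def test_symmetric_landscape(self):
        _, dg = energies_from_lifetimes(3e-3, 3e-3)
        assert dg == 0.0

    @pytest.mark.parametrize("dG, dGd", [(1.5, 7.5), (0.3, 2.0), (-1.0, 4.0)])
    def test_exact_round_trip(self, dG, dGd):
        k12, k21 = rates_from_energies(dG, dGd)
        tau1, tau2, _, _ = lifetimes_and_K(k12, k21)
        gb, dg = energies_from_lifetimes(tau1, tau2)
        assert gb == pytest.approx(dG + dGd, rel=1e-12)
        assert dg == pytest.approx(dG, rel=1e-12)

    def test_rejects_nonpositive_lifetime(self):
        with pytest.raises(ValueError):
            energies_from_lifetimes(-1e-3, 1e-3)


class TestLifetimesAndK:
    def test_equilibrium_constant_dG_1p5(self):
        k12, k21 = rates_from_energies(1.5, 9.5)
        _, _, K, _ = lifetimes_and_K(k12, k21)
        assert K == pytest.approx(np.exp(1.5), rel=1e-12)
        assert round(K, 1) == 4.5

    def test_printed_lifetimes_g11(self):
        k12, k21 = rates_from_energies(1.5, 9.5)  # G_barrier = 11
        tau1, tau2, _, _ = lifetimes_and_K(k12, k21)
        assert tau1 * 1e3 == pytest.approx(59.9, abs=0.05)
        assert tau2 * 1e3 == pytest.approx(13.4, abs=0.05)

    def test_symmetric_rates(self):
        tau1, tau2, K, tau_K = lifetimes_and_K(100.0, 100.0)
        assert K == 1.0
        assert tau_K == pytest.approx(1.0 / 200.0)
        assert tau_K < min(tau1, tau2)

    def test_rejects_zero_rate(self):
        with pytest.raises(ValueError):
            lifetimes_and_K(0.0, 10.0)


class TestTransitionMatrix:
    def test_zero_dt_is_identity(self):
        P = transition_matrix(100.0, 300.0, 0.0)
        assert np.allclose(P, np.eye(2))

    def test_long_time_limit_symmetric(self):
        # equal rates: P12 -> 1/2 as dt -> infinity (stationary mixing)
        P = transition_matrix(50.0, 50.0, 1e6)
        assert P[0, 1] == pytest.approx(0.5, rel=1e-9)

    def test_rows_sum_to_one_and_bounded(self):
        for dt in (0.0, 1e-6, 1e-3, 10.0):
            P = transition_matrix(123.0, 456.0, dt)
            assert np.allclose(P.sum(axis=1), 1.0)
            assert np.all((P >= 0) & (P <= 1))

    def test_first_order_agreement_of_modes(self):
        k12, k21, dt = 100.0, 300.0, 1e-7  # k*dt = 1e-5 << 1
        exact = transition_matrix(k12, k21, dt)
        literal = transition_matrix(k12, k21, dt, mode="literal")
        assert exact[0, 1] == pytest.approx(k12 * dt, rel=1e-4)
        assert literal[0, 1] == pytest.approx(k12 * dt, rel=1e-4)

    def test_semigroup_property(self):
        k12, k21 = 222.0, 777.0
        P1 = transition_matrix(k12, k21, 1e-3)
        P2 = transition_matrix(k12, k21, 3e-3)
        P12 = transition_matrix(k12, k21, 4e-3)
        assert np.allclose(P1 @ P2, P12, atol=1e-14)

    def test_negative_dt_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(1.0, 1.0, -1.0)


class TestInitialState:
    def test_stationary_probability(self, rng):
        # dG = 1.5: P(state 1) = e^1.5/(1+e^1.5) ~ 0.8176
        k12, k21 = rates_from_energies(1.5, 7.5)
        n = 100_000
        draws = np.array([sample_initial_state(k12, k21, rng) for _ in range(n)])
        p1 = np.exp(1.5) / (1 + np.exp(1.5))
        f1 = np.mean(draws == 1)
        assert abs(f1 - p1) < 3 * np.sqrt(p1 * (1 - p1) / n)

    def test_symmetric_rates_give_half(self, rng):
        draws = [sample_initial_state(10.0, 10.0, rng) for _ in range(20_000)]
        assert abs(np.mean(np.array(draws) == 1) - 0.5) < 0.011


class TestStateTrajectory:
    def test_empty_for_zero_duration(self, rng):
        model = TwoStateModel.from_barrier(9.0, 1.5)
        traj = simulate_state_trajectory(model, 0.0, 1e-5, rng)
        assert traj.n_steps == 0
        assert traj.states_per_step().size == 0

    def test_mean_dwell_times_g9(self, rng):
        # G_barrier = 9 kBT: lifetimes 8.1 ms (state 1) and 1.8 ms (state 2)
        model = TwoStateModel.from_barrier(9.0, 1.5)
        traj = simulate_state_trajectory(model, 60.0, 1e-5, rng)
        d1, d2 = traj.dwell_times()
        assert d1.mean() == pytest.approx(8.1e-3, rel=0.05)
        assert d2.mean() == pytest.approx(1.8e-3, rel=0.05)

    def test_occupancy_matches_stationary_distribution(self, rng):
        model = TwoStateModel.from_barrier(7.0, 1.5)
        traj = simulate_state_trajectory(model, 30.0, 1e-5, rng)
        states = traj.states_per_step()
        f1 = np.mean(states == 1)
        # binomial error with the effective number of independent dwells
        n_eff = traj.switch_steps.size
        p = model.occupancy1
        assert abs(f1 - p) < 4 * np.sqrt(p * (1 - p) / max(n_eff, 1))

    def test_dwell_times_are_exponential(self, rng):
        # KS test against the exponential law at fine time resolution
        model = TwoStateModel.from_barrier(9.0, 1.5)
        traj = simulate_state_trajectory(model, 120.0, 1e-7, rng)
        d1, d2 = traj.dwell_times()
        assert d1.size > 1e4 / 2 and d2.size > 1e4 / 2
        for d, k in ((d1, model.k12), (d2, model.k21)):
            p = stats.kstest(d, "expon", args=(0, 1.0 / k)).pvalue
            assert p > 0.01

    def test_event_representation_alternates(self, rng):
        model = TwoStateModel.from_barrier(8.0, 1.5)
        traj = simulate_state_trajectory(model, 5.0, 1e-5, rng)
        states = traj.states_per_step()
        seg_states = states[np.concatenate(([0], traj.switch_steps))]
        assert np.all(np.abs(np.diff(seg_states.astype(int))) == 1)
        assert traj.duration == pytest.approx(5.0)


class TestTwoStateModel:
    def test_derived_quantities_consistent(self):
        m = TwoStateModel.from_barrier(10.0, 1.5)
        assert m.K == pytest.approx(np.exp(1.5), rel=1e-12)
        assert m.tau_K < min(m.tau1, m.tau2)
        assert m.G_barrier == pytest.approx(10.0)

    def test_from_lifetimes_round_trip(self):
        m = TwoStateModel.from_lifetimes(20.3e-3, 4.4e-3)
        assert m.tau1 == pytest.approx(20.3e-3, rel=1e-12)
        assert m.tau2 == pytest.approx(4.4e-3, rel=1e-12)
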