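"""Reaction-network construction, SSA/ODE simulation, and duration extraction."""

import numpy as np
import pytest

from sigtherm import (
    CascadeSpec,
    ConcentrationState,
    DurationProfile,
    Trajectory,
    build_network,
    extract_durations,
    activation_order,
    occurrence_probabilities,
    simulate_deterministic,
    simulate_stochastic,
)
from sigtherm.kinetics import (
    DurationExtractionError,
    LigandPulse,
    trajectory_from_tsv,
    trajectory_to_tsv,
)


def cascade_spec(n, k=1.0, kb=1.0, atp=1.0, ph=1.0, inactive=None, volume=1.0):
    return CascadeSpec(
        n_steps=n,
        forward_rates=[k] * (n - 1),
        backward_rates=[kb] * (n - 1),
        phosphatase_levels=[ph] * (n - 1),
        atp=atp,
        adp=1.0,
        pi=1.0,
        initial_inactive=inactive if inactive is not None else [100.0] * n,
        initial_active=[0.0] * n,
        volume=volume,
    )


def two_state_spec(k=0.02, kb=1.0, ligand=50.0, substrate=100.0, volume=1.0):
    """n=2 cascade whose receptor relaxes as a linear two-state system."""
    return CascadeSpec(
        2, [k], [kb], [1.0], 1.0, 1.0, 1.0, [ligand, substrate], [0.0, 0.0],
        volume=volume,
    )


class TestBuildNetwork:
    @pytest.mark.parametrize("n, expected", [(1, 0), (2, 2), (5, 8)])
    def test_reaction_count(self, n, expected):
        assert len(build_network(cascade_spec(n))) == expected

    def test_third_species_activation_rate_law(self):
        # activation of X_m3 must be proportional to [X_m2*].[X_m3].[ATP]
        spec = cascade_spec(5, k=2.0, atp=3.0)
        net = build_network(spec)
        inact = np.array([10.0, 0.0, 7.0, 0.0, 0.0])
        act = np.array([0.0, 5.0, 0.0, 0.0, 0.0])
        a = net.propensities(inact, act, 0.0, pulse=None)
        # reactions come in (activation, deactivation) pairs per step
        act_x3 = a[2]
        assert act_x3 == pytest.approx(2.0 * 3.0 * 5.0 * 7.0)
        rxn = net.reactions[2]
        assert rxn.kind == "activation" and rxn.step == 3
        assert "X_m2*" in rxn.reactants and "X_m3" in rxn.reactants

    def test_catalysts_conserved_in_stoichiometry(self):
        net = build_network(cascade_spec(4))
        for rxn in net.reactions:
            for sp, cnt in rxn.reactants.items():
                if sp in rxn.products:
                    assert rxn.products[sp] == cnt


class TestSimulateStochastic:
    def test_activation_fires_with_positive_propensity(self):
        spec = cascade_spec(2, inactive=[50.0, 50.0])
        net = build_network(spec)
        traj = simulate_stochastic(
            net, ConcentrationState([50, 50], [0, 0], 0.0), 5.0, seed=0
        )
        assert traj.active[:, 1].max() >= 1

    def test_near_absorbing_state_when_deactivation_negligible(self):
        spec = cascade_spec(3, kb=1e-9, inactive=[50.0, 50.0, 50.0])
        net = build_network(spec)
        traj = simulate_stochastic(
            net, ConcentrationState([50, 50, 50], [0, 0, 0], 0.0), 50.0, seed=1
        )
        assert traj.active[-1, 1] == 50 and traj.active[-1, 2] == 50

    def test_two_state_occupancy_matches_markov_stationary_half(self):
        # per-molecule switching rates equal -> stationary starred fraction 1/2
        spec = two_state_spec()  # k*ATP*L = 1 = kb*Ph
        net = build_network(spec)
        init = ConcentrationState([50, 100], [0, 0], 0.0)
        fracs = []
        for seed in range(12):
            traj = simulate_stochastic(net, init, 60.0, seed=seed)
            t, y = traj.times, traj.active[:, 1]
            dt = np.diff(t)
            sel = t[:-1] > 20.0  # discard the relaxation
            fracs.append(np.sum(y[:-1][sel] * dt[sel]) / np.sum(dt[sel]) / 100.0)
        fracs = np.array(fracs)
        se = fracs.std(ddof=1) / np.sqrt(len(fracs))
        assert abs(fracs.mean() - 0.5) < 3 * se + 1e-12

    def test_seed_determinism(self):
        spec = two_state_spec()
        net = build_network(spec)
        init = ConcentrationState([50, 100], [0, 0], 0.0)
        a = simulate_stochastic(net, init, 10.0, seed=42)
        b = simulate_stochastic(net, init, 10.0, seed=42)
        np.testing.assert_array_equal(a.times, b.times)
        np.testing.assert_array_equal(a.active, b.active)

    def test_conservation_exact_at_every_event(self):
        spec = cascade_spec(3, inactive=[30.0, 40.0, 30.0])
        net = build_network(spec)
        traj = simulate_stochastic(
            net, ConcentrationState([30, 40, 30], [0, 0, 0], 0.0), 5.0, seed=3
        )
        assert np.all(traj.totals() == 100.0)

    def test_rejects_non_integer_state(self):
        spec = cascade_spec(2)
        net = build_network(spec)
        with pytest.raises(ValueError, match="integer"):
            simulate_stochastic(net, ConcentrationState([1.5, 2], [0, 0], 0.0), 1.0, 0)

    def test_rejects_bad_t_max(self):
        spec = cascade_spec(2)
        net = build_network(spec)
        with pytest.raises(ValueError, match="t_max"):
            simulate_stochastic(net, ConcentrationState([1, 2], [0, 0], 0.0), -1.0, 0)


class TestSimulateDeterministic:
    def test_single_time_returns_initial_state(self):
        spec = cascade_spec(3)
        net = build_network(spec)
        init = ConcentrationState([10.0, 20.0, 30.0], [0.0, 0.0, 0.0], 0.0)
        traj = simulate_deterministic(net, init, [0.0])
        np.testing.assert_array_equal(traj.inactive[0], [10.0, 20.0, 30.0])

    def test_two_state_relaxation_matches_closed_form(self):
        k, kb, L, tot = 0.02, 1.0, 50.0, 100.0
        spec = two_state_spec(k=k, kb=kb, ligand=L, substrate=tot)
        net = build_network(spec)
        times = np.linspace(0.0, 10.0, 200)
        traj = simulate_deterministic(
            net, ConcentrationState([L, tot], [0.0, 0.0], 0.0), times
        )
        lam = k * L * 1.0 + kb * 1.0
        x_ss = tot * k * L / lam
        closed = x_ss * (1.0 - np.exp(-lam * times))
        assert np.max(np.abs(traj.active[:, 1] - closed)) < 1e-6

    def test_conservation_within_tolerance(self):
        spec = cascade_spec(4, inactive=[25.0, 25.0, 25.0, 25.0])
        net = build_network(spec)
        traj = simulate_deterministic(
            net,
            ConcentrationState(spec.initial_inactive, spec.initial_active, 0.0),
            np.linspace(0, 20, 100),
        )
        assert np.max(np.abs(traj.totals() - 100.0)) < 1e-9

    def test_non_monotone_grid_rejected(self):
        spec = cascade_spec(2)
        net = build_network(spec)
        init = ConcentrationState(spec.initial_inactive, spec.initial_active, 0.0)
        with pytest.raises(ValueError, match="increasing"):
            simulate_deterministic(net, init, [0.0, 2.0, 1.0])

    def test_ssa_ensemble_mean_tracks_ode(self):
        # law of large numbers: mean of replicate SSA runs follows the ODE
        spec = two_state_spec(volume=10.0, ligand=500.0, substrate=1000.0)
        net = build_network(spec)
        init = ConcentrationState([500, 1000], [0, 0], 0.0)
        tgrid = np.linspace(0.0, 5.0, 11)
        ode = simulate_deterministic(net, init, tgrid)
        runs = []
        for seed in range(40):
            tr = simulate_stochastic(net, init, 5.0, seed=seed)
            idx = np.searchsorted(tr.times, tgrid, side="right") - 1
            runs.append(tr.active[idx, 1])
        runs = np.array(runs)
        se = runs.std(axis=0, ddof=1) / np.sqrt(len(runs))
        z = np.abs(runs.mean(axis=0) - ode.active[:, 1]) / np.maximum(se, 1e-9)
        assert np.max(z[1:]) < 3.0


def triangular_pulse_traj(rise=2.0, fall=3.0, peak=5.0, t_start=1.0, dt=0.01):
    t_end = t_start + rise + fall
    times = np.arange(0.0, t_end + 1.0 + dt, dt)
    y = np.interp(times, [0.0, t_start, t_start + rise, t_end, t_end + 1.0],
                  [0.0, 0.0, peak, 0.0, 0.0])
    zeros = np.zeros_like(times)
    return Trajectory(times, zeros[:, None], y[:, None], "deterministic")


class TestExtractDurations:
    def test_triangular_pulse_recovers_rise_and_fall(self):
        traj = triangular_pulse_traj(rise=2.0, fall=3.0)
        prof = extract_durations(traj, [0.0], rise_fraction=1e-9)
        assert prof.forward[0] == pytest.approx(2.0, abs=1e-6)
        assert prof.backward[0] == pytest.approx(-3.0, abs=1e-6)

    def test_truncated_pulse_reports_truncation(self):
        times = np.linspace(0.0, 3.0, 100)
        y = np.interp(times, [0.0, 1.0, 3.0], [0.0, 0.0, 5.0])  # never comes back
        traj = Trajectory(times, np.zeros((100, 1)), y[:, None], "deterministic")
        with pytest.raises(DurationExtractionError, match="truncated"):
            extract_durations(traj, [0.0], rise_fraction=0.05)

    def test_flat_species_reports_which_step(self):
        times = np.linspace(0.0, 3.0, 50)
        flat = np.zeros((50, 2))
        pulse = np.interp(times, [0, 1, 2, 3], [0, 0, 5, 0])
        act = np.column_stack([pulse, np.zeros(50)])
        traj = Trajectory(times, flat, act, "deterministic")
        with pytest.raises(DurationExtractionError, match="step 2"):
            extract_durations(traj, [0.0, 0.0], rise_fraction=0.05)

    def test_matches_analytic_crossing_times_of_exponential_pulse(self):
        # receptor driven by a ligand gate: rise to quasi-steady, then decay
        k, kb, L, tot = 0.1, 0.5, 20.0, 100.0
        spec = two_state_spec(k=k, kb=kb, ligand=L, substrate=tot)
        net = build_network(spec)
        pulse = LigandPulse(onset=0.0, duration=4.0)
        times = np.linspace(0.0, 30.0, 6000)
        traj = simulate_deterministic(
            net, ConcentrationState([L, tot], [0.0, 0.0], 0.0), times, pulse=pulse
        )
        lam = k * L + kb
        x_ss = tot * k * L / lam
        peak = x_ss * (1.0 - np.exp(-lam * 4.0))
        rf = 0.05
        thresh = rf * peak
        # analytic onset: x_ss(1-e^(-lam t)) = thresh
        t_on = -np.log(1.0 - thresh / x_ss) / lam
        # analytic return: decay peak*e^(-kb (t-4)) = thresh
        t_ret = 4.0 + np.log(peak / thresh) / kb
        prof = extract_durations(traj, [0.0, 0.0], rise_fraction=rf, species=[1])
        dt_grid = times[1] - times[0]
        assert prof.forward[0] == pytest.approx(4.0 - t_on, abs=2 * dt_grid)
        assert prof.backward[0] == pytest.approx(-(t_ret - 4.0), abs=2 * dt_grid)

    def test_invariant_under_time_shift(self):
        traj = triangular_pulse_traj()
        shifted = Trajectory(
            traj.times + 17.3, traj.inactive, traj.active, "deterministic"
        )
        a = extract_durations(traj, [0.0], rise_fraction=0.05)
        b = extract_durations(shifted, [0.0], rise_fraction=0.05)
        np.testing.assert_allclose(a.forward, b.forward, atol=1e-12)
        np.testing.assert_allclose(a.backward, b.backward, atol=1e-12)


class TestOccurrenceProbabilities:
    def test_symmetric_single_step(self):
        p, q = occurrence_probabilities(ConcentrationState([50.0], [50.0], 0.0))
        assert p[0] == 0.5 and q[0] == 0.5

    def test_vertex_concentration(self):
        p, q = occurrence_probabilities(
            ConcentrationState([100.0, 0.0, 0.0, 0.0], [0.0] * 4, 0.0)
        )
        np.testing.assert_array_equal(p, [1.0, 0.0, 0.0, 0.0])
        np.testing.assert_array_equal(q, np.zeros(4))

    def test_direct_division(self):
        p, q = occurrence_probabilities(
            ConcentrationState([30.0, 10.0], [5.0, 5.0], 0.0)
        )
        np.testing.assert_allclose(p, [0.6, 0.2], rtol=0, atol=1e-15)
        np.testing.assert_allclose(q, [0.1, 0.1], rtol=0, atol=1e-15)
        assert p.sum() + q.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            occurrence_probabilities(ConcentrationState([0.0], [0.0], 0.0))


class TestActivationOrder:
    def test_constructed_pulses_sorted_by_onset(self):
        times = np.linspace(0.0, 10.0, 1000)
        y1 = np.interp(times, [1.0, 2.0, 3.0], [0, 5, 0])
        y2 = np.interp(times, [0.5, 1.5, 2.5], [0, 5, 0])
        traj = Trajectory(
            times, np.zeros((1000, 2)), np.column_stack([y1, y2]), "deterministic"
        )
        order = activation_order(traj, [0.0, 0.0], rise_fraction=1e-6)
        assert order.index("X_m2*") < order.index("X_m1*")

    def test_sequential_cascade_starred_labels_in_index_order(self):
        spec = CascadeSpec(
            3, [0.05, 0.05], [0.5, 0.5], [1.0, 1.0], 1.0, 1.0, 1.0,
            [20.0, 50.0, 50.0], [0.0, 0.0, 0.0],
        )
        net = build_network(spec)
        traj = simulate_deterministic(
            net,
            ConcentrationState(spec.initial_inactive, spec.initial_active, 0.0),
            np.linspace(0, 60, 4000),
            pulse=LigandPulse(onset=0.5, duration=3.0),
        )
        order = activation_order(traj, [0.0] * 3, species=[1, 2])
        assert order.index("X_m2*") < order.index("X_m3*")

    def test_order_consistent_with_brute_force_crossings(self):
        spec = CascadeSpec(
            3, [0.05, 0.08], [0.4, 0.9], [1.0, 1.0], 1.0, 1.0, 1.0,
            [20.0, 50.0, 50.0], [0.0, 0.0, 0.0],
        )
        net = build_network(spec)
        times = np.linspace(0, 80, 8000)
        traj = simulate_deterministic(
            net,
            ConcentrationState(spec.initial_inactive, spec.initial_active, 0.0),
            times,
            pulse=LigandPulse(onset=0.5, duration=3.0),
        )
        rf = 0.05
        order = activation_order(traj, [0.0] * 3, rise_fraction=rf, species=[1, 2])
        # brute-force scan: onset = first sample above rf*peak; recovery = peak time
        events = []
        for s, lbl_on, lbl_rec in [(1, "X_m2*", "X_m2"), (2, "X_m3*", "X_m3")]:
            y = traj.active[:, s]
            thr = rf * y.max()
            events.append((times[np.argmax(y > thr)], lbl_on))
            events.append((times[np.argmax(y)], lbl_rec))
        expected = [lbl for _, lbl in sorted(events)]
        assert order == expected


class TestTrajectoryTsv:
    def test_round_trip(self, tmp_path):
        spec = cascade_spec(3, inactive=[10.0, 20.0, 30.0])
        net = build_network(spec)
        traj = simulate_deterministic(
            net,
            ConcentrationState(spec.initial_inactive, spec.initial_active, 0.0),
            np.linspace(0, 5, 20),
        )
        path = tmp_path / "traj.tsv"
        trajectory_to_tsv(traj, path)
        back = trajectory_from_tsv(path)
        np.testing.assert_allclose(back.times, traj.times)
        np.testing.assert_allclose(back.active, traj.active)
        np.testing.assert_allclose(back.inactive, traj.inactive)
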