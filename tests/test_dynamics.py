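"""Integration, steady-state location, parameter fitting, sensitivity sweeps."""

import numpy as np
import pytest
from scipy.stats import qmc

from grnscape import zoo
from grnscape.dynamics import (
    DynamicsSettings,
    FitInfeasibleError,
    TimeSeries,
    UnderdeterminedError,
    fit_to_attractors,
    fit_to_timeseries,
    fixed_point_jacobian,
    integrate,
    sensitivity_sweep,
    steady_states,
)
from grnscape.model import GeneNetwork, NoiseModel, force, logit, sigmoid


def flat_net(n, l=None):
    return GeneNetwork([f"g{i}" for i in range(n)], np.zeros((n, n)), l or np.zeros(n))


class TestIntegrate:
    def test_relaxes_to_half_without_interactions(self):
        traj = integrate(flat_net(2), NoiseModel(0.5), [0.1, 0.9], DynamicsSettings(t_max=60))
        np.testing.assert_allclose(traj.values[-1], 0.5, atol=1e-6)

    def test_closed_form_fixed_point(self):
        noise = NoiseModel(0.5)
        net = flat_net(1, [float(noise.theta * logit(0.8))])
        traj = integrate(net, noise, [0.3], DynamicsSettings(t_max=60))
        assert traj.values[-1, 0] == pytest.approx(0.8, abs=1e-6)

    def test_bistable_switch_two_limits(self, single_gene_entry):
        e = single_gene_entry
        lo = integrate(e.network, e.noise, [0.05], DynamicsSettings(t_max=100))
        hi = integrate(e.network, e.noise, [0.95], DynamicsSettings(t_max=100))
        assert lo.values[-1, 0] < 0.1 < 0.9 < hi.values[-1, 0]

    def test_trajectory_stays_in_unit_cube(self, toggle_entry):
        traj = integrate(
            toggle_entry.network, toggle_entry.noise, [0.02, 0.97], DynamicsSettings()
        )
        assert np.all(traj.values > 0) and np.all(traj.values < 1)

    def test_settings_stability_guard(self):
        with pytest.raises(ValueError):
            DynamicsSettings(dt=1.5, gamma=1.0, eta=1.0)


class TestSteadyStates:
    def test_unique_state_without_interactions(self):
        states = steady_states(flat_net(3), NoiseModel(0.5), n_starts=10, seed=0)
        assert len(states) == 1
        np.testing.assert_allclose(states[0], 0.5, atol=1e-9)

    def test_toggle_two_mirror_states(self, toggle_entry):
        states = steady_states(toggle_entry.network, toggle_entry.noise, n_starts=60, seed=1)
        assert len(states) == 2
        np.testing.assert_allclose(states[0], states[1][::-1], atol=1e-6)

    def test_toggle_against_dense_fixed_point_scan(self, toggle_entry):
        """Residual sign-change scan of v = g(h/Theta) over a 1000^2 grid."""
        net, noise = toggle_entry.network, toggle_entry.noise
        g = np.linspace(0.001, 0.999, 1000)
        V1, V2 = np.meshgrid(g, g, indexing="ij")
        V = np.stack([V1, V2], axis=-1)
        R = V - sigmoid(force(net, V) / noise.theta)
        s1, s2 = np.sign(R[..., 0]), np.sign(R[..., 1])
        cross1 = (s1[:-1, :-1] * s1[1:, :-1] < 0) | (s1[:-1, :-1] * s1[:-1, 1:] < 0)
        cross2 = (s2[:-1, :-1] * s2[1:, :-1] < 0) | (s2[:-1, :-1] * s2[:-1, 1:] < 0)
        cells = np.argwhere(cross1 & cross2)
        # cluster candidate cells; the toggle has 2 stable + 1 saddle solution
        pts = (cells + 0.5) / 1000
        clusters = []
        for p in pts:
            for c in clusters:
                if np.max(np.abs(p - c[0])) < 0.05:
                    c.append(p)
                    break
            else:
                clusters.append([p])
        assert len(clusters) == 3
        states = steady_states(net, noise, n_starts=60, seed=0)
        assert len(states) == 2
        for v in states:
            assert any(np.max(np.abs(v - np.mean(c, axis=0))) < 0.01 for c in clusters)

    def test_single_gene_zoo_two_states(self, single_gene_entry):
        states = steady_states(
            single_gene_entry.network, single_gene_entry.noise, n_starts=40, seed=0
        )
        assert len(states) == 2

    def test_states_satisfy_fixed_point_equation(self, toggle_entry):
        net, noise = toggle_entry.network, toggle_entry.noise
        for v in steady_states(net, noise, n_starts=30, seed=3):
            assert np.max(np.abs(v - sigmoid(force(net, v) / noise.theta))) < 1e-8

    def test_deterministic_under_seed(self, toggle_entry):
        a = steady_states(toggle_entry.network, toggle_entry.noise, n_starts=20, seed=7)
        b = steady_states(toggle_entry.network, toggle_entry.noise, n_starts=20, seed=7)
        assert all((x == y).all() for x, y in zip(a, b))


def _toggle_training_series(entry, noise_sd, n_traj=10, n_points=5):
    sampler = qmc.Halton(d=2, seed=7)
    starts = 0.1 + 0.8 * sampler.random(n_traj)
    s = DynamicsSettings(dt=0.2, t_max=0.2 * (n_points - 1))
    return [
        zoo.generate_synthetic_timeseries(
            entry, v0, noise_sd, seed=100 + i, n_points=n_points, dt=0.2, settings=s
        )
        for i, v0 in enumerate(starts)
    ], s


class TestFitToTimeseries:
    def test_noiseless_recovery(self, toggle_entry):
        e = toggle_entry
        series, s = _toggle_training_series(e, 0.0)
        wm, lm = e.network.W != 0, e.network.l != 0
        res = fit_to_timeseries(series, wm, lm, e.noise, settings=s, seed=0, n_starts=2)
        rel = np.abs((res.network.W[wm] - e.network.W[wm]) / e.network.W[wm])
        assert rel.max() < 0.05
        rel_l = np.abs((res.network.l[lm] - e.network.l[lm]) / e.network.l[lm])
        assert rel_l.max() < 0.05

    def test_underdetermined_constant_series(self):
        ts = TimeSeries([0.0, 1.0], [[0.5, 0.5], [0.5, 0.5]], ("a", "b"))
        with pytest.raises(UnderdeterminedError):
            fit_to_timeseries(
                ts, np.ones((2, 2), bool), np.ones(2, bool), NoiseModel(0.5)
            )

    def test_deterministic_under_seed(self, toggle_entry):
        e = toggle_entry
        series, s = _toggle_training_series(e, 0.01, n_traj=4)
        wm, lm = e.network.W != 0, e.network.l != 0
        r1 = fit_to_timeseries(series, wm, lm, e.noise, settings=s, seed=5, n_starts=2)
        r2 = fit_to_timeseries(series, wm, lm, e.noise, settings=s, seed=5, n_starts=2)
        assert (r1.network.W == r2.network.W).all()


class TestFitToAttractors:
    def test_trivial_centre_target(self):
        res = fit_to_attractors(
            [np.full(2, 0.5)],
            np.eye(2, dtype=bool),
            np.ones(2, bool),
            NoiseModel(0.5),
            seed=0,
        )
        assert res.residual < 1e-10
        np.testing.assert_allclose(res.network.W, 0.0, atol=1e-6)
        np.testing.assert_allclose(res.network.l, 0.0, atol=1e-6)

    def test_toggle_mirror_targets_become_stable_states(self):
        wm = np.array([[True, True], [True, True]])
        lm = np.ones(2, bool)
        noise = NoiseModel(0.4)
        targets = [np.array([0.88, 0.12]), np.array([0.12, 0.88])]
        res = fit_to_attractors(targets, wm, lm, noise, seed=0, n_starts=4)
        states = steady_states(res.network, noise, n_starts=40, seed=0)
        for t in targets:
            assert any(np.max(np.abs(t - v)) < 1e-3 for v in states)
        for t in targets:
            rho = np.max(np.abs(np.linalg.eigvals(fixed_point_jacobian(res.network, t, noise))))
            assert rho < 1.0

    def test_target_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            fit_to_attractors(
                [np.array([1.2, 0.5])], np.ones((2, 2), bool), np.ones(2, bool), NoiseModel(0.5)
            )

    def test_infeasible_topology_reported(self):
        # a single gene with no parameters free except a bounded input
        # cannot hold two different targets fixed simultaneously
        with pytest.raises(FitInfeasibleError):
            fit_to_attractors(
                [np.array([0.2]), np.array([0.8])],
                np.zeros((1, 1), bool),
                np.ones(1, bool),
                NoiseModel(0.5),
                n_starts=2,
            )


class TestSensitivitySweep:
    def test_barrier_decreases_with_temperature(self, single_gene_entry):
        e = single_gene_entry
        tab = sensitivity_sweep(e.network, e.noise, "T", [0.2, 0.3, 0.4], d=200)
        b = tab["barrier_height"].to_numpy()
        assert (np.diff(b) < 0).all()
        assert (tab["n_attractors"] == 2).all()

    def test_self_interaction_creates_bistability(self, single_gene_entry):
        e = single_gene_entry
        tab = sensitivity_sweep(e.network, e.noise, "W[A,A]", [0.0, 2.0, 4.0], d=200)
        assert tab["n_attractors"].tolist() == [1, 1, 2]

    def test_gamma_uses_dynamics_route(self, single_gene_entry):
        e = single_gene_entry
        tab = sensitivity_sweep(e.network, e.noise, "gamma", [1.0], d=50)
        assert tab["n_attractors"].iloc[0] == 2
        assert np.isnan(tab["barrier_height"].iloc[0])

    def test_unknown_parameter_rejected(self, single_gene_entry):
        with pytest.raises(ValueError):
            sensitivity_sweep(
                single_gene_entry.network, single_gene_entry.noise, "Q[0]", [1.0]
            )


class TestTimeSeries:
    def test_validation(self):
        with pytest.raises(ValueError):
            TimeSeries([0.0, 0.0], [[0.5], [0.5]])
        with pytest.raises(ValueError):
            TimeSeries([0.0, 1.0], [[0.5], [1.5]])

    def test_frame_round_trip(self):
        ts = TimeSeries([0.0, 0.5, 1.0], [[0.2, 0.8], [0.3, 0.7], [0.4, 0.6]], ("x", "y"))
        back = TimeSeries.from_frame(ts.to_frame())
        np.testing.assert_allclose(back.values, ts.values)
        assert back.gene_names == ts.gene_names


class TestSyntheticTimeseries:
    def test_noiseless_matches_integrator(self, toggle_entry):
        e = toggle_entry
        s = DynamicsSettings(dt=0.2, t_max=4.0)
        ts = zoo.generate_synthetic_timeseries(e, [0.3, 0.6], 0.0, seed=0, n_points=10, settings=s)
        traj = integrate(e.network, e.noise, [0.3, 0.6], s)
        np.testing.assert_allclose(ts.values, traj.values[:10], atol=1e-12)

    def test_seed_reproducibility(self, toggle_entry):
        a = zoo.generate_synthetic_timeseries(toggle_entry, [0.3, 0.6], 0.02, seed=9)
        b = zoo.generate_synthetic_timeseries(toggle_entry, [0.3, 0.6], 0.02, seed=9)
        assert (a.values == b.values).all()
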