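"""FSSH machinery: couplings, electronic propagation, hops, trajectories."""

import numpy as np
import pytest

from vibronica import fixtures as fx, lvc_model as lvc
from vibronica import surface_hopping as sh
from vibronica import units
from vibronica.errors import PropagationError


def _harmonic_model(omega=0.005):
    return lvc.LVCModel(omega=[omega], epsilon=[0.0], kappa=[[0.0]],
                        lam=np.zeros((1, 1, 1)))


class TestHstTdc:
    def test_symmetric_overlap_gives_zero(self):
        s = np.array([[0.9, 0.1], [0.1, 0.9]])
        ov = lvc.OverlapMatrix(S=s, dt=1.0, sign_flips=np.ones(2),
                               permutation=np.arange(2))
        assert np.all(sh.hst_tdc(ov).T == 0)

    def test_rotation_angle(self):
        theta, dt = 0.05, 2.0
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        ov = lvc.OverlapMatrix(S=rot, dt=dt, sign_flips=np.ones(2),
                               permutation=np.arange(2))
        t = sh.hst_tdc(ov).T
        assert t[0, 1] == pytest.approx(-np.sin(theta) / dt, rel=1e-12)
        assert t[1, 0] == -t[0, 1]

    def test_nonpositive_dt_rejected(self):
        ov = lvc.OverlapMatrix(S=np.eye(2), dt=0.0, sign_flips=np.ones(2),
                               permutation=np.arange(2))
        with pytest.raises(PropagationError):
            sh.hst_tdc(ov)

    def test_converges_to_analytic_tdc(self):
        """Halving dt reduces the HST-vs-analytic deviation >= 3.5x."""
        m = fx.make_two_state_crossing(gap=0.05, slope=0.01,
                                       coupling_const=0.005, omega=0.005)
        v = 0.05

        def max_dev(dt):
            ts = np.arange(0.0, 300.0, dt)
            pts = [lvc.evaluate_adiabatic(m, np.array([-8.0 + v * t]))
                   for t in ts]
            devs = []
            for k in range(len(ts) - 1):
                ov, _ = lvc.frame_overlap(pts[k].U, pts[k + 1].U, dt)
                t_hst = sh.hst_tdc(ov).T[0, 1]
                t_mid = 0.5 * v * (pts[k].nac[0, 1, 0]
                                   + pts[k + 1].nac[0, 1, 0])
                devs.append(abs(t_hst - t_mid))
            return max(devs)

        assert max_dev(4.0) / max_dev(2.0) >= 3.5


class TestElectronicPropagation:
    def test_single_state_pure_phase(self):
        c = np.array([1.0 + 0j])
        e = np.array([0.3])
        out = sh.propagate_electronic(c, (e, e), (np.zeros((1, 1)),) * 2,
                                      2.0)
        assert out[0] == pytest.approx(np.exp(-1j * 0.3 * 2.0), abs=1e-12)

    def test_rabi_closed_form(self):
        t12 = 0.02
        t_mat = np.array([[0.0, t12], [-t12, 0.0]])
        e = np.zeros(2)
        c = np.array([1.0 + 0j, 0.0])
        dt, n = 1.0, 150
        for k in range(n):
            c = sh.propagate_electronic(c, (e, e), (t_mat, t_mat), dt)
            expected = np.sin(t12 * (k + 1) * dt) ** 2
            assert abs(abs(c[1]) ** 2 - expected) < 1e-6

    def test_three_state_norm_conservation(self, rng):
        n_states = 3
        e0 = rng.uniform(0, 0.5, n_states)
        t = rng.standard_normal((n_states, n_states)) * 0.01
        t = 0.5 * (t - t.T)
        c = rng.standard_normal(n_states) + 1j * rng.standard_normal(n_states)
        c /= np.linalg.norm(c)
        for _ in range(10000):
            c = sh.propagate_electronic(c, (e0, e0), (t, t), 0.5, n_sub=1)
        assert abs(np.sum(np.abs(c) ** 2) - 1.0) < 1e-10

    def test_non_finite_input_rejected(self):
        with pytest.raises(PropagationError):
            sh.propagate_electronic(
                np.array([np.nan + 0j, 0]), (np.zeros(2), np.zeros(2)),
                (np.zeros((2, 2)), np.zeros((2, 2))), 1.0,
            )


class TestHopProbabilities:
    def test_zero_coupling_zero_probability(self):
        c = np.array([0.8 + 0j, 0.6])
        tdc = sh.CouplingMatrix(np.zeros((2, 2)), "nac")
        assert np.all(sh.hop_probabilities(c, tdc, 0, 1.0) == 0)

    def test_matches_population_flux(self):
        """g equals the negative population derivative of the active state
        times dt/|c_a|^2 when that derivative is negative."""
        t12 = 0.03
        t_mat = np.array([[0.0, t12], [-t12, 0.0]])
        e = np.zeros(2)
        c = np.array([0.9 + 0j, 0.1 + 0.2j])
        c /= np.linalg.norm(c)
        dt = 1e-4
        g = sh.hop_probabilities(c, sh.CouplingMatrix(t_mat, "nac"), 0, dt)
        c_next = sh.propagate_electronic(c, (e, e), (t_mat, t_mat), dt, 1)
        dpop = (abs(c_next[0]) ** 2 - abs(c[0]) ** 2) / dt
        if dpop < 0:
            expected = -dpop * dt / abs(c[0]) ** 2
            assert g[1] == pytest.approx(expected, rel=1e-3)
        else:
            assert g[1] == 0.0

    def test_total_never_exceeds_one(self, rng):
        for _ in range(2000):
            c = rng.standard_normal(3) + 1j * rng.standard_normal(3)
            c /= np.linalg.norm(c)
            t = rng.standard_normal((3, 3)) * rng.uniform(0, 5)
            t = 0.5 * (t - t.T)
            g = sh.hop_probabilities(c, sh.CouplingMatrix(t, "nac"), 0, 1.0)
            assert np.all(g >= 0)
            assert g.sum() <= 1.0 + 1e-12

    def test_depleted_active_state_warns(self):
        c = np.array([1e-9 + 0j, 1.0])
        t = sh.CouplingMatrix(np.array([[0, 0.1], [-0.1, 0]]), "nac")
        with pytest.warns(UserWarning, match="depleted"):
            g = sh.hop_probabilities(c, t, 0, 1.0)
        assert np.all(g == 0)


class TestAttemptHop:
    def _point(self, gap=0.01):
        m = fx.make_two_state_crossing(gap=gap, slope=0.0,
                                       coupling_const=0.001)
        return lvc.evaluate_adiabatic(m, np.zeros(1)), m.omega

    def test_no_probability_no_hop(self):
        point, omega = self._point()
        active, p, frustrated = sh.attempt_hop(
            np.zeros(2), 0.5, 0, point, np.array([3.0]), omega)
        assert (active, frustrated) == (0, False)
        assert np.array_equal(p, [3.0])

    def test_downward_hop_gains_gap(self):
        point, omega = self._point(gap=0.01)
        p0 = np.array([2.0])
        active, p1, frustrated = sh.attempt_hop(
            np.array([0.9, 0.0]), 0.1, 1, point, p0, omega)
        assert active == 0 and not frustrated
        ke0 = 0.5 * float(omega @ (p0 * p0))
        ke1 = 0.5 * float(omega @ (p1 * p1))
        gap = point.energies[1] - point.energies[0]
        assert ke1 - ke0 == pytest.approx(gap, rel=1e-10)

    def test_insufficient_energy_frustrates(self):
        point, omega = self._point(gap=0.5)
        p0 = np.array([0.1])  # tiny kinetic energy
        active, p1, frustrated = sh.attempt_hop(
            np.array([0.0, 0.9]), 0.1, 0, point, p0, omega)
        assert active == 0 and frustrated
        assert np.array_equal(p1, p0)


class TestRunTrajectory:
    def test_harmonic_period(self):
        omega = 0.005
        m = _harmonic_model(omega)
        dt = 0.25 * units.FS_TO_AUT
        n = 2500
        traj = sh.run_trajectory(m, np.array([1.0]), np.array([0.0]), 0,
                                 dt, n)
        q = np.array([s.Q[0] for s in traj.states])
        t = np.array([s.time for s in traj.states])
        # successive positive-going zero crossings -> period
        sign_change = np.where((q[:-1] < 0) & (q[1:] >= 0))[0]
        crossings = [t[i] - q[i] * (t[i + 1] - t[i]) / (q[i + 1] - q[i])
                     for i in sign_change]
        periods = np.diff(crossings)
        assert abs(periods.mean() - 2 * np.pi / omega) \
            < 1e-3 * 2 * np.pi / omega
        assert traj.n_hops == 0

    def test_energy_conservation(self):
        m = _harmonic_model(0.0023)
        traj = sh.run_trajectory(m, np.array([1.0]), np.array([0.0]), 0,
                                 0.5 * units.FS_TO_AUT, 1000)
        drift = np.abs(traj.energy_history - traj.energy_history[0]).max()
        assert drift < 1e-6

    def test_uncoupled_states_never_hop(self):
        m = fx.make_two_state_crossing(gap=0.1, slope=0.005,
                                       coupling_const=0.0,
                                       coupling_linear=0.0)
        traj = sh.run_trajectory(m, np.array([1.0]), np.array([2.0]), 1,
                                 0.5 * units.FS_TO_AUT, 400,
                                 rng=np.random.default_rng(0))
        assert traj.n_hops == 0
        pops = np.abs(traj.states[-1].coefficients) ** 2
        assert pops[1] == pytest.approx(1.0, abs=1e-10)

    def test_norm_conserved_through_crossing(self):
        m = fx.make_two_state_crossing(coupling_const=0.01)
        traj = sh.run_trajectory(m, np.array([-8.0]), np.array([15.0]), 0,
                                 0.1 * units.FS_TO_AUT, 150,
                                 rng=np.random.default_rng(1))
        for s in traj.states:
            assert abs(np.sum(np.abs(s.coefficients) ** 2) - 1.0) < 1e-8

    def test_time_reversal_retraces(self):
        m = _harmonic_model(0.004)
        dt = 0.25 * units.FS_TO_AUT
        fwd = sh.run_trajectory(m, np.array([1.5]), np.array([0.3]), 0,
                                dt, 500)
        end = fwd.states[-1]
        back = sh.run_trajectory(m, end.Q, -end.P, 0, dt, 500)
        assert np.abs(back.states[-1].Q - fwd.states[0].Q).max() < 1e-6
        assert np.abs(back.states[-1].P + fwd.states[0].P).max() < 1e-6

    def test_deterministic_per_seed(self):
        m = fx.make_two_state_crossing(coupling_const=0.01)
        runs = [sh.run_trajectory(m, np.array([-8.0]), np.array([15.0]), 0,
                                  0.1 * units.FS_TO_AUT, 120,
                                  rng=np.random.default_rng(7))
                for _ in range(2)]
        assert np.array_equal(runs[0].active_history, runs[1].active_history)
        assert np.array_equal(runs[0].energy_history, runs[1].energy_history)

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_escape_terminates_gracefully(self):
        # absurd step size blows the integrator up -> overflow, not raise
        m = lvc.LVCModel(omega=[0.5], epsilon=[0.0], kappa=[[5.0]],
                         lam=np.zeros((1, 1, 1)))
        traj = sh.run_trajectory(m, np.array([1.0]), np.array([0.0]), 0,
                                 1e8, 50)
        assert traj.termination in ("escaped", "completed")

    def test_invalid_source_rejected(self):
        with pytest.raises(PropagationError):
            sh.run_trajectory(_harmonic_model(), np.zeros(1), np.zeros(1),
                              0, 1.0, 10, tdc_source="bogus")


class TestEnsembleAnalysis:
    def _stuck_trajectories(self, n=4):
        m = fx.make_displaced_two_state(kappa_excited=0.0)
        return [sh.run_trajectory(m, np.zeros(1), np.zeros(1), 0,
                                  1.0 * units.FS_TO_AUT, 50)
                for _ in range(n)]

    def test_all_on_ground_state(self):
        trajs = self._stuck_trajectories()
        t_grid = np.linspace(0, 40 * units.FS_TO_AUT, 10)
        pops = sh.ensemble_populations(trajs, t_grid)
        assert np.array_equal(pops[:, 0], np.ones(10))
        assert np.all(pops[:, 1:] == 0)

    def test_duplicate_copies_idempotent(self):
        trajs = self._stuck_trajectories(2)
        t_grid = np.linspace(0, 40 * units.FS_TO_AUT, 10)
        one = sh.ensemble_populations([trajs[0]], t_grid)
        two = sh.ensemble_populations([trajs[0], trajs[0]], t_grid)
        assert np.array_equal(one, two)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(PropagationError):
            sh.ensemble_populations([], np.zeros(1))

    def test_fit_recovers_generating_rate(self, rng):
        k_true = 0.01
        t = np.linspace(0, 300, 200)
        p = np.exp(-k_true * t) * (1 + 0.01 * rng.standard_normal(t.size))
        k, se = sh.fit_decay(p, t)
        assert abs(k - k_true) < 2 * max(se, 1e-6)

    def test_ensemble_seeding_order_independent(self):
        m = fx.make_two_state_crossing(coupling_const=0.01)
        ics = [(np.array([-8.0]), np.array([15.0])) for _ in range(3)]
        ens = sh.run_ensemble(m, ics, 0, 0.1 * units.FS_TO_AUT, 100,
                              master_seed=5)
        solo = sh.run_trajectory(
            m, ics[2][0], ics[2][1], 0, 0.1 * units.FS_TO_AUT, 100,
            rng=np.random.default_rng([5, 2]))
        assert np.array_equal(ens[2].active_history, solo.active_history)
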