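"""Ensemble spectra, transient maps, photolysis integral, kinetics."""

import math

import numpy as np
import pytest

from vibronica import fixtures as fx
from vibronica import spectra as sp
from vibronica import surface_hopping as sh
from vibronica import units
from vibronica.errors import KineticsError, SpectrumError

C_PREF = sp.CROSS_SECTION_PREFACTOR_CM2_EV


@pytest.fixture
def bright_model():
    """2-state model, vertical gap 0.1 E_h, z-polarized unit dipole."""
    return fx.make_displaced_two_state(gap=0.1, kappa_excited=-0.02,
                                       dipole=1.0)


class TestBroadening:
    @pytest.mark.parametrize("kind", ["gaussian", "lorentzian"])
    def test_unit_area(self, kind):
        spec = sp.BroadeningSpec(kind=kind, fwhm_ev=0.2)
        x = np.linspace(-400.0, 400.0, 4_000_001)
        area = np.trapezoid(spec.lineshape(x), x)
        assert area == pytest.approx(1.0, abs=1e-3 if kind == "lorentzian"
                                     else 1e-9)

    def test_fwhm_definition(self):
        spec = sp.BroadeningSpec(kind="gaussian", fwhm_ev=0.2)
        peak = spec.lineshape(np.array([0.0]))[0]
        half = spec.lineshape(np.array([0.1]))[0]
        assert half == pytest.approx(peak / 2.0, rel=1e-12)

    def test_invalid_width(self):
        with pytest.raises(SpectrumError):
            sp.BroadeningSpec(fwhm_ev=0.0)

    def test_invalid_kind(self):
        with pytest.raises(SpectrumError):
            sp.BroadeningSpec(kind="voigt")


class TestTransitions:
    def test_fixed_geometry_fixed_gap(self, bright_model):
        m = fx.make_displaced_two_state(gap=0.1, kappa_excited=0.0)
        tr = sp.transitions_from_ensemble(m, [np.zeros(1)] * 5)
        assert np.allclose(tr.delta_e, 0.1)

    def test_linear_gap_with_kappa_difference(self):
        kappa = -0.02
        m = fx.make_displaced_two_state(gap=0.1, kappa_excited=kappa)
        qs = [np.array([q]) for q in (-1.0, 0.0, 2.0)]
        tr = sp.transitions_from_ensemble(m, qs)
        for q, de in zip(qs, tr.delta_e[:, 0]):
            assert de == pytest.approx(0.1 + kappa * q[0], rel=1e-12)

    def test_zero_dipole_zero_strength(self):
        m = fx.make_displaced_two_state(dipole=0.0)
        tr = sp.transitions_from_ensemble(m, [np.zeros(1)])
        assert np.all(tr.f == 0)

    def test_too_many_states_rejected(self, bright_model):
        with pytest.raises(SpectrumError):
            sp.transitions_from_ensemble(bright_model, [np.zeros(1)], 5)


class TestNEASpectrum:
    def test_single_transition_area(self):
        tr = sp.TransitionSet(delta_e=[[0.1]], f=[[0.7]])
        grid = np.linspace(1.0, 4.5, 20000)
        spec = sp.nea_spectrum(
            tr, sp.BroadeningSpec(fwhm_ev=0.1, grid_ev=grid))
        area = np.trapezoid(spec.sigma, spec.grid_ev)
        assert area == pytest.approx(C_PREF * 0.7, rel=1e-6)

    def test_linearity_in_f(self):
        tr1 = sp.TransitionSet(delta_e=[[0.1]], f=[[0.3]])
        tr2 = sp.TransitionSet(delta_e=[[0.1]], f=[[0.6]])
        grid = np.linspace(2.0, 3.5, 500)
        b = sp.BroadeningSpec(fwhm_ev=0.1, grid_ev=grid)
        assert np.allclose(sp.nea_spectrum(tr2, b).sigma,
                           2 * sp.nea_spectrum(tr1, b).sigma)

    def test_duplicate_geometries_idempotent(self):
        one = sp.TransitionSet(delta_e=[[0.1, 0.12]], f=[[0.3, 0.1]])
        two = sp.TransitionSet(delta_e=[[0.1, 0.12]] * 2, f=[[0.3, 0.1]] * 2)
        b = sp.BroadeningSpec(fwhm_ev=0.1)
        assert np.allclose(sp.nea_spectrum(one, b).sigma,
                           sp.nea_spectrum(two, b).sigma)

    def test_decomposition_sums_to_total(self, rng):
        de = 0.1 + 0.01 * rng.standard_normal((20, 2))
        f = np.abs(rng.standard_normal((20, 2)))
        spec = sp.nea_spectrum(sp.TransitionSet(de, f),
                               sp.BroadeningSpec(fwhm_ev=0.15))
        assert np.allclose(spec.per_transition.sum(0), spec.sigma)

    @pytest.mark.parametrize("kind", ["gaussian", "lorentzian"])
    def test_sum_rule_independent_of_width(self, kind, rng):
        """Total area = C * mean total f, for any width (truncation-
        corrected on the finite grid)."""
        de = 0.11 + 0.005 * rng.standard_normal((50, 1))
        f = np.abs(rng.standard_normal((50, 1)))
        grid = np.linspace(0.5, 5.5, 40000)
        for fwhm in (0.05, 0.2):
            b = sp.BroadeningSpec(kind=kind, fwhm_ev=fwhm, grid_ev=grid)
            spec = sp.nea_spectrum(sp.TransitionSet(de, f), b)
            area = np.trapezoid(spec.sigma, grid)
            # analytic in-grid mass of each line
            if kind == "gaussian":
                from scipy.special import erf
                s = fwhm / (2 * math.sqrt(2 * math.log(2)))
                centers = (de / units.EV_TO_HARTREE).ravel()
                frac = 0.5 * (
                    erf((grid[-1] - centers) / (s * math.sqrt(2)))
                    - erf((grid[0] - centers) / (s * math.sqrt(2)))
                )
            else:
                hw = fwhm / 2
                centers = (de / units.EV_TO_HARTREE).ravel()
                frac = (np.arctan((grid[-1] - centers) / hw)
                        - np.arctan((grid[0] - centers) / hw)) / math.pi
            expected = C_PREF * np.mean(f.ravel() * frac)
            assert area == pytest.approx(expected, rel=1e-4)

    def test_first_moment_converges_to_weighted_mean(self):
        de = np.array([[0.10, 0.14]])
        f = np.array([[0.3, 0.6]])
        grid = np.linspace(2.0, 4.5, 60000)
        spec = sp.nea_spectrum(sp.TransitionSet(de, f),
                               sp.BroadeningSpec(fwhm_ev=0.005,
                                                 grid_ev=grid))
        m0 = np.trapezoid(spec.sigma, grid)
        m1 = np.trapezoid(spec.sigma * grid, grid)
        expected = (f * de).sum() / f.sum() / units.EV_TO_HARTREE
        assert m1 / m0 == pytest.approx(expected, rel=1e-5)


class TestTransient:
    def _frozen_trajectories(self, model, n=3, steps=40):
        return [sh.run_trajectory(model, np.zeros(1), np.zeros(1), 0,
                                  1.0 * units.FS_TO_AUT, steps)
                for _ in range(n)]

    def test_static_limit_equals_nea(self):
        m = fx.make_displaced_two_state(gap=0.1, kappa_excited=0.0)
        trajs = self._frozen_trajectories(m)
        grid = np.linspace(1.5, 4.0, 400)
        b = sp.BroadeningSpec(fwhm_ev=0.1, grid_ev=grid)
        tmap = sp.transient_spectrum(trajs, m, 1, b)
        nea = sp.nea_spectrum(
            sp.transitions_from_ensemble(m, [np.zeros(1)]), b,
            prefactor=1.0,
        )
        assert np.all(tmap.signal >= 0)
        for row in tmap.signal:
            assert np.allclose(row, nea.sigma, atol=1e-12)

    def test_absorption_only_nonnegative(self):
        # start on the upper state: the only band is SE, masked out
        m = fx.make_displaced_two_state(gap=0.1, kappa_excited=0.0)
        trajs = [sh.run_trajectory(m, np.zeros(1), np.zeros(1), 1,
                                   1.0 * units.FS_TO_AUT, 20)
                 for _ in range(2)]
        grid = np.linspace(1.5, 4.0, 200)
        b = sp.BroadeningSpec(fwhm_ev=0.1, grid_ev=grid)
        full = sp.transient_spectrum(trajs, m, 1, b, signs="full")
        absorption = sp.transient_spectrum(trajs, m, 1, b,
                                           signs="absorption")
        assert full.signal.min() < 0
        assert np.all(absorption.signal >= 0)

    def test_se_band_decay_refits_rate(self):
        """Synthetic ensemble decaying at k recovers k from the SE band."""
        m = fx.make_displaced_two_state(gap=0.1, kappa_excited=0.0)
        k_true = 0.01  # fs^-1
        n_traj, n_steps = 400, 60
        dt = 5.0 * units.FS_TO_AUT
        rng = np.random.default_rng(17)
        template = sh.run_trajectory(m, np.zeros(1), np.zeros(1), 1,
                                     dt, n_steps)
        trajs = []
        for _ in range(n_traj):
            tau_fs = rng.exponential(1.0 / k_true)
            traj = sh.run_trajectory(m, np.zeros(1), np.zeros(1), 1,
                                     dt, n_steps)
            for s in traj.states:
                if s.time / units.FS_TO_AUT >= tau_fs:
                    s.active = 0
            trajs.append(traj)
        grid = np.linspace(1.5, 4.0, 200)
        tmap = sp.transient_spectrum(trajs, m, 1,
                                     sp.BroadeningSpec(fwhm_ev=0.1,
                                                       grid_ev=grid))
        k_fit, se = sp.decay_rate_from_map(
            tmap, energy_ev=0.1 / units.EV_TO_HARTREE,
            window_fs=(0.0, 300.0))
        assert abs(k_fit - k_true) < 2 * max(se, k_true / np.sqrt(n_traj))
        _ = template

    def test_bad_stride_rejected(self):
        m = fx.make_displaced_two_state()
        trajs = self._frozen_trajectories(m, n=1, steps=5)
        with pytest.raises(SpectrumError):
            sp.transient_spectrum(trajs, m, 100, sp.BroadeningSpec())


class TestPhotolysis:
    def test_constant_integrand(self):
        lam = np.linspace(300.0, 400.0, 11)
        inputs = sp.PhotolysisInputs(
            phi_lambda=lam, phi=np.ones(11),
            flux_lambda=lam, flux=np.full(11, 1e14),
            window=(300.0, 400.0),
        )
        j = sp.photolysis_rate((lam, np.full(11, 1e-18)), inputs)
        assert j == pytest.approx(1e-2, rel=1e-12)

    def test_zero_quantum_yield(self):
        lam = np.linspace(300.0, 400.0, 11)
        inputs = sp.PhotolysisInputs(
            phi_lambda=lam, phi=np.zeros(11),
            flux_lambda=lam, flux=np.full(11, 1e14),
            window=(300.0, 400.0),
        )
        assert sp.photolysis_rate((lam, np.full(11, 1e-18)), inputs) == 0.0

    def test_gaussian_cross_section_closed_form(self):
        lam = np.linspace(200.0, 500.0, 6001)
        center, width, peak = 350.0, 10.0, 1e-18
        sigma = peak * np.exp(-0.5 * ((lam - center) / width) ** 2)
        inputs = sp.PhotolysisInputs(
            phi_lambda=lam, phi=np.ones(lam.size),
            flux_lambda=lam, flux=np.full(lam.size, 1e14),
            window=(200.0, 500.0),
        )
        j = sp.photolysis_rate((lam, sigma), inputs)
        expected = peak * 1e14 * width * math.sqrt(2 * math.pi)
        assert j == pytest.approx(expected, rel=1e-6)

    def test_window_outside_support_rejected(self):
        lam = np.linspace(300.0, 400.0, 11)
        with pytest.raises(SpectrumError):
            sp.PhotolysisInputs(
                phi_lambda=lam, phi=np.ones(11),
                flux_lambda=lam, flux=np.ones(11),
                window=(250.0, 400.0),
            )

    def test_invalid_quantum_yield_rejected(self):
        lam = np.linspace(300.0, 400.0, 3)
        with pytest.raises(SpectrumError):
            sp.PhotolysisInputs(
                phi_lambda=lam, phi=np.array([0.5, 1.5, 0.5]),
                flux_lambda=lam, flux=np.ones(3), window=(300.0, 400.0),
            )


class TestKinetics:
    def _two_state(self, k=0.01):
        kmat = np.array([[-k, 0.0], [k, 0.0]])
        return sp.KineticsModel(K=kmat, p0=np.array([1.0, 0.0]))

    def test_exponential_decay(self):
        pops = sp.kinetics_propagate(self._two_state(0.01),
                                     np.array([0.0, 100.0]))
        assert pops[1, 0] == pytest.approx(math.exp(-1.0), abs=1e-12)

    def test_zero_rates_constant(self):
        km = sp.KineticsModel(K=np.zeros((2, 2)), p0=np.array([0.3, 0.7]))
        pops = sp.kinetics_propagate(km, np.linspace(0, 50, 6))
        assert np.allclose(pops, [0.3, 0.7])

    def test_three_state_chain_vs_series_oracle(self):
        k1, k2 = 0.02, 0.005
        kmat = np.array([
            [-k1, 0.0, 0.0],
            [k1, -k2, 0.0],
            [0.0, k2, 0.0],
        ])
        km = sp.KineticsModel(K=kmat, p0=np.array([1.0, 0.0, 0.0]))
        t = 37.0
        pops = sp.kinetics_propagate(km, np.array([t]))[0]
        # dense Taylor-series summation oracle
        term = np.eye(3)
        total = np.eye(3)
        for n in range(1, 60):
            term = term @ (kmat * t) / n
            total += term
        assert np.abs(pops - total @ km.p0).max() < 1e-10

    def test_population_conserved(self):
        pops = sp.kinetics_propagate(self._two_state(0.03),
                                     np.linspace(0, 200, 21))
        assert np.abs(pops.sum(axis=1) - 1.0).max() < 1e-12

    def test_negative_off_diagonal_rejected(self):
        with pytest.raises(KineticsError):
            sp.KineticsModel(K=np.array([[0.0, -0.1], [0.0, 0.1]]),
                             p0=np.array([1.0, 0.0]))
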