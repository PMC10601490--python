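"""Nuclear-ensemble spectra, transient maps, photolysis rates, kinetics.

The nuclear ensemble approach (NEA) reconstructs an electronic spectrum
from vertical transitions computed over a geometry ensemble: each
transition (Delta E, f) is broadened with a unit-area Gaussian or
Lorentzian of empirical full width at half maximum delta, weighted by its
oscillator strength, and the ensemble average is scaled to an absolute
cross section by

    sigma(E) = C * (1/N) sum_geom sum_states f * g_delta(E - Delta E)

where ``C = pi e^2 hbar / (2 m_e c eps_0)`` is the standard
oscillator-strength-to-integrated-cross-section constant, here expressed
in cm^2 eV (approximately 1.0975e-16).  The same broadening machinery
produces transient absorption maps from trajectory snapshots (excited-
state absorption positive, stimulated emission negative), and the
absolute cross section feeds the photolysis-rate integral

    J = integral phi(lambda, T) sigma_abs(lambda) F(lambda) dlambda

with phi the quantum yield and F the actinic flux in
quanta s^-1 cm^-2 nm^-1.  A first-order rate-equation propagator covers
phenomenological population kinetics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.constants import c as _c
from scipy.constants import e as _e
from scipy.constants import electron_volt as _ev_J
from scipy.constants import epsilon_0 as _eps0
from scipy.constants import hbar as _hbar
from scipy.constants import m_e as _m_e
from scipy.linalg import expm

from . import units
from .errors import DimensionMismatchError, KineticsError, SpectrumError
from .lvc_model import LVCModel, evaluate_adiabatic
from .surface_hopping import Trajectory, fit_decay

#: pi e^2 hbar / (2 m_e c eps_0) in cm^2 eV — the area under the
#: cross-section curve of a transition of unit oscillator strength.
CROSS_SECTION_PREFACTOR_CM2_EV = (
    math.pi * _e**2 * _hbar
    / (2.0 * _m_e * _c * _eps0)
) / _ev_J * 1e4

#: lambda(nm) * E(eV) for a photon.
NM_EV = units.NM_EV


@dataclass
class TransitionSet:
    """Vertical transitions over an ensemble of geometries.

    ``delta_e`` and ``f`` have shape ``(n_geometries, n_transitions)``;
    energies are stored in E_h with an eV view.  Negative ``delta_e`` is
    allowed (emission bookkeeping); oscillator strengths must be
    non-negative.
    """

    delta_e: np.ndarray
    f: np.ndarray
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.delta_e = np.atleast_2d(np.asarray(self.delta_e, dtype=float))
        self.f = np.atleast_2d(np.asarray(self.f, dtype=float))
        if self.delta_e.shape != self.f.shape:
            raise DimensionMismatchError("delta_e/f shape mismatch")
        if not np.all(np.isfinite(self.delta_e)):
            raise SpectrumError("non-finite transition energy")
        if np.any(self.f < 0):
            raise SpectrumError("negative oscillator strength")

    @property
    def n_geometries(self) -> int:
        return self.delta_e.shape[0]

    @property
    def delta_e_ev(self) -> np.ndarray:
        return self.delta_e / units.EV_TO_HARTREE


@dataclass
class BroadeningSpec:
    """Lineshape: kind ('gaussian' | 'lorentzian'), FWHM delta in eV, grid.

    If ``grid`` is None a default grid spanning the transitions plus
    3 delta on each side (1000 points) is built at spectrum time.
    """

    kind: str = "gaussian"
    fwhm_ev: float = 0.1
    grid_ev: np.ndarray | None = None
    n_grid: int = 1000

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "lorentzian"):
            raise SpectrumError(f"unknown lineshape {self.kind!r}")
        if self.fwhm_ev <= 0:
            raise SpectrumError("broadening width must be positive")

    def lineshape(self, x: np.ndarray) -> np.ndarray:
        """Unit-area lineshape evaluated at x (eV from line center)."""
        d = self.fwhm_ev
        if self.kind == "gaussian":
            sigma = d / (2.0 * math.sqrt(2.0 * math.log(2.0)))
            return np.exp(-0.5 * (x / sigma) ** 2) \
                / (sigma * math.sqrt(2.0 * math.pi))
        return (d / (2.0 * math.pi)) / (x**2 + (d / 2.0) ** 2)

    def make_grid(self, centers_ev: np.ndarray) -> np.ndarray:
        if self.grid_ev is not None:
            return np.asarray(self.grid_ev, dtype=float)
        lo = centers_ev.min() - 3.0 * self.fwhm_ev
        hi = centers_ev.max() + 3.0 * self.fwhm_ev
        return np.linspace(lo, hi, self.n_grid)


@dataclass
class EnsembleSpectrum:
    """Absolute cross-section spectrum on an energy grid.

    ``sigma`` is the total in cm^2; ``per_transition`` decomposes it by
    transition column and sums to the total.
    """

    grid_ev: np.ndarray
    sigma: np.ndarray
    per_transition: np.ndarray       # (n_transitions, n_grid)
    n_samples: int
    prefactor: float = CROSS_SECTION_PREFACTOR_CM2_EV

    def as_wavelength(self) -> tuple[np.ndarray, np.ndarray]:
        """Pointwise cross section vs wavelength in nm (ascending).

        A cross section is a pointwise quantity, so the wavelength view is
        ``sigma(lambda) = sigma(E(lambda))`` with ``E = 1239.84.../lambda``;
        no Jacobian applies to sigma itself (only to per-eV vs per-nm
        spectral densities).
        """
        mask = self.grid_ev > 0
        lam = NM_EV / self.grid_ev[mask]
        order = np.argsort(lam)
        return lam[order], self.sigma[mask][order]


@dataclass
class TransientMap:
    """Time- and energy-resolved differential signal (arbitrary units)."""

    times: np.ndarray
    grid_ev: np.ndarray
    signal: np.ndarray               # (n_times, n_grid); SE negative
    esa: np.ndarray
    se: np.ndarray


@dataclass
class PhotolysisInputs:
    """Quantum-yield and actinic-flux curves on wavelength grids (nm).

    ``phi`` must lie in [0, 1]; ``flux`` (quanta s^-1 cm^-2 nm^-1) must be
    non-negative; the integration window must be inside the support of
    both curves (and of the cross-section spectrum).
    """

    phi_lambda: np.ndarray
    phi: np.ndarray
    flux_lambda: np.ndarray
    flux: np.ndarray
    window: tuple[float, float]

    def __post_init__(self) -> None:
        self.phi_lambda = np.asarray(self.phi_lambda, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        self.flux_lambda = np.asarray(self.flux_lambda, dtype=float)
        self.flux = np.asarray(self.flux, dtype=float)
        if np.any(self.phi < 0) or np.any(self.phi > 1):
            raise SpectrumError("quantum yield must lie in [0, 1]")
        if np.any(self.flux < 0):
            raise SpectrumError("actinic flux must be non-negative")
        lo, hi = self.window
        if lo >= hi:
            raise SpectrumError("empty wavelength window")
        for name, grid in (("quantum yield", self.phi_lambda),
                           ("flux", self.flux_lambda)):
            if lo < grid.min() - 1e-9 or hi > grid.max() + 1e-9:
                raise SpectrumError(
                    f"window [{lo}, {hi}] nm outside the {name} curve support"
                )


@dataclass
class KineticsModel:
    """First-order rate matrix K (fs^-1) and initial populations.

    ``dp/dt = K p``; off-diagonal entries (rates into a state) must be
    non-negative.  K is probability-conserving when each column sums to
    zero; declared sink states may make column sums negative.
    """

    K: np.ndarray
    p0: np.ndarray

    def __post_init__(self) -> None:
        self.K = np.atleast_2d(np.asarray(self.K, dtype=float))
        self.p0 = np.atleast_1d(np.asarray(self.p0, dtype=float))
        n = self.p0.size
        if self.K.shape != (n, n):
            raise DimensionMismatchError("rate matrix / population mismatch")
        off = self.K - np.diag(np.diag(self.K))
        if np.any(off < 0):
            raise KineticsError("off-diagonal rates must be non-negative")
        if np.any(np.sum(self.K, axis=0) > 1e-12):
            raise KineticsError("column sums must be <= 0 (no source terms)")


def transitions_from_ensemble(
    model: LVCModel,
    coordinates: list[np.ndarray] | np.ndarray,
    n_states: int | None = None,
) -> TransitionSet:
    """Vertical excitations from the ground state over an ensemble.

    ``coordinates`` are dimensionless model coordinates, one vector per
    geometry.  Returns gaps ``E_a - E_0`` (E_h) and oscillator strengths
    for the ``n_states - 1`` excited states of the model.
    """
    n_states = model.n_states if n_states is None else n_states
    if n_states > model.n_states:
        raise SpectrumError(
            f"requested {n_states} states but model has {model.n_states}"
        )
    if n_states < 2:
        raise SpectrumError("need at least one excited state")
    coords = list(coordinates)
    if not coords:
        raise SpectrumError("empty ensemble")
    de = np.empty((len(coords), n_states - 1))
    f = np.empty_like(de)
    for g, q in enumerate(coords):
        point = evaluate_adiabatic(model, np.asarray(q, dtype=float))
        de[g] = point.gaps_from_ground[1:n_states]
        f[g] = point.oscillator_strengths[1:n_states]
    return TransitionSet(delta_e=de, f=f)


def nea_spectrum(
    transitions: TransitionSet,
    broadening: BroadeningSpec,
    prefactor: float = CROSS_SECTION_PREFACTOR_CM2_EV,
) -> EnsembleSpectrum:
    """Broadened ensemble-average cross section.

    Each transition contributes a unit-area lineshape centered at its
    Delta E with area ``prefactor * f``; the spectrum is the mean over
    geometries, so duplicating the ensemble leaves it unchanged and the
    total area obeys the sum rule ``area = prefactor * mean total f``
    independent of the width delta.
    """
    centers = transitions.delta_e_ev
    grid = broadening.make_grid(centers)
    n_geom, n_tr = centers.shape
    per = np.zeros((n_tr, grid.size))
    for j in range(n_tr):
        diff = grid[None, :] - centers[:, [j]]
        per[j] = (transitions.f[:, [j]] * broadening.lineshape(diff)).sum(0)
    per *= prefactor / n_geom
    return EnsembleSpectrum(grid_ev=grid, sigma=per.sum(0),
                            per_transition=per, n_samples=n_geom,
                            prefactor=prefactor)


def transient_spectrum(
    trajectories: list[Trajectory],
    model: LVCModel,
    stride: int,
    broadening: BroadeningSpec,
    signs: str = "full",
    grid_ev: np.ndarray | None = None,
    irf_fwhm_fs: float | None = None,
) -> TransientMap:
    """Trajectory-resolved transient spectrum.

    Geometries are extracted every ``stride`` stored snapshots; at each
    one, excited-state absorption (ESA) runs from the active state to all
    higher states (positive sign) and stimulated emission (SE) to all
    lower states (negative sign, with the emission gap and oscillator
    strength).  Slices are averaged over trajectories, broadened in
    energy, and optionally convolved in time with a Gaussian instrument
    response of the stated FWHM.  ``signs="absorption"`` keeps only the
    ESA part.
    """
    if signs not in ("full", "absorption"):
        raise SpectrumError(f"unknown signs mode {signs!r}")
    if not trajectories:
        raise SpectrumError("empty trajectory ensemble")
    n_snap = min(len(t.states) for t in trajectories)
    if stride < 1 or stride > n_snap:
        raise SpectrumError(
            f"stride {stride} not commensurate with {n_snap} stored snapshots"
        )
    slice_idx = range(0, n_snap, stride)
    times = np.array([trajectories[0].states[i].time for i in slice_idx])

    esa_tr: list[tuple[list[float], list[float]]] = []
    se_tr: list[tuple[list[float], list[float]]] = []
    for i in slice_idx:
        e_de: list[float] = []
        e_f: list[float] = []
        s_de: list[float] = []
        s_f: list[float] = []
        for traj in trajectories:
            snap = traj.states[i]
            point = evaluate_adiabatic(model, snap.Q)
            a = snap.active
            mu = point.dipoles
            for b in range(model.n_states):
                if b == a:
                    continue
                gap = point.energies[b] - point.energies[a]
                f_ab = (2.0 / 3.0) * abs(gap) * float(mu[a, b] @ mu[a, b])
                if gap > 0:
                    e_de.append(gap)
                    e_f.append(f_ab)
                else:
                    s_de.append(-gap)
                    s_f.append(f_ab)
        esa_tr.append((e_de, e_f))
        se_tr.append((s_de, s_f))

    if grid_ev is None and broadening.grid_ev is None:
        all_de = np.array(
            [de for sl in (esa_tr, se_tr) for pair in sl for de in pair[0]]
        )
        if all_de.size == 0:
            raise SpectrumError("no transitions found in the trajectories")
        grid_ev = broadening.make_grid(all_de / units.EV_TO_HARTREE)
    elif grid_ev is None:
        grid_ev = broadening.grid_ev
    grid_ev = np.asarray(grid_ev, dtype=float)

    n_traj = len(trajectories)
    esa = np.zeros((times.size, grid_ev.size))
    se = np.zeros_like(esa)
    for k, ((e_de, e_f), (s_de, s_f)) in enumerate(zip(esa_tr, se_tr)):
        esa[k] = _broadened_sum(e_de, e_f, grid_ev, broadening) / n_traj
        se[k] = _broadened_sum(s_de, s_f, grid_ev, broadening) / n_traj
    signal = esa.copy() if signs == "absorption" else esa - se
    if irf_fwhm_fs is not None:
        signal = _time_convolve(signal, times, irf_fwhm_fs)
    return TransientMap(times=times, grid_ev=grid_ev, signal=signal,
                        esa=esa, se=se)


def _broadened_sum(de_list, f_list, grid_ev, broadening):
    out = np.zeros(grid_ev.size)
    if not de_list:
        return out
    centers = np.asarray(de_list) / units.EV_TO_HARTREE
    weights = np.asarray(f_list)
    diff = grid_ev[None, :] - centers[:, None]
    return (weights[:, None] * broadening.lineshape(diff)).sum(0)


def _time_convolve(signal, times_au, irf_fwhm_fs):
    times_fs = times_au / units.FS_TO_AUT
    sigma = irf_fwhm_fs / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    diff = times_fs[:, None] - times_fs[None, :]
    kernel = np.exp(-0.5 * (diff / sigma) ** 2)
    kernel /= kernel.sum(axis=1, keepdims=True)
    return kernel @ signal


def photolysis_rate(
    sigma_lambda: tuple[np.ndarray, np.ndarray] | EnsembleSpectrum,
    inputs: PhotolysisInputs,
) -> float:
    """Photolysis rate J (s^-1) by composite trapezoid.

    ``J = integral phi(lambda) sigma(lambda) F(lambda) dlambda`` over the
    window, on the merged grid of all input curves (every breakpoint of
    every curve is a quadrature node, so piecewise-linear inputs are
    integrated exactly).
    """
    if isinstance(sigma_lambda, EnsembleSpectrum):
        lam_s, sig = sigma_lambda.as_wavelength()
    else:
        lam_s, sig = (np.asarray(a, dtype=float) for a in sigma_lambda)
    lo, hi = inputs.window
    if lo < lam_s.min() - 1e-9 or hi > lam_s.max() + 1e-9:
        raise SpectrumError(
            "integration window outside the cross-section support"
        )
    grid = np.unique(np.concatenate([
        np.asarray([lo, hi]),
        lam_s[(lam_s >= lo) & (lam_s <= hi)],
        inputs.phi_lambda[(inputs.phi_lambda >= lo)
                          & (inputs.phi_lambda <= hi)],
        inputs.flux_lambda[(inputs.flux_lambda >= lo)
                           & (inputs.flux_lambda <= hi)],
    ]))
    phi = np.interp(grid, inputs.phi_lambda, inputs.phi)
    flux = np.interp(grid, inputs.flux_lambda, inputs.flux)
    sigma = np.interp(grid, lam_s, sig)
    return float(np.trapezoid(phi * sigma * flux, grid))


def kinetics_propagate(
    kmodel: KineticsModel, t_grid: np.ndarray,
) -> np.ndarray:
    """Populations ``p(t) = exp(K t) p(0)`` on a time grid (fs).

    Uses the matrix exponential (scaling-and-squaring); for a
    probability-conserving K the total population stays 1 to round-off.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0 or np.any(np.diff(t_grid) < 0) or t_grid[0] < 0:
        raise KineticsError("t_grid must ascend from a non-negative time")
    out = np.empty((t_grid.size, kmodel.p0.size))
    for i, t in enumerate(t_grid):
        out[i] = expm(kmodel.K * t) @ kmodel.p0
    return out


def decay_rate_from_map(
    tmap: TransientMap, energy_ev: float, window_fs: tuple[float, float],
) -> tuple[float, float]:
    """Fit the SE-band amplitude decay at one probe energy.

    Returns ``(k, SE_k)`` in fs^-1 from a single-exponential fit of the
    |SE| amplitude at the grid point nearest ``energy_ev``.
    """
    j = int(np.argmin(np.abs(tmap.grid_ev - energy_ev)))
    amp = tmap.se[:, j]
    t_fs = tmap.times / units.FS_TO_AUT
    return fit_decay(amp, t_fs, window=window_fs)
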