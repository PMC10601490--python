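"""Synthetic model systems for exercising the full pipeline.

Every generator is deterministic given its parameters (and seed), builds
objects that serialize through :mod:`vibronica.chemio`, and has simple
closed-form properties: the diatomic has the textbook stretching
frequency ``sqrt(k/mu)``, the bent triatomic is reverse-engineered from
chosen frequencies and eigenvectors so normal-mode analysis must recover
them exactly, and the two-state crossing model realizes the
Landau--Zener geometry (linear diabats of opposite slope with a constant
coupling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import units
from .chemio import Molecule
from .errors import SamplingError
from .lvc_model import LVCModel
from .normal_modes import NormalModeSet, external_generators


@dataclass
class FixtureSpec:
    """Recorded recipe of a generated fixture (family, parameters, seed)."""

    family: str
    params: dict = field(default_factory=dict)
    seed: int = 0


def make_diatomic(
    masses_amu: tuple[float, float] = (1.0, 1.0),
    k: float = 0.1,
    separation: float = 1.4,
) -> tuple[Molecule, np.ndarray]:
    """Homonuclear-style diatomic on the x axis with one stretching block.

    ``k`` is the bond force constant in E_h/bohr^2; the Hessian couples
    only the two x components, so the single vibration is the stretch
    with ``omega = sqrt(k/mu)``.
    """
    if k <= 0:
        raise SamplingError("force constant must be positive")
    mol = Molecule(
        ["H", "H"],
        np.array([[0.0, 0.0, 0.0], [separation, 0.0, 0.0]]),
        masses=np.array(masses_amu) * units.AMU_TO_ME,
    )
    h = np.zeros((6, 6))
    h[0, 0] = h[3, 3] = k
    h[0, 3] = h[3, 0] = -k
    return mol, h


def make_bent_triatomic(
    seed: int = 0,
    freqs_cm1: tuple[float, float, float] = (1200.0, 1800.0, 3100.0),
) -> tuple[Molecule, np.ndarray, np.ndarray]:
    """Bent three-atom molecule with three prescribed vibrations.

    A water-like geometry is paired with a Hessian constructed as
    ``H = M^(1/2) L omega^2 L^T M^(1/2)`` from orthonormal mass-weighted
    eigenvectors L chosen (via a seeded rotation) in the orthogonal
    complement of the translation/rotation subspace, so
    :func:`vibronica.normal_modes.compute_modes` must return exactly
    ``freqs_cm1``.  Returns ``(molecule, hessian, omega_au)``.
    """
    mol = Molecule(
        ["O", "H", "H"],
        np.array([
            [0.0, 0.0, 0.222],
            [0.0, 1.434, -0.886],
            [0.0, -1.434, -0.886],
        ]),
    )
    ext = external_generators(mol)
    # orthonormal basis of the internal (vibrational) subspace
    proj = np.eye(9) - ext @ ext.T
    evals, evecs = np.linalg.eigh(proj)
    internal = evecs[:, evals > 0.5]
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    l_mat = internal @ q
    omega = np.asarray(freqs_cm1) * units.CM1_TO_HARTREE
    sqrt_m = np.sqrt(mol.mass_vector)
    mw_h = l_mat @ np.diag(omega**2) @ l_mat.T
    hessian = mw_h * np.outer(sqrt_m, sqrt_m)
    return mol, 0.5 * (hessian + hessian.T), omega


def make_two_state_crossing(
    gap: float = 0.0,
    slope: float = 0.01,
    coupling_const: float = 0.005,
    coupling_linear: float = 0.0,
    omega: float = 0.005,
    dipole: float = 1.0,
) -> LVCModel:
    """One-mode two-state crossing model.

    Diabats ``eps = (0, gap)`` with intrastate gradients ``(+slope,
    -slope)`` on the shared harmonic baseline, coupled by a constant
    ``eta`` and/or linear ``lambda``.  With ``gap = 0`` the diabats cross
    at Q = 0 and a trajectory shot through the crossing realizes the
    Landau--Zener problem; the adiabatic gap at the crossing is
    ``2 eta``.
    """
    lam = np.zeros((2, 2, 1))
    lam[0, 1, 0] = lam[1, 0, 0] = coupling_linear
    eta = np.array([[0.0, coupling_const], [coupling_const, 0.0]])
    dip = np.zeros((2, 2, 3))
    dip[0, 1, 0] = dip[1, 0, 0] = dipole
    return LVCModel(
        omega=np.array([omega]),
        epsilon=np.array([0.0, gap]),
        kappa=np.array([[slope], [-slope]]),
        lam=lam, eta=eta, dipoles=dip,
    )


def make_displaced_two_state(
    gap: float = 0.1,
    kappa_excited: float = -0.02,
    coupling_linear: float = 0.0,
    omega: float = 0.01,
    dipole: float = 1.0,
) -> LVCModel:
    """Two states with a displaced excited surface (spectroscopy test bed).

    The ground state is the bare harmonic oscillator; the excited state
    is shifted up by ``gap`` and displaced via ``kappa_excited``, which
    makes the vertical gap vary linearly with Q when ``lambda = 0``.
    """
    lam = np.zeros((2, 2, 1))
    lam[0, 1, 0] = lam[1, 0, 0] = coupling_linear
    dip = np.zeros((2, 2, 3))
    dip[0, 1, 2] = dip[1, 0, 2] = dipole
    return LVCModel(
        omega=np.array([omega]),
        epsilon=np.array([0.0, gap]),
        kappa=np.array([[0.0], [kappa_excited]]),
        lam=lam, dipoles=dip,
    )


def make_multimode_lvc(
    n_modes: int = 3,
    n_states: int = 3,
    kappa_scale: float = 0.01,
    lambda_scale: float = 0.005,
    omega_band: tuple[float, float] = (500.0, 2000.0),
    gap_scale: float = 0.1,
    seed: int = 0,
) -> LVCModel:
    """Random multimode vibronic model (pyrazine-like test bed).

    Frequencies are log-uniform in ``omega_band`` (cm^-1); kappa and
    lambda entries are normal with the given scales; vertical gaps are
    ``gap_scale * (0, 1, 2, ...)``.  Zero scales give an uncoupled
    harmonic model.  Fully reproducible from the seed.
    """
    rng = np.random.default_rng(seed)
    omega = np.exp(rng.uniform(np.log(omega_band[0]), np.log(omega_band[1]),
                               n_modes)) * units.CM1_TO_HARTREE
    eps = gap_scale * np.arange(n_states, dtype=float)
    kappa = kappa_scale * rng.standard_normal((n_states, n_modes))
    lam = np.zeros((n_states, n_states, n_modes))
    for i in range(n_states):
        for j in range(i + 1, n_states):
            v = lambda_scale * rng.standard_normal(n_modes)
            lam[i, j] = lam[j, i] = v
    dip = np.zeros((n_states, n_states, 3))
    for j in range(1, n_states):
        dip[0, j] = dip[j, 0] = rng.standard_normal(3)
    return LVCModel(omega=omega, epsilon=eps, kappa=kappa, lam=lam,
                    dipoles=dip)


def make_flux_table(
    kind: str = "constant",
    window: tuple[float, float] = (300.0, 400.0),
    level: float = 1e14,
    center: float | None = None,
    width: float = 20.0,
    n_points: int = 201,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-column actinic-flux (or cross-section) curve on a nm grid.

    ``kind="constant"`` is flat at ``level``; ``kind="gaussian"`` is a
    Gaussian of standard deviation ``width`` centered in the window (its
    quadrature area approaches ``level * width * sqrt(2 pi)`` as the
    window widens).
    """
    lo, hi = window
    if lo >= hi:
        raise SamplingError("empty wavelength window")
    lam = np.linspace(lo, hi, n_points)
    if kind == "constant":
        return lam, np.full(n_points, level)
    if kind == "gaussian":
        c = 0.5 * (lo + hi) if center is None else center
        return lam, level * np.exp(-0.5 * ((lam - c) / width) ** 2)
    raise SamplingError(f"unknown flux-table kind {kind!r}")


def single_mode_set(omega_au: float = 0.01,
                    mass_amu: float = 1.0) -> NormalModeSet:
    """Minimal one-mode NormalModeSet built on the diatomic stretch.

    Useful for sampling tests where closed-form moments are wanted for a
    single frequency; the mode is the antisymmetric x stretch of two
    equal masses.
    """
    mol = Molecule(
        ["H", "H"], np.array([[0.0, 0.0, 0.0], [1.4, 0.0, 0.0]]),
        masses=np.array([mass_amu, mass_amu]) * units.AMU_TO_ME,
    )
    l_col = np.zeros((6, 1))
    l_col[0, 0] = 1.0 / np.sqrt(2.0)
    l_col[3, 0] = -1.0 / np.sqrt(2.0)
    return NormalModeSet(mol, np.array([omega_au]), l_col)
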