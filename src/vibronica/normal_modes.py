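"""Harmonic normal-mode analysis of Cartesian Hessians.

The pipeline is the standard one: mass-weight the Hessian with
``M^(-1/2) H M^(-1/2)``, project out rigid translations and rotations by
explicit construction of the external-mode generators (Eckart-style), and
diagonalize the projected matrix.  Frequencies are ``sqrt(eigenvalue)`` in
atomic units; negative eigenvalues are flagged as imaginary modes with
``|omega|`` stored.  Eigenvector columns are orthonormal in the
mass-weighted metric and carry a deterministic sign convention (largest-
magnitude component positive, first index on ties).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import units
from .chemio import Molecule
from .errors import DimensionMismatchError, HessianFormatError

#: Modes with |omega| below this (cm^-1) after projection are treated as
#: numerical zeros left over from the external-mode projection.
EXTERNAL_MODE_THRESHOLD_CM1 = 10.0


@dataclass
class NormalModeSet:
    """Vibrational frequencies and mass-weighted eigenvectors.

    Attributes
    ----------
    molecule
        Reference (equilibrium) geometry.
    omega
        Vibrational angular frequencies in atomic units (``|omega|`` for
        imaginary modes), sorted ascending.
    modes
        Mass-weighted eigenvector columns, shape ``(3N, n_vib)``,
        orthonormal.
    imaginary
        Boolean flag per mode.
    n_external
        Number of translational/rotational modes projected out.
    """

    molecule: Molecule
    omega: np.ndarray
    modes: np.ndarray
    imaginary: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_external: int = 0

    def __post_init__(self) -> None:
        self.omega = np.atleast_1d(np.asarray(self.omega, dtype=float))
        self.modes = np.asarray(self.modes, dtype=float)
        if self.modes.ndim != 2 or self.modes.shape[1] != self.omega.size:
            raise DimensionMismatchError("modes/omega shape mismatch")
        if self.imaginary is None:
            self.imaginary = np.zeros(self.omega.size, dtype=bool)

    @property
    def n_modes(self) -> int:
        return self.omega.size

    @property
    def frequencies_cm1(self) -> np.ndarray:
        """Signed frequencies in cm^-1 (negative for imaginary modes)."""
        sign = np.where(self.imaginary, -1.0, 1.0)
        return sign * self.omega / units.CM1_TO_HARTREE

    def vibrational(self) -> "NormalModeSet":
        """Subset with imaginary modes removed (the sampleable modes)."""
        keep = ~self.imaginary
        return NormalModeSet(
            self.molecule, self.omega[keep], self.modes[:, keep],
            self.imaginary[keep], self.n_external,
        )


def mass_weight(hessian: np.ndarray, masses: np.ndarray,
                symmetry_tol: float = 1e-8) -> np.ndarray:
    """Mass-weight a Cartesian Hessian: ``M^(-1/2) H M^(-1/2)``.

    ``masses`` is per-atom (electron masses); the result is symmetric and
    shares the eigenvalue problem of the vibrational secular equation.
    """
    h = np.asarray(hessian, dtype=float)
    n3 = h.shape[0]
    if h.shape != (n3, n3):
        raise DimensionMismatchError("Hessian must be square")
    masses = np.asarray(masses, dtype=float)
    if masses.size * 3 != n3:
        raise DimensionMismatchError("3 * n_atoms != Hessian dimension")
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    scale = max(np.abs(h).max(), 1.0)
    if np.abs(h - h.T).max() > symmetry_tol * scale:
        raise HessianFormatError("Hessian asymmetric beyond tolerance")
    inv_sqrt_m = 1.0 / np.sqrt(np.repeat(masses, 3))
    mw = h * np.outer(inv_sqrt_m, inv_sqrt_m)
    return 0.5 * (mw + mw.T)


def external_generators(molecule: Molecule) -> np.ndarray:
    """Orthonormal mass-weighted generators of rigid translation/rotation.

    Returns columns spanning the external subspace: 3 translations plus 3
    rotations (2 for linear molecules, 0 for a single atom).  Linearity is
    detected from the rank of the inertia tensor.
    """
    n = molecule.n_atoms
    sqrt_m = np.sqrt(molecule.masses)
    vecs = []
    for k in range(3):
        t = np.zeros((n, 3))
        t[:, k] = sqrt_m
        vecs.append(t.ravel())
    com = molecule.center_of_mass()
    rel = molecule.coords - com
    inertia = np.einsum("i,ij,ik->jk", molecule.masses, rel, rel)
    inertia = np.trace(inertia) * np.eye(3) - inertia
    evals, evecs = np.linalg.eigh(inertia)
    tol = max(evals.max(), 1.0) * 1e-10
    for axis, ev in zip(evecs.T, evals):
        if ev < tol:  # rotation about a zero-inertia axis is no motion
            continue
        r = np.cross(np.broadcast_to(axis, rel.shape), rel)
        vecs.append((sqrt_m[:, None] * r).ravel())
    basis = np.column_stack(vecs)
    # orthonormalize; drop numerically dependent columns (e.g. single atom)
    q, r = np.linalg.qr(basis)
    keep = np.abs(np.diag(r)) > 1e-10
    return q[:, keep]


def project_external(mw_hessian: np.ndarray,
                     molecule: Molecule) -> tuple[np.ndarray, int]:
    """Project translations/rotations out of a mass-weighted Hessian.

    Returns the projected matrix and the external-subspace dimension.  The
    projected matrix annihilates rigid translation vectors exactly (up to
    round-off), so spurious center-of-mass forces cannot leak into
    sampling.
    """
    d = external_generators(molecule)
    proj = np.eye(mw_hessian.shape[0]) - d @ d.T
    h = proj @ mw_hessian @ proj
    return 0.5 * (h + h.T), d.shape[1]


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|component| entry positive."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        idx = np.argmax(np.abs(col))  # first index wins ties
        if col[idx] < 0:
            out[:, j] = -col
    return out


def compute_modes(
    hessian: np.ndarray,
    molecule: Molecule,
    external_threshold_cm1: float = EXTERNAL_MODE_THRESHOLD_CM1,
) -> NormalModeSet:
    """Full normal-mode analysis of a Cartesian Hessian.

    Modes with ``|omega|`` under ``external_threshold_cm1`` after projection
    are discarded as numerical zeros.  Negative eigenvalues are flagged
    imaginary (with ``|omega|`` stored) and a warning names their count;
    they are excluded from sampling downstream.
    """
    mw = mass_weight(hessian, molecule.masses)
    projected, n_external = project_external(mw, molecule)
    evals, evecs = np.linalg.eigh(projected)
    omega = np.sqrt(np.abs(evals))
    imaginary = evals < 0
    threshold = external_threshold_cm1 * units.CM1_TO_HARTREE
    keep = omega >= threshold
    omega, evecs, imaginary = omega[keep], evecs[:, keep], imaginary[keep]
    order = np.argsort(omega)
    omega, evecs, imaginary = omega[order], evecs[:, order], imaginary[order]
    evecs = _fix_signs(evecs)
    if not omega.size:
        warnings.warn("Hessian yields no vibrational modes", stacklevel=2)
    if imaginary.any():
        warnings.warn(
            f"{int(imaginary.sum())} imaginary mode(s) present; they will "
            "not be sampled",
            stacklevel=2,
        )
    return NormalModeSet(molecule, omega, evecs, imaginary, n_external)


def modes_from_molden(molecule: Molecule, freqs_cm1: np.ndarray,
                      displacements: np.ndarray) -> NormalModeSet:
    """Build a NormalModeSet from Molden-style Cartesian displacements.

    Molden stores plain Cartesian displacement vectors; they are converted
    to the mass-weighted metric and re-orthonormalized (Gram-Schmidt via
    QR) before use.
    """
    sqrt_m = np.sqrt(molecule.mass_vector)
    mw = sqrt_m[:, None] * np.asarray(displacements, dtype=float)
    norms = np.linalg.norm(mw, axis=0)
    if np.any(norms == 0):
        raise DimensionMismatchError("zero displacement vector")
    q, _ = np.linalg.qr(mw / norms)
    freqs = np.atleast_1d(np.asarray(freqs_cm1, dtype=float))
    omega = np.abs(freqs) * units.CM1_TO_HARTREE
    imaginary = freqs < 0
    order = np.argsort(omega)
    return NormalModeSet(
        molecule, omega[order], _fix_signs(q[:, order]), imaginary[order],
        n_external=3 * molecule.n_atoms - freqs.size,
    )
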