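"""Initial-condition generation for excited-state dynamics.

Two families of phase-space sampling around a harmonic minimum:

* **Normal-mode sampling (NMS)** — each vibrational mode receives an energy
  drawn from the classical Boltzmann distribution, ``E_i = -k_B T ln(u)``,
  and a uniformly random vibrational phase.  The mode amplitude is
  ``A_i = sqrt(2 E_i)/omega_i`` so that ``Q_i = A_i cos(phi)`` and
  ``P_i = -A_i omega_i sin(phi)`` carry exactly ``E_i`` of harmonic energy.
  After transforming to Cartesian coordinates, center-of-mass motion is
  removed and positions and momenta are rescaled by one common factor so
  the total harmonic energy equals the sampled ``sum(E_i)``.

* **Wigner sampling** — quantum phase-space density of the harmonic
  oscillator.  Ground state: ``W ~ exp(-omega Q^2) exp(-P^2/omega)``
  (hbar = 1).  Thermal: the same Gaussians with exponents multiplied by
  ``alpha_i(T) = tanh(hbar omega_i / (2 k_B T))``, which reduces to the
  ground-state form as T -> 0.  Sampling is either by rejection on a
  +-5 sigma box ("reject") or by drawing directly from the equivalent
  Gaussians ("direct"); both target the same density.  No energy rescaling
  is applied — rescaling would destroy the quantum distribution (zero-point
  spread) that distinguishes Wigner from classical sampling.

All coordinates here are mass-weighted normal coordinates (a.u.); the
Cartesian views use ``x = x_eq + M^(-1/2) L Q`` and ``p = M^(1/2) L P``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import units
from .errors import DimensionMismatchError, SamplingError
from .normal_modes import NormalModeSet


@dataclass
class ModeSample:
    """Per-mode phase-space draw before the Cartesian transform."""

    Q: np.ndarray                  # mass-weighted normal coordinates (a.u.)
    P: np.ndarray                  # conjugate momenta
    energies: np.ndarray           # per-mode harmonic energy (E_h)
    amplitudes: np.ndarray | None = None   # NMS only
    phases: np.ndarray | None = None       # NMS only


@dataclass
class PhaseSpaceSample:
    """One initial condition: normal-mode and Cartesian views.

    ``method`` is one of ``nms``, ``wigner0``, ``wignerT``; ``seed`` and
    ``index`` record provenance so ensembles are reproducible draw by
    draw.
    """

    Q: np.ndarray
    P: np.ndarray
    x: np.ndarray                  # (n_atoms, 3) bohr
    p: np.ndarray                  # (n_atoms, 3) a.u.
    mode_energies: np.ndarray
    method: str
    temperature: float
    seed: int
    index: int
    #: the per-mode energies the draw targeted (the Boltzmann draw for
    #: NMS, the realized energies for Wigner)
    target_energies: np.ndarray | None = None

    @property
    def total_energy(self) -> float:
        return float(self.mode_energies.sum())


@dataclass
class ThermalWignerSpec:
    """Per-mode thermal sharpening factors alpha_i(T) = tanh(w_i/(2 kT))."""

    temperature: float
    alpha: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.alpha <= 0) or np.any(self.alpha > 1.0 + 1e-12):
            raise SamplingError("alpha factors must lie in (0, 1]")


def thermal_spec(mode_set: NormalModeSet, temperature: float) -> ThermalWignerSpec:
    """Build alpha_i(T); T = 0 (or tiny) gives alpha = 1 exactly."""
    if temperature < 0:
        raise SamplingError("temperature must be non-negative")
    omega = mode_set.omega
    if temperature == 0:
        alpha = np.ones_like(omega)
    else:
        kt = units.KB_HARTREE_PER_K * temperature
        alpha = np.tanh(omega / (2.0 * kt))
    return ThermalWignerSpec(temperature, alpha)


def sample_boltzmann_energies(
    mode_set: NormalModeSet, temperature: float, rng: np.random.Generator,
    n: int = 1,
) -> np.ndarray:
    """Draw per-mode classical Boltzmann energies, shape ``(n, n_modes)``.

    Each mode independently: ``E = -k_B T ln(u)`` with u uniform on (0, 1]
    (the exponential distribution with mean ``k_B T``).  T = 0 gives zeros.
    """
    if temperature < 0:
        raise SamplingError("temperature must be non-negative")
    shape = (n, mode_set.n_modes)
    if temperature == 0:
        return np.zeros(shape)
    u = 1.0 - rng.random(shape)  # uniform on (0, 1]
    return -units.KB_HARTREE_PER_K * temperature * np.log(u)


def to_cartesian(
    mode_set: NormalModeSet, Q: np.ndarray, P: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Mass-weighted normal coordinates -> Cartesian positions/momenta.

    ``x = x_eq + M^(-1/2) L Q`` and ``p = M^(1/2) L P``; the inverse
    transform :func:`from_cartesian` is exact because L is orthonormal.
    """
    Q = np.asarray(Q, dtype=float)
    P = np.asarray(P, dtype=float)
    if Q.shape != (mode_set.n_modes,) or P.shape != (mode_set.n_modes,):
        raise DimensionMismatchError("Q/P length must equal mode count")
    sqrt_m = np.sqrt(mode_set.molecule.mass_vector)
    dx = (mode_set.modes @ Q) / sqrt_m
    p = (mode_set.modes @ P) * sqrt_m
    x = mode_set.molecule.coords + dx.reshape(-1, 3)
    return x, p.reshape(-1, 3)


def from_cartesian(
    mode_set: NormalModeSet, x: np.ndarray, p: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`to_cartesian` (projection onto the mode basis)."""
    sqrt_m = np.sqrt(mode_set.molecule.mass_vector)
    dx = (np.asarray(x, dtype=float) - mode_set.molecule.coords).ravel()
    Q = mode_set.modes.T @ (sqrt_m * dx)
    P = mode_set.modes.T @ (np.asarray(p, dtype=float).ravel() / sqrt_m)
    return Q, P


def remove_com_motion(
    molecule, x: np.ndarray, p: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Remove center-of-mass displacement and total linear momentum."""
    masses = molecule.masses
    total_m = masses.sum()
    com_shift = masses @ (x - molecule.coords) / total_m
    x = x - com_shift
    v_com = p.sum(axis=0) / total_m
    p = p - masses[:, None] * v_com
    return x, p


def mode_energies(mode_set: NormalModeSet, Q: np.ndarray,
                  P: np.ndarray) -> np.ndarray:
    """Harmonic per-mode energies ``(P^2 + omega^2 Q^2)/2``."""
    return 0.5 * (P**2 + (mode_set.omega * Q) ** 2)


def finalize_sample(
    mode_set: NormalModeSet, Q: np.ndarray, P: np.ndarray,
    target_energy: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """COM cleanup plus common-factor energy rescaling.

    Transforms to Cartesian, removes center-of-mass displacement and
    momentum, projects back onto the modes, and scales both Q and P by the
    single factor ``s = sqrt(E_target/E_current)`` so the total harmonic
    energy matches ``target_energy`` while each mode keeps its
    kinetic/potential split.  Returns ``(Q, P, x, p)``.
    """
    x, p = to_cartesian(mode_set, Q, P)
    x, p = remove_com_motion(mode_set.molecule, x, p)
    Q, P = from_cartesian(mode_set, x, p)
    current = float(mode_energies(mode_set, Q, P).sum())
    if target_energy > 0 and current <= 0:
        raise SamplingError("cannot rescale a zero-energy sample")
    if current > 0:
        s = math.sqrt(target_energy / current)
        Q, P = s * Q, s * P
    x, p = to_cartesian(mode_set, Q, P)
    # scaling preserves the zero-COM property; re-clean for strictness
    x, p = remove_com_motion(mode_set.molecule, x, p)
    return Q, P, x, p


def _check_sampleable(mode_set: NormalModeSet) -> None:
    if mode_set.n_modes == 0:
        raise SamplingError("mode set has no vibrational modes")
    if mode_set.imaginary.any():
        raise SamplingError(
            "imaginary modes must be filtered out before sampling "
            "(use NormalModeSet.vibrational())"
        )
    if np.any(mode_set.omega <= 0):
        raise SamplingError("zero-frequency mode in the sampled set")


def sample_nms(
    mode_set: NormalModeSet, temperature: float, n: int,
    rng: np.random.Generator, seed: int = -1, rescale: bool = True,
) -> list[PhaseSpaceSample]:
    """Classical normal-mode sampling of ``n`` initial conditions."""
    _check_sampleable(mode_set)
    if temperature < 0:
        raise SamplingError("temperature must be non-negative")
    omega = mode_set.omega
    samples = []
    for i in range(n):
        energies = sample_boltzmann_energies(mode_set, temperature, rng)[0]
        phases = rng.uniform(0.0, 2.0 * np.pi, size=omega.size)
        amp = np.sqrt(2.0 * energies) / omega
        draw = ModeSample(
            Q=amp * np.cos(phases), P=-amp * omega * np.sin(phases),
            energies=energies, amplitudes=amp, phases=phases,
        )
        target = float(energies.sum())
        if rescale and target > 0:
            Q, P, x, p = finalize_sample(mode_set, draw.Q, draw.P, target)
        else:
            x, p = to_cartesian(mode_set, draw.Q, draw.P)
            x, p = remove_com_motion(mode_set.molecule, x, p)
            Q, P = from_cartesian(mode_set, x, p)
        samples.append(PhaseSpaceSample(
            Q=Q, P=P, x=x, p=p,
            mode_energies=mode_energies(mode_set, Q, P),
            method="nms", temperature=temperature, seed=seed, index=i,
            target_energies=energies,
        ))
    return samples


def _draw_wigner_mode(
    omega: float, alpha: float, rng: np.random.Generator, scheme: str,
) -> tuple[float, float]:
    """One (Q, P) draw for a single mode from the Wigner density."""
    sigma_q = math.sqrt(1.0 / (2.0 * omega * alpha))
    sigma_p = math.sqrt(omega / (2.0 * alpha))
    if scheme == "direct":
        return rng.normal(0.0, sigma_q), rng.normal(0.0, sigma_p)
    # rejection on a +-5 sigma box; W normalized to its maximum at (0,0)
    while True:
        q = rng.uniform(-5.0 * sigma_q, 5.0 * sigma_q)
        p = rng.uniform(-5.0 * sigma_p, 5.0 * sigma_p)
        w = math.exp(-alpha * (omega * q * q + p * p / omega))
        if w > rng.random():
            return q, p


def sample_wigner(
    mode_set: NormalModeSet, temperature: float, n: int,
    rng: np.random.Generator, scheme: str = "reject", seed: int = -1,
) -> list[PhaseSpaceSample]:
    """Wigner sampling (ground-state at T = 0, thermal otherwise).

    ``scheme="reject"`` follows the accept/reject construction (uniform
    draws on a +-5 sigma box, accepted when ``W/W_max`` beats a uniform
    cutoff); ``scheme="direct"`` draws from the equivalent Gaussians.  Both
    yield the same distribution.  Center-of-mass motion is removed; no
    energy rescaling is applied.
    """
    _check_sampleable(mode_set)
    if scheme not in ("reject", "direct"):
        raise SamplingError(f"unknown Wigner scheme {scheme!r}")
    spec = thermal_spec(mode_set, temperature)
    omega = mode_set.omega
    method = "wigner0" if temperature == 0 else "wignerT"
    samples = []
    for i in range(n):
        Q = np.empty(omega.size)
        P = np.empty(omega.size)
        for k in range(omega.size):
            Q[k], P[k] = _draw_wigner_mode(
                float(omega[k]), float(spec.alpha[k]), rng, scheme
            )
        x, p = to_cartesian(mode_set, Q, P)
        x, p = remove_com_motion(mode_set.molecule, x, p)
        Q, P = from_cartesian(mode_set, x, p)
        energies = mode_energies(mode_set, Q, P)
        samples.append(PhaseSpaceSample(
            Q=Q, P=P, x=x, p=p, mode_energies=energies,
            method=method, temperature=temperature, seed=seed, index=i,
            target_energies=energies,
        ))
    return samples
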