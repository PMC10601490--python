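"""Linear vibronic coupling (LVC) model Hamiltonians.

The diabatic potential is built on dimensionless mass-frequency-scaled
normal coordinates ``Q_a = sqrt(omega_a) * (mass-weighted displacement
along mode a)``, so the shared harmonic baseline of every diabatic state
is ``sum_a (omega_a/2) Q_a^2``:

    V_ii(Q) = eps_i + sum_a kappa_{i,a} Q_a + sum_a (omega_a/2) Q_a^2
    V_ij(Q) = eta_ij + sum_a lambda_{ij,a} Q_a        (i != j)

``eps`` are vertical energy shifts, ``kappa`` state-specific gradients,
``lambda`` linear interstate couplings, ``eta`` coordinate-independent
couplings (e.g. spin-orbit-like), and the (transition) dipoles are
constant in the diabatic basis.  Diagonalizing V at a geometry yields the
adiabatic energies, Hellmann-Feynman gradients, and nonadiabatic coupling
vectors that drive trajectory surface hopping; eigenvector frames at
consecutive times are matched by overlap with per-column phase fixing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DimensionMismatchError, ModelError
from .normal_modes import NormalModeSet

#: Adiabatic gaps below this (E_h) are treated as degenerate: couplings are
#: capped instead of diverging, with a warning.
DEGENERACY_FLOOR = 1e-10

LVC_FORMAT_VERSION = 1


@dataclass
class LVCModel:
    """Diabatic LVC Hamiltonian parameters (all atomic units)."""

    omega: np.ndarray                # (n_modes,)
    epsilon: np.ndarray              # (n_states,)
    kappa: np.ndarray                # (n_states, n_modes)
    lam: np.ndarray                  # (n_states, n_states, n_modes)
    eta: np.ndarray | None = None    # (n_states, n_states)
    dipoles: np.ndarray | None = None  # (n_states, n_states, 3)

    def __post_init__(self) -> None:
        self.omega = np.atleast_1d(np.asarray(self.omega, dtype=float))
        self.epsilon = np.atleast_1d(np.asarray(self.epsilon, dtype=float))
        ns, nm = self.n_states, self.n_modes
        self.kappa = np.asarray(self.kappa, dtype=float).reshape(ns, nm)
        self.lam = np.asarray(self.lam, dtype=float).reshape(ns, ns, nm)
        if self.eta is None:
            self.eta = np.zeros((ns, ns))
        self.eta = np.asarray(self.eta, dtype=float).reshape(ns, ns)
        if self.dipoles is None:
            self.dipoles = np.zeros((ns, ns, 3))
        self.dipoles = np.asarray(self.dipoles, dtype=float).reshape(ns, ns, 3)
        for name, arr in (("lambda", self.lam), ("eta", self.eta)):
            sym = arr.swapaxes(0, 1)
            if not np.allclose(arr, sym, atol=1e-12):
                raise ModelError(f"{name} must be symmetric in (i, j)")
        if np.any(np.abs(np.einsum("iik->ik", self.lam)) > 1e-12):
            raise ModelError("lambda must have zero diagonal")
        for arr in (self.omega, self.epsilon, self.kappa, self.lam,
                    self.eta, self.dipoles):
            if not np.all(np.isfinite(arr)):
                raise ModelError("non-finite LVC parameter")

    @property
    def n_states(self) -> int:
        return self.epsilon.size

    @property
    def n_modes(self) -> int:
        return self.omega.size


@dataclass
class AdiabaticPoint:
    """Adiabatic quantities at one geometry."""

    Q: np.ndarray
    energies: np.ndarray             # ascending
    U: np.ndarray                    # diabatic -> adiabatic, columns
    gradients: np.ndarray            # (n_states, n_modes) dE_a/dQ
    nac: np.ndarray                  # (n_s, n_s, n_modes), antisymmetric
    dipoles: np.ndarray              # adiabatic (n_s, n_s, 3)
    oscillator_strengths: np.ndarray  # f_{0a}, length n_states
    degenerate_pairs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def gaps_from_ground(self) -> np.ndarray:
        return self.energies - self.energies[0]


@dataclass
class OverlapMatrix:
    """Eigenvector-frame overlap between consecutive times."""

    S: np.ndarray
    dt: float
    sign_flips: np.ndarray           # per-column signs applied to U_curr
    permutation: np.ndarray          # state reordering applied to U_curr


def diabatic_hamiltonian(model: LVCModel, Q: np.ndarray) -> np.ndarray:
    """Evaluate the diabatic potential matrix V(Q)."""
    Q = np.asarray(Q, dtype=float)
    if Q.shape != (model.n_modes,):
        raise DimensionMismatchError("Q length must equal mode count")
    base = 0.5 * float(model.omega @ Q**2)
    v = model.eta + model.lam @ Q
    diag = model.epsilon + model.kappa @ Q + base
    v[np.diag_indices(model.n_states)] = diag
    return v


def diabatic_gradient(model: LVCModel, Q: np.ndarray) -> np.ndarray:
    """dV/dQ_a as an array of shape (n_modes, n_s, n_s)."""
    ns, nm = model.n_states, model.n_modes
    g = np.transpose(model.lam, (2, 0, 1)).copy()
    idx = np.arange(ns)
    g[:, idx, idx] = model.kappa.T + (model.omega * np.asarray(Q))[:, None]
    return g


def evaluate_adiabatic(
    model: LVCModel, Q: np.ndarray, need_dipoles: bool = True,
) -> AdiabaticPoint:
    """Diagonalize V(Q); return energies, gradients, NACs, dipoles, f.

    Gradients are Hellmann-Feynman diagonal elements of ``U^T dV U``;
    nonadiabatic couplings are the off-diagonal elements divided by the
    adiabatic gap.  Gaps below :data:`DEGENERACY_FLOOR` are capped (the
    coupling uses the floor instead of the true gap) and the pair is
    recorded, with a warning.  ``need_dipoles=False`` skips the adiabatic
    dipole/oscillator-strength transform (the propagation loop does not
    use it).
    """
    v = diabatic_hamiltonian(model, Q)
    energies, u = np.linalg.eigh(v)
    grads_d = diabatic_gradient(model, Q)            # (nm, ns, ns)
    w = u.T @ (grads_d @ u)                          # (nm, ns, ns)
    ns = model.n_states
    idx = np.arange(ns)
    gradients = w[:, idx, idx].T                     # (ns, nm)
    gap = energies[None, :] - energies[:, None]      # E_b - E_a
    degenerate = []
    abs_gap = np.abs(gap)
    small = abs_gap < DEGENERACY_FLOOR
    small[idx, idx] = False
    if small.any():
        for a, b in zip(*np.nonzero(np.triu(small))):
            degenerate.append((int(a), int(b)))
        warnings.warn(
            f"near-degenerate adiabatic pair(s) {degenerate}; couplings "
            "capped at the degeneracy floor",
            stacklevel=2,
        )
    sign = np.where(gap >= 0, 1.0, -1.0)
    safe_gap = np.where(abs_gap < DEGENERACY_FLOOR,
                        sign * DEGENERACY_FLOOR, gap)
    nac = np.transpose(w, (1, 2, 0)) / safe_gap[:, :, None]
    nac[idx, idx, :] = 0.0
    if need_dipoles:
        mu3 = np.moveaxis(model.dipoles, 2, 0)       # (3, ns, ns)
        mu_ad = np.moveaxis(u.T @ (mu3 @ u), 0, 2)   # (ns, ns, 3)
        de = energies - energies[0]
        f = (2.0 / 3.0) * de * np.einsum("ax,ax->a", mu_ad[0], mu_ad[0])
        f[0] = 0.0
    else:
        mu_ad = np.zeros((ns, ns, 3))
        f = np.zeros(ns)
    return AdiabaticPoint(
        Q=np.asarray(Q, dtype=float), energies=energies, U=u,
        gradients=gradients, nac=nac, dipoles=mu_ad,
        oscillator_strengths=f, degenerate_pairs=degenerate,
    )


def frame_overlap(
    U_prev: np.ndarray, U_curr: np.ndarray, dt: float,
) -> tuple[OverlapMatrix, np.ndarray]:
    """Overlap ``S = U_prev^T U_curr`` with phase fixing and state tracking.

    Mirrors the wavefunction-overlap bookkeeping of surface-hopping codes:
    the arbitrary global phase (sign, for real eigenvectors) of each
    adiabatic state is fixed by flipping columns of ``U_curr`` until all
    diagonal overlaps are non-negative, and when a diagonal overlap
    magnitude drops below ``1/sqrt(2)`` the states are reordered by
    maximal-overlap assignment (a trivially avoided crossing).  Returns the
    corrected overlap and the corrected ``U_curr``.
    """
    if U_prev.shape != U_curr.shape:
        raise DimensionMismatchError("overlap frames differ in shape")
    s = U_prev.T @ U_curr
    n = s.shape[0]
    perm = np.arange(n)
    diag = np.abs(np.diag(s))
    if np.any(diag < 1.0 / np.sqrt(2.0)):
        perm = _max_overlap_assignment(np.abs(s))
        s = s[:, perm]
    signs = np.where(np.diag(s) < 0, -1.0, 1.0)
    s = s * signs[None, :]
    u_fixed = U_curr[:, perm] * signs[None, :]
    return OverlapMatrix(S=s, dt=dt, sign_flips=signs, permutation=perm), \
        u_fixed


def _max_overlap_assignment(abs_s: np.ndarray) -> np.ndarray:
    """Greedy maximal-overlap column assignment (near-permutation S)."""
    n = abs_s.shape[0]
    perm = np.full(n, -1)
    work = abs_s.copy()
    for _ in range(n):
        i, j = np.unravel_index(np.argmax(work), work.shape)
        perm[i] = j
        work[i, :] = -1.0
        work[:, j] = -1.0
    return perm


# ---------------------------------------------------------------------------
# Parameterization from reference ab initio-style data
# ---------------------------------------------------------------------------

def build_lvc(
    mode_set: NormalModeSet,
    energies: np.ndarray,
    gradients: np.ndarray,
    nac_vectors: dict[tuple[int, int], np.ndarray] | None = None,
    coupling_gradients: dict[tuple[int, int], np.ndarray] | None = None,
    eta: np.ndarray | None = None,
    dipoles: np.ndarray | None = None,
    degeneracy_tol: float = 1e-8,
) -> LVCModel:
    """Parameterize an LVC model from single-point data at the reference.

    ``energies`` (E_h) and Cartesian ``gradients`` (E_h/bohr, one row of
    length 3N per state) are taken at the mode_set reference geometry.
    Vertical shifts are ``eps_i = E_i - E_0``; each gradient is chained
    through ``M^(-1/2) L omega^(-1/2)`` into dimensionless coordinates to
    give ``kappa``.  Interstate couplings come either from nonadiabatic
    coupling vectors (``lambda = (E_j - E_i) * projection``) or directly
    from coupling-gradient vectors (projection only); the latter is the
    route of choice near degeneracies, where NACs diverge.
    """
    energies = np.atleast_1d(np.asarray(energies, dtype=float))
    ns = energies.size
    grads = np.asarray(gradients, dtype=float).reshape(ns, -1)
    sqrt_m = np.sqrt(mode_set.molecule.mass_vector)
    # chain rule dx/dQ_a = M^(-1/2) L_a / sqrt(omega_a)
    jac = (mode_set.modes / sqrt_m[:, None]) / np.sqrt(mode_set.omega)[None, :]
    eps = energies - energies[0]
    kappa = grads @ jac
    lam = np.zeros((ns, ns, mode_set.n_modes))
    if nac_vectors:
        for (i, j), vec in nac_vectors.items():
            gap = energies[j] - energies[i]
            if abs(gap) < degeneracy_tol:
                raise ModelError(
                    f"states {i},{j} degenerate at the reference; "
                    "parameterize with coupling_gradients instead of NACs"
                )
            proj = np.asarray(vec, dtype=float).ravel() @ jac
            lam[i, j] = gap * proj
            lam[j, i] = lam[i, j]
    if coupling_gradients:
        for (i, j), vec in coupling_gradients.items():
            proj = np.asarray(vec, dtype=float).ravel() @ jac
            lam[i, j] = proj
            lam[j, i] = proj
    return LVCModel(
        omega=mode_set.omega.copy(), epsilon=eps, kappa=kappa, lam=lam,
        eta=eta, dipoles=dipoles,
    )


def sample_to_model_coords(
    mode_set: NormalModeSet, Q_mw: np.ndarray, P_mw: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Mass-weighted (Q, P) -> dimensionless model coordinates.

    ``Q = sqrt(omega) Q_mw`` and ``P = P_mw / sqrt(omega)``, so the
    harmonic energy ``(P_mw^2 + omega^2 Q_mw^2)/2`` becomes
    ``(omega/2)(P^2 + Q^2)``.
    """
    s = np.sqrt(mode_set.omega)
    return s * np.asarray(Q_mw, dtype=float), np.asarray(P_mw, dtype=float) / s


# ---------------------------------------------------------------------------
# Text format
# ---------------------------------------------------------------------------

def write_lvc(model: LVCModel, path: str | Path) -> None:
    """Write the documented plain-text LVC parameter format."""
    ns, nm = model.n_states, model.n_modes
    out = [
        f"# LVC model format v{LVC_FORMAT_VERSION} (all values in atomic units)",
        f"LVC {ns} {nm}",
        "OMEGA",
        " ".join(f"{w:.16e}" for w in model.omega),
        "EPSILON",
        " ".join(f"{e:.16e}" for e in model.epsilon),
        "KAPPA",
    ]
    out.extend(" ".join(f"{v:.16e}" for v in row) for row in model.kappa)
    out.append("LAMBDA")
    for i in range(ns):
        for j in range(i + 1, ns):
            if np.any(model.lam[i, j] != 0):
                out.append(f"{i} {j} " +
                           " ".join(f"{v:.16e}" for v in model.lam[i, j]))
    out.append("ETA")
    for i in range(ns):
        for j in range(i + 1, ns):
            if model.eta[i, j] != 0:
                out.append(f"{i} {j} {model.eta[i, j]:.16e}")
    out.append("DIPOLES")
    for i in range(ns):
        for j in range(i, ns):
            if np.any(model.dipoles[i, j] != 0):
                out.append(f"{i} {j} " +
                           " ".join(f"{v:.16e}" for v in model.dipoles[i, j]))
    Path(path).write_text("\n".join(out) + "\n")


def read_lvc(path: str | Path) -> LVCModel:
    """Read the plain-text LVC parameter format written by :func:`write_lvc`."""
    lines = [l.split("#", 1)[0].strip()
             for l in Path(path).read_text().splitlines()]
    lines = [l for l in lines if l]
    if not lines or not lines[0].startswith("LVC"):
        raise ModelError(f"{path}: missing LVC header")
    _, ns_s, nm_s = lines[0].split()
    ns, nm = int(ns_s), int(nm_s)
    blocks: dict[str, list[str]] = {}
    current = None
    for line in lines[1:]:
        key = line.upper()
        if key in ("OMEGA", "EPSILON", "KAPPA", "LAMBDA", "ETA", "DIPOLES"):
            current = key
            blocks[current] = []
        elif current is None:
            raise ModelError(f"{path}: data before first block: {line!r}")
        else:
            blocks[current].append(line)
    for req in ("OMEGA", "EPSILON", "KAPPA"):
        if req not in blocks:
            raise ModelError(f"{path}: missing {req} block")
    omega = np.array(" ".join(blocks["OMEGA"]).split(), dtype=float)
    eps = np.array(" ".join(blocks["EPSILON"]).split(), dtype=float)
    if omega.size != nm or eps.size != ns:
        raise ModelError(f"{path}: header/block size mismatch")
    kappa = np.array(" ".join(blocks["KAPPA"]).split(),
                     dtype=float).reshape(ns, nm)
    lam = np.zeros((ns, ns, nm))
    for line in blocks.get("LAMBDA", []):
        parts = line.split()
        i, j = int(parts[0]), int(parts[1])
        lam[i, j] = lam[j, i] = np.array(parts[2:], dtype=float)
    eta = np.zeros((ns, ns))
    for line in blocks.get("ETA", []):
        parts = line.split()
        i, j = int(parts[0]), int(parts[1])
        eta[i, j] = eta[j, i] = float(parts[2])
    dip = np.zeros((ns, ns, 3))
    for line in blocks.get("DIPOLES", []):
        parts = line.split()
        i, j = int(parts[0]), int(parts[1])
        dip[i, j] = dip[j, i] = np.array(parts[2:5], dtype=float)
    return LVCModel(omega=omega, epsilon=eps, kappa=kappa, lam=lam,
                    eta=eta, dipoles=dip)
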