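"""Tully fewest-switches surface hopping (FSSH) on LVC model surfaces.

Nuclei follow velocity-Verlet dynamics on one adiabatic surface of an
:class:`~vibronica.lvc_model.LVCModel`, in the model's dimensionless
coordinates, where the classical Hamiltonian is
``H = sum_a (omega_a/2) P_a^2 + E_active(Q)`` so ``dQ/dt = omega * P``.

The electronic coefficients obey the time-dependent Schroedinger equation
in the adiabatic basis, ``dc_k/dt = -i E_k c_k - sum_i T_ki c_i``, driven
by time-derivative couplings (TDC) obtained from either

* ``nac`` — the analytic route ``T_ik = d_ik . dQ/dt``, or
* ``hst`` — the Hammes-Schiffer--Tully overlap approximation
  ``T_ik = (S_ik - S_ki) / (2 dt)`` with
  ``S_ik = <phi_i(t)|phi_k(t + dt)>``, here the overlap of eigenvector
  frames of the model Hamiltonian at consecutive steps, with per-column
  phase (sign) correction.

Hops are attempted after each full nuclear step using midpoint couplings;
on a hop, kinetic energy is adjusted along the nonadiabatic coupling
vector (uniform momentum scaling as fallback) to conserve total energy,
and hops without sufficient kinetic energy are frustrated: nothing
changes.  Plain FSSH — no decoherence correction — is the default; an
energy-based decoherence damping can be switched on.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import DimensionMismatchError, PropagationError
from .lvc_model import (
    AdiabaticPoint,
    LVCModel,
    OverlapMatrix,
    evaluate_adiabatic,
)

#: Default number of electronic substeps per nuclear step.
N_SUBSTEPS = 25


@dataclass
class CouplingMatrix:
    """Antisymmetric time-derivative couplings T_ik (a.u.^-1)."""

    T: np.ndarray
    source: str  # "nac" | "hst"

    def __post_init__(self) -> None:
        t = np.asarray(self.T, dtype=float)
        if not np.allclose(t, -t.T, atol=1e-10):
            raise PropagationError("TDC matrix must be antisymmetric")
        self.T = 0.5 * (t - t.T)


@dataclass
class TrajectoryState:
    """Snapshot of one trajectory at an output time."""

    time: float
    Q: np.ndarray
    P: np.ndarray
    active: int
    coefficients: np.ndarray
    energies: np.ndarray
    total_energy: float


@dataclass
class Trajectory:
    """Result of one FSSH propagation."""

    states: list[TrajectoryState]
    times: np.ndarray                # every nuclear step
    active_history: np.ndarray       # active state at every nuclear step
    energy_history: np.ndarray       # total energy at every nuclear step
    hops: list[tuple[float, int, int]] = field(default_factory=list)
    frustrated: int = 0
    seed: int = -1
    termination: str = "completed"

    @property
    def n_hops(self) -> int:
        return len(self.hops)


def hst_tdc(overlap: OverlapMatrix) -> CouplingMatrix:
    """TDC from a phase-corrected frame overlap: ``(S - S^T)/(2 dt)``.

    This is the antisymmetrized finite-difference estimate of
    ``<phi_i | d phi_k / dt>`` at the step midpoint, accurate to O(dt).
    """
    if overlap.dt <= 0:
        raise PropagationError("time step must be positive")
    s = overlap.S
    return CouplingMatrix(T=(s - s.T) / (2.0 * overlap.dt), source="hst")


def nac_tdc(point: AdiabaticPoint, velocity: np.ndarray) -> CouplingMatrix:
    """Analytic TDC ``T_ik = d_ik . dQ/dt`` at one geometry."""
    t = point.nac @ np.asarray(velocity, dtype=float)
    return CouplingMatrix(T=0.5 * (t - t.T), source="nac")


def propagate_electronic(
    c: np.ndarray,
    energies_pair: tuple[np.ndarray, np.ndarray],
    tdc_pair: tuple[np.ndarray, np.ndarray],
    dt: float,
    n_sub: int = N_SUBSTEPS,
) -> np.ndarray:
    """Propagate electronic coefficients across one nuclear step.

    Energies and couplings are interpolated linearly between the step
    endpoints; each of ``n_sub`` substeps applies the exact exponential of
    the midpoint effective Hamiltonian ``H = diag(E) - i T`` (Hermitian for
    antisymmetric real T), so the norm is conserved to round-off.
    """
    c = np.asarray(c, dtype=complex)
    e0, e1 = (np.asarray(e, dtype=float) for e in energies_pair)
    t0, t1 = (np.asarray(t, dtype=float) for t in tdc_pair)
    if not (np.all(np.isfinite(c)) and np.all(np.isfinite(e0))
            and np.all(np.isfinite(e1)) and np.all(np.isfinite(t0))
            and np.all(np.isfinite(t1))):
        raise PropagationError("non-finite electronic propagation input")
    if dt <= 0:
        raise PropagationError("time step must be positive")
    return _propagate_raw(c, e0, e1, t0, t1, dt, n_sub)


def _propagate_2state(c, e0, e1, t0, t1, dt, n_sub):
    """Closed-form midpoint exponentials for the two-state case.

    ``H = m I + Delta sigma_z + t sigma_y`` gives
    ``exp(-iHh) = e^{-imh}(cos(rh) I - i sin(rh)(Delta sigma_z +
    t sigma_y)/r)`` with ``r = sqrt(Delta^2 + t^2)``; all substep
    propagator elements are evaluated vectorized, then applied in order.
    """
    h = dt / n_sub
    f = (np.arange(n_sub) + 0.5) / n_sub
    ea = (1 - f) * e0[0] + f * e1[0]
    eb = (1 - f) * e0[1] + f * e1[1]
    tt = (1 - f) * t0[0, 1] + f * t1[0, 1]
    m = 0.5 * (ea + eb)
    delta = 0.5 * (ea - eb)
    r = np.sqrt(delta * delta + tt * tt)
    cos_r = np.cos(r * h)
    sinc = np.where(r > 0, np.sin(r * h) / np.where(r > 0, r, 1.0), h)
    gphase = np.exp(-1j * m * h)
    # exp(-iHh) = gphase * [[cos - i sinc*delta, -sinc*t], [sinc*t, cos + i sinc*delta]]
    u00 = gphase * (cos_r - 1j * sinc * delta)
    u01 = gphase * (-sinc * tt)
    u10 = gphase * (sinc * tt)
    u11 = gphase * (cos_r + 1j * sinc * delta)
    a, b = complex(c[0]), complex(c[1])
    for k in range(n_sub):
        a, b = u00[k] * a + u01[k] * b, u10[k] * a + u11[k] * b
    return np.array([a, b])


def _propagate_raw(c, e0, e1, t0, t1, dt, n_sub):
    """Validation-free core of :func:`propagate_electronic`."""
    if c.size == 1:
        # pure phase; exact for linearly interpolated E
        return c * np.exp(-0.5j * (e0[0] + e1[0]) * dt)
    if c.size == 2:
        return _propagate_2state(c, e0, e1, t0, t1, dt, n_sub)
    h = dt / n_sub
    for k in range(n_sub):
        f = (k + 0.5) / n_sub
        e = (1 - f) * e0 + f * e1
        t = (1 - f) * t0 + f * t1
        heff = np.diag(e).astype(complex) - 1j * t
        evals, vecs = np.linalg.eigh(heff)
        phase = np.exp(-1j * evals * h)
        c = vecs @ (phase * (vecs.conj().T @ c))
    return c


def hop_probabilities(
    c: np.ndarray, tdc: CouplingMatrix, active: int, dt: float,
) -> np.ndarray:
    """Fewest-switches hop probabilities out of the active state.

    ``g_{a->k} = max[0, (2 dt / |c_a|^2) Re(c_a^* c_k T_{ak})]`` with
    ``T_ik = <phi_i|d phi_k/dt>`` — the positive part of the population
    flux leaving the active state toward k under the electronic equation
    of motion — clipped so the total never exceeds one.  A depleted
    active coefficient (``|c_a|^2 < 1e-12``) zeroes all probabilities
    with a warning.
    """
    return _hop_probabilities_raw(np.asarray(c, dtype=complex), tdc.T,
                                  active, dt)


def _hop_probabilities_raw(c, t_mat, active, dt):
    pop_a = abs(c[active]) ** 2
    if pop_a < 1e-12:
        warnings.warn("active-state population depleted; no hop attempted",
                      stacklevel=2)
        return np.zeros(c.size)
    g = (2.0 * dt / pop_a) * np.real(np.conj(c[active]) * c * t_mat[active, :])
    g[active] = 0.0
    np.clip(g, 0.0, None, out=g)
    total = g.sum()
    if total > 1.0:
        g /= total
    return g


def attempt_hop(
    g: np.ndarray,
    xi: float,
    active: int,
    point: AdiabaticPoint,
    P: np.ndarray,
    omega: np.ndarray,
) -> tuple[int, np.ndarray, bool]:
    """Select a hop target from probabilities and adjust momenta.

    The target is chosen by comparing one uniform draw ``xi`` with the
    cumulative probabilities.  On a hop the kinetic energy is changed by
    ``-(E_new - E_old)`` by adjusting the momentum along the nonadiabatic
    coupling vector of the pair (uniform scaling when the NAC is
    ill-conditioned); if that is impossible the hop is frustrated and the
    state and momenta are left unchanged.  Returns
    ``(new_active, new_P, frustrated)``.
    """
    cumulative = 0.0
    target = -1
    for k, gk in enumerate(g):
        if gk <= 0:
            continue
        cumulative += gk
        if xi < cumulative:
            target = k
            break
    if target < 0:
        return active, P, False
    d_e = point.energies[target] - point.energies[active]
    d_vec = point.nac[active, target]
    new_p = _rescale_momentum(P, omega, d_e, d_vec)
    if new_p is None:
        return active, P, True
    return target, new_p, False


def _rescale_momentum(P, omega, d_e, direction):
    """Solve the energy-conserving momentum adjustment; None if frustrated."""
    ke = 0.5 * float(omega @ (P * P))
    norm = float(np.linalg.norm(direction))
    if norm > 1e-12 and np.all(np.isfinite(direction)):
        d = direction / norm
        a = float(omega @ (d * d))
        b = float(omega @ (P * d))
        disc = b * b - 2.0 * a * d_e
        if disc < 0:
            return None
        root = math.sqrt(disc)
        g1 = (-b + root) / a
        g2 = (-b - root) / a
        gamma = g1 if abs(g1) <= abs(g2) else g2
        return P + gamma * d
    if ke <= d_e:
        return None
    return P * math.sqrt(1.0 - d_e / ke)


def _align_frame(u_prev: np.ndarray, point: AdiabaticPoint) -> None:
    """Sign-align the eigenvector frame of ``point`` to the previous step.

    Column signs are flipped so diagonal overlaps are non-negative, and
    the NAC tensor is updated consistently (``d_ab -> s_a s_b d_ab``).
    State ordering stays energy-ascending, the standard FSSH convention.
    """
    signs = np.where(np.einsum("ij,ij->j", u_prev, point.U) < 0, -1.0, 1.0)
    if np.any(signs < 0):
        point.U *= signs[None, :]
        point.nac *= signs[:, None, None] * signs[None, :, None]
        point.dipoles = point.dipoles * signs[:, None, None] \
            * signs[None, :, None]


def run_trajectory(
    model: LVCModel,
    Q0: np.ndarray,
    P0: np.ndarray,
    initial_state: int | np.ndarray,
    dt: float,
    n_steps: int,
    tdc_source: str = "nac",
    rng: np.random.Generator | None = None,
    n_sub: int = N_SUBSTEPS,
    stride: int = 1,
    seed: int = -1,
    decoherence: float | None = None,
) -> Trajectory:
    """Propagate one FSSH trajectory.

    Parameters
    ----------
    Q0, P0
        Initial dimensionless model coordinates/momenta (see
        :func:`vibronica.lvc_model.sample_to_model_coords`).
    initial_state
        Active adiabatic state index, or a complex coefficient vector
        (the active state is then the one of largest population).
    dt
        Nuclear time step in atomic time units.
    tdc_source
        ``"nac"`` for analytic couplings, ``"hst"`` for the overlap-based
        scheme.
    decoherence
        If not None, the C parameter (E_h) of energy-based decoherence
        damping; plain FSSH when None (the default).

    Non-finite energies terminate the trajectory with
    ``termination="escaped"`` instead of raising.
    """
    if tdc_source not in ("nac", "hst"):
        raise PropagationError(f"unknown TDC source {tdc_source!r}")
    if dt <= 0 or n_steps < 1:
        raise PropagationError("dt and n_steps must be positive")
    rng = np.random.default_rng(0) if rng is None else rng
    omega = model.omega
    Q = np.array(Q0, dtype=float)
    P = np.array(P0, dtype=float)
    if Q.shape != (model.n_modes,) or P.shape != (model.n_modes,):
        raise DimensionMismatchError("Q0/P0 length must equal mode count")
    if np.isscalar(initial_state) or np.ndim(initial_state) == 0:
        active = int(initial_state)
        c = np.zeros(model.n_states, dtype=complex)
        c[active] = 1.0
    else:
        c = np.asarray(initial_state, dtype=complex)
        c = c / np.linalg.norm(c)
        active = int(np.argmax(np.abs(c) ** 2))
    if not 0 <= active < model.n_states:
        raise PropagationError("active state index out of range")

    point = evaluate_adiabatic(model, Q, need_dipoles=False)
    force = -point.gradients[active]
    velocity = omega * P
    t_raw = point.nac @ velocity
    t_mat = 0.5 * (t_raw - t_raw.T)
    energy = 0.5 * float(omega @ (P * P)) + point.energies[active]

    times = np.empty(n_steps + 1)
    active_hist = np.empty(n_steps + 1, dtype=int)
    energy_hist = np.empty(n_steps + 1)
    times[0], active_hist[0], energy_hist[0] = 0.0, active, energy
    states = [TrajectoryState(0.0, Q.copy(), P.copy(), active, c.copy(),
                              point.energies.copy(), energy)]
    hops: list[tuple[float, int, int]] = []
    frustrated = 0
    termination = "completed"

    for step in range(1, n_steps + 1):
        p_half = P + 0.5 * dt * force
        q_new = Q + dt * omega * p_half
        try:
            new_point = evaluate_adiabatic(model, q_new, need_dipoles=False)
        except np.linalg.LinAlgError:
            new_point = None
        if new_point is None or not np.all(np.isfinite(new_point.energies)):
            termination = "escaped"
            times = times[:step]
            active_hist = active_hist[:step]
            energy_hist = energy_hist[:step]
            break
        _align_frame(point.U, new_point)
        force_new = -new_point.gradients[active]
        p_new = p_half + 0.5 * dt * force_new
        v_new = omega * p_new

        if tdc_source == "nac":
            t_raw = new_point.nac @ v_new
            t_new = 0.5 * (t_raw - t_raw.T)
            t_mid = 0.5 * (t_mat + t_new)
            pair = (t_mat, t_new)
        else:
            s = point.U.T @ new_point.U
            t_mid = (s - s.T) / (2.0 * dt)
            t_new = t_mid
            pair = (t_mid, t_mid)

        c = _propagate_raw(c, point.energies, new_point.energies,
                           pair[0], pair[1], dt, n_sub)
        g = _hop_probabilities_raw(c, t_mid, active, dt)
        if g.sum() > 0:
            new_active, p_new, was_frustrated = attempt_hop(
                g, rng.random(), active, new_point, p_new, omega
            )
            if was_frustrated:
                frustrated += 1
            elif new_active != active:
                hops.append((step * dt, active, new_active))
                active = new_active
                force_new = -new_point.gradients[active]
        else:
            rng.random()  # keep the draw sequence aligned across sources

        if decoherence is not None:
            c = _apply_decoherence(c, active, new_point.energies,
                                   0.5 * float(omega @ (p_new * p_new)),
                                   dt, decoherence)

        Q, P, force, point, t_mat = q_new, p_new, force_new, new_point, t_new
        energy = 0.5 * float(omega @ (P * P)) + point.energies[active]
        times[step] = step * dt
        active_hist[step] = active
        energy_hist[step] = energy
        if step % stride == 0:
            states.append(TrajectoryState(
                step * dt, Q.copy(), P.copy(), active, c.copy(),
                point.energies.copy(), energy,
            ))

    return Trajectory(states=states, times=times,
                      active_history=active_hist, energy_history=energy_hist,
                      hops=hops, frustrated=frustrated, seed=seed,
                      termination=termination)


def _apply_decoherence(c, active, energies, kinetic, dt, c_param):
    """Energy-based decoherence damping of non-active coefficients."""
    for k in range(c.size):
        if k == active:
            continue
        gap = abs(energies[k] - energies[active])
        if gap < 1e-12:
            continue
        tau = (1.0 + c_param / max(kinetic, 1e-12)) / gap
        c[k] *= math.exp(-dt / tau)
    pop_other = float(np.sum(np.abs(c) ** 2)) - abs(c[active]) ** 2
    pop_active = abs(c[active]) ** 2
    if pop_active > 0:
        c[active] *= math.sqrt(max(1.0 - pop_other, 0.0) / pop_active)
    return c


def run_ensemble(
    model: LVCModel,
    initial_conditions: list[tuple[np.ndarray, np.ndarray]],
    initial_state: int,
    dt: float,
    n_steps: int,
    tdc_source: str = "nac",
    master_seed: int = 0,
    stride: int = 1,
    n_sub: int = N_SUBSTEPS,
) -> list[Trajectory]:
    """Run one trajectory per initial condition.

    Each trajectory gets its own generator seeded from
    ``(master_seed, index)``, so results are reproducible and independent
    of execution order.
    """
    trajectories = []
    for idx, (q0, p0) in enumerate(initial_conditions):
        rng = np.random.default_rng([master_seed, idx])
        trajectories.append(run_trajectory(
            model, q0, p0, initial_state, dt, n_steps,
            tdc_source=tdc_source, rng=rng, stride=stride, n_sub=n_sub,
            seed=master_seed,
        ))
    return trajectories


def ensemble_populations(
    trajectories: list[Trajectory], t_grid: np.ndarray,
) -> np.ndarray:
    """Classical state populations (active-state counts) on a time grid.

    Zero-order hold between nuclear steps; trajectories that terminated
    early keep their last state.  Returns shape ``(len(t_grid), n_states)``.
    """
    if not trajectories:
        raise PropagationError("empty trajectory ensemble")
    n_states = trajectories[0].states[0].coefficients.size
    t_grid = np.asarray(t_grid, dtype=float)
    counts = np.zeros((t_grid.size, n_states))
    for traj in trajectories:
        idx = np.searchsorted(traj.times, t_grid, side="right") - 1
        idx = np.clip(idx, 0, traj.active_history.size - 1)
        counts[np.arange(t_grid.size), traj.active_history[idx]] += 1.0
    return counts / len(trajectories)


def fit_decay(
    populations: np.ndarray, t_grid: np.ndarray,
    window: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Least-squares single-exponential fit ``p(t) = A exp(-k t)``.

    Returns ``(k, standard_error_of_k)``.  ``window`` restricts the fit to
    a time interval.
    """
    t = np.asarray(t_grid, dtype=float)
    p = np.asarray(populations, dtype=float)
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        t, p = t[mask], p[mask]
    if t.size < 3:
        raise PropagationError("too few points for a decay fit")

    def model_fn(tt, amp, k):
        return amp * np.exp(-k * tt)

    span = t[-1] - t[0] if t[-1] > t[0] else 1.0
    k0 = 1.0 / span
    popt, pcov = curve_fit(model_fn, t, p, p0=[max(p[0], 1e-8), k0],
                           maxfev=10000)
    return float(popt[1]), float(np.sqrt(pcov[1, 1]))
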