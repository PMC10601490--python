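# Methods

This note records the models implemented, the defaults that matter, the
numerical choices, and what the synthetic test systems do and do not
probe.

## Units and conventions

Everything internal is in Hartree atomic units (ℏ = m_e = e = a₀ = 1).
I/O accepts Å, amu, cm⁻¹, eV, fs and converts on ingest through a single
registry (1 amu = 1822.888486 m_e, 1 Å = 1.8897261258 bohr,
1 cm⁻¹ = 4.556335×10⁻⁶ E_h, 1 eV = 3.674932×10⁻² E_h,
1 fs = 41.341374 a.t.u., k_B = 3.166811563×10⁻⁶ E_h/K). Default atomic
masses are those of the most abundant isotope (H 1.007825, C 12, ...),
the convention of dynamics codes — an isotope-averaged weight describes
no physical molecule. Per-atom overrides (`mass[i]=<amu>` on the XYZ
comment line) support isotope studies.

## Normal modes

The Cartesian Hessian (plain-text format: atom count, then 3N×3N reals
in E_h/bohr², symmetrized on read with tolerance 1e-8) is mass-weighted
as M^(−1/2)HM^(−1/2). Rigid translations and rotations are removed by
explicit construction of the 6 (5 linear, 0 monatomic) mass-weighted
generator vectors and projection onto their orthogonal complement;
linearity is detected from the inertia-tensor rank. This projector
route, rather than eigenvalue shifting, makes the null space directly
testable (a rigid translation applied to the projected Hessian returns
zero force). Frequencies are √eigenvalue; modes with |ω| < 10 cm⁻¹
after projection are discarded as projection residue (configurable);
negative eigenvalues are kept as flagged imaginary modes (|ω| stored,
warning emitted) and are never sampled. Eigenvector columns carry a
deterministic sign (largest-magnitude component positive, first index
on ties) so archives are bit-reproducible.

## Initial conditions

Coordinates here are mass-weighted normal coordinates Q (a.u.) with
conjugate momenta P; the Cartesian views are x = x_eq + M^(−1/2)LQ and
p = M^(1/2)LP, exactly invertible because L is orthonormal.

**Normal-mode sampling (classical).** Each mode independently receives
E_i = −k_B T ln(u), u uniform on (0,1] — the exponential law with mean
k_B T — and a uniform phase φ; then Q_i = A_i cos φ, P_i = −A_i ω_i sin φ
with A_i = √(2E_i)/ω_i, which carries exactly E_i of harmonic energy for
every phase. After the Cartesian transform, center-of-mass displacement
and momentum are removed and both Q and P are scaled by the single
factor √(E_target/E_current) to restore the sampled ΣE_i. One common
factor (not separate position/momentum factors) preserves each mode's
kinetic/potential split. The Boltzmann draw is stored on each sample
(`target_energies`) so exactness is auditable.

**Wigner sampling (quantum).** The harmonic Wigner density
W ∝ exp(−α(ωQ² + P²/ω)) with α(T) = tanh(ℏω/2k_BT); α = 1 at T = 0
(ground state), α → k_BT·2/(ℏω)·... → the classical limit at high T.
Two schemes target the same density: `reject` draws uniformly on ±5σ
boxes and accepts when W/W_max beats a uniform cutoff (truncation error
< 1e-5 of the mass), `direct` draws the equivalent Gaussians. Closed
forms used in tests: Var(Q) = 1/(2ωα), Var(P) = ω/(2α), mean energy
(ω/2)coth(ℏω/2k_BT). **No energy rescaling is applied to Wigner
ensembles** — rescaling to the classical ΣE_i would destroy the
zero-point spread that distinguishes the quantum distribution; this is
the reason Wigner ensembles come out broader and hotter than NMS at the
same temperature, which the tests assert on a 2000 cm⁻¹ mode at 300 K.
Only translation is removed by default; rigid rotation is left in the
samples (an optional cleanup removes it), since angular momentum carries
physical information about the sampled state.

Determinism: every sampler takes a `numpy.random.Generator`; a fixed
seed reproduces ensembles bitwise.

## LVC models

Dimensionless mass-frequency-scaled coordinates Q_α = √ω_α × (mass-
weighted displacement) make the shared ground baseline Σ(ω_α/2)Q_α² and
match common vibronic-model practice. Parameterization from reference
single-point data: ε_i = E_i − E_0; κ_{i,α} is the Cartesian gradient
chained through M^(−1/2)L·ω_α^(−1/2); λ_{ij,α} is the gap times the
same projection of the NAC vector (NACs diverge at degeneracies, so
raw coupling-gradient vectors are accepted as a first-class
alternative, projection only). Constant couplings η (spin–orbit-like)
and constant diabatic dipoles complete the model; no quadratic terms,
no geometry-dependent couplings or dipoles.

Adiabatic quantities come from the symmetric eigendecomposition:
gradients and couplings via the Hellmann–Feynman elements of U^T(∂V)U,
with d_ab = [U^T ∂V U]_ab/(E_b − E_a). Gaps under 1e-10 E_h are capped
at that floor (couplings finite, warning emitted, pair recorded) rather
than raising mid-trajectory — robustness near conical intersections.
Oscillator strengths use f = (2/3)ΔE|μ|² in atomic units.

Eigenvector phase is meaningless pointwise and fixed only *between*
frames: `frame_overlap` flips columns of the later frame until all
diagonal overlaps are non-negative, and reassigns states by maximal
overlap when a diagonal magnitude drops below 1/√2 (trivially avoided
crossings). The propagation loop applies the sign fix every step (for
both coupling schemes) and keeps energy-ascending state ordering, the
standard surface-hopping convention.

## Surface hopping

Classical Hamiltonian H = Σ(ω_α/2)P_α² + E_active(Q), so Q̇ = ωP; nuclei
use velocity Verlet (time-reversible; tested by momentum-negation
retrace). Electronic coefficients obey ċ = −i·diag(E)c − Tc and are
advanced by n_sub = 25 midpoint exponentials of the Hermitian
H_eff = diag(E) − iT per nuclear step, with E and T linearly
interpolated across the step — unitary by construction (norm drift at
round-off over 10⁴ steps). The two-state propagator uses the closed
Pauli form; larger systems use eigendecomposition per substep.

Couplings: `nac` evaluates T = d·Q̇ at both step ends; `hst` builds
T = (S − Sᵀ)/(2Δt) from the phase-corrected eigenvector overlap, an
O(Δt)-midpoint estimate whose deviation from the analytic value falls
quadratically with Δt (asserted ≥ 3.5× reduction on halving).

Hops are attempted once per nuclear step, after the step, with midpoint
couplings: g_{a→k} = max[0, (2Δt/|c_a|²)Re(c_a* c_k T_ak)], clipped so
Σg ≤ 1; this is exactly the positive part of the population flux
leaving the active state, so probabilities are non-negative toward the
gaining state. Target selection compares one uniform draw against the
cumulative probabilities. Energy conservation at a hop adjusts the
momentum along the nonadiabatic coupling vector of the pair (solving
the quadratic for the smaller-|γ| root), falling back to uniform
momentum scaling when the NAC is ill-conditioned; hops with
insufficient kinetic energy along that direction are frustrated — state
and momenta unchanged, never velocity-reversed. Plain FSSH is the
default; an optional energy-based decoherence damping exists but is
off, matching the plain-Tully scope.

Ensembles seed one generator per trajectory from (master_seed, index),
so results are reproducible and independent of execution order.
Non-finite energies terminate a trajectory with reason "escaped" rather
than raising. Populations are active-state counts on a zero-order-hold
time grid; lifetimes come from a least-squares single-exponential fit
(parameter standard error from the covariance).

Validation anchors: total-energy drift < 1e-6 E_h over 1000 steps at
Δt = 0.5 fs on a 500 cm⁻¹ surface; oscillation period within 0.1% of
2π/ω; and on a linear two-diabat crossing (slopes ±κ, constant η) the
diabatic survival of 2000 trajectories matches the Landau–Zener closed
form exp(−2πη²/(v|Δslope|)) within statistics for both coupling
schemes, with the crossing velocity v obtained from energy conservation.

## Spectra and kinetics

NEA: each transition contributes a unit-area lineshape at ΔE weighted
by f; δ is interpreted as FWHM for both Gaussian and Lorentzian (the
Gaussian σ is δ/2√(2ln2)). The ensemble average times
C = πe²ℏ/(2m_e c ε₀) (≈1.0975×10⁻¹⁶ cm²·eV, computed from CODATA
constants at import) gives the absolute cross section; the area sum
rule (area = C × mean total f, independent of δ) is asserted with
analytic truncation corrections on the finite grid. Default grid:
[min ΔE − 3δ, max ΔE + 3δ], 1000 points.

Transient maps extract snapshots every `stride` stored steps and use the
trajectory's active state only (classical NEA-over-trajectories; no
coherence contributions): transitions to higher states enter positive
(excited-state absorption), to lower states negative (stimulated
emission, with the emission gap and strength); an optional Gaussian
instrument-response convolution in time is off by default.

A cross section is pointwise, so its wavelength view is
σ(λ) = σ(E(λ)) with λ(nm) = 1239.841984/E(eV); Jacobians apply only to
per-eV vs per-nm spectral densities, not to σ. The photolysis integral
J = ∫φσF dλ uses composite trapezoid on the merged grid of all input
curves, so piecewise-linear inputs integrate exactly (the constant toy
reproduces J = 1e-2 s⁻¹ to machine precision).

Rate equations: dp/dt = Kp with non-negative off-diagonal rates and
non-positive column sums; p(t) = exp(Kt)p(0) via scaling-and-squaring.
A 0.01 fs⁻¹ two-state decay reaches 1/e at 100 fs exactly.

## What the synthetic systems do and do not show

The fixtures are built backwards from known answers: the diatomic has
ω = √(k/μ); the bent triatomic's Hessian is reconstructed from chosen
(ω, L) so analysis must return them exactly; crossing models realize
the Landau–Zener geometry; the random multimode models are
pyrazine-like in scale (ω log-uniform in 500–2000 cm⁻¹, κ ~ 0.01,
λ ~ 0.005 E_h). Passing tests therefore demonstrate the *machinery* —
transforms, conservation laws, statistics, convergence orders — on
harmonic-plus-linear surfaces. They do not probe anharmonicity, true
conical-intersection topology beyond the linear model, geometry-
dependent couplings or dipoles, spin–orbit dynamics beyond constant η,
solvent or QM/MM effects, or the accuracy of any electronic-structure
method; quantitative agreement with experiments on real molecules is
out of scope by construction.

## Problem sizes and defaults

Chosen so the whole validation (test suite plus acceptance script) runs
in a few minutes on one CPU: 10⁵-sample moment checks, 2000-trajectory
hopping statistics at Δt = 0.1 fs (~120 steps per trajectory),
1000-step conservation runs at Δt = 0.5 fs, 5×10⁴-point spectral grids.
n_sub = 25 electronic substeps per nuclear step is comfortable for the
phase frequencies these models generate (E·Δt/n_sub ≪ 1); the
degeneracy floor (1e-10 E_h), external-mode threshold (10 cm⁻¹), and
rejection-box half-width (5σ) are exposed as parameters.

## Known limitations

- No decoherence correction by default: long-time FSSH coherence
  artifacts are inherited from plain Tully dynamics.
- The overlap (`hst`) coupling scheme assumes the time step resolves the
  coupling region; extremely narrow crossings need smaller Δt (the
  convergence test quantifies the O(Δt²) error).
- `frame_overlap` state tracking is greedy maximal-overlap assignment —
  adequate for near-permutation overlaps, not a general assignment
  solver.
- Archives store double precision throughout; no compression.
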