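"""File formats, the molecule container, and persistent archives.

Readers convert to atomic units on ingest (coordinates to bohr, masses to
electron masses); writers convert back to the conventional units of each
format.  All formats here are plain text except the ensemble/trajectory
archives, which use HDF5 with an explicit schema version.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from . import units
from .errors import (
    ArchiveVersionError,
    CoordinateParseError,
    CorruptRecordError,
    DimensionMismatchError,
    HessianFormatError,
    MalformedCountError,
    MoldenSectionError,
    UnknownElementError,
)

# Masses of the most abundant isotope, in amu.  Dynamics and vibrational
# sampling conventionally use single-isotope masses (an averaged weight
# corresponds to no physical molecule); override per atom for isotope
# studies via XYZ comment directives or the Molecule constructor.
ISOTOPE_MASSES_AMU: dict[str, float] = {
    "H": 1.007825, "D": 2.014102, "T": 3.016049,
    "He": 4.002603, "Li": 7.016004, "Be": 9.012182, "B": 11.009305,
    "C": 12.0, "N": 14.003074, "O": 15.994915, "F": 18.998403,
    "Ne": 19.992440, "Na": 22.989770, "Mg": 23.985042, "Al": 26.981538,
    "Si": 27.976927, "P": 30.973762, "S": 31.972071, "Cl": 34.968853,
    "Ar": 39.962383, "K": 38.963707, "Ca": 39.962591, "Sc": 44.955910,
    "Ti": 47.947947, "V": 50.943964, "Cr": 51.940512, "Mn": 54.938050,
    "Fe": 55.934942, "Co": 58.933200, "Ni": 57.935348, "Cu": 62.929601,
    "Zn": 63.929147, "Br": 78.918338, "I": 126.904468, "Hg": 201.970626,
}

ARCHIVE_SCHEMA_VERSION = 1


@dataclass
class Molecule:
    """A molecular geometry in atomic units.

    Parameters
    ----------
    symbols
        Element symbol per atom.
    coords
        Cartesian coordinates, shape ``(n_atoms, 3)``, in bohr.
    masses
        Atomic masses in electron masses.  If omitted, filled from the
        single-isotope table (amu values converted on construction).
    comment
        Free-form comment (e.g. the XYZ comment line).
    """

    symbols: list[str]
    coords: np.ndarray
    masses: np.ndarray | None = None
    comment: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.symbols) != self.coords.shape[0]:
            raise DimensionMismatchError(
                f"{len(self.symbols)} symbols but {self.coords.shape[0]} "
                "coordinate rows"
            )
        if self.masses is None:
            self.masses = np.array(
                [_default_mass(s) for s in self.symbols], dtype=float
            )
        else:
            self.masses = np.asarray(self.masses, dtype=float)
            if self.masses.shape != (len(self.symbols),):
                raise DimensionMismatchError("masses shape mismatch")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be strictly positive")

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    @property
    def mass_vector(self) -> np.ndarray:
        """Per-Cartesian-component masses, length ``3 n_atoms``."""
        return np.repeat(self.masses, 3)

    def center_of_mass(self) -> np.ndarray:
        return self.masses @ self.coords / self.masses.sum()

    def copy(self) -> "Molecule":
        return Molecule(
            list(self.symbols), self.coords.copy(), self.masses.copy(),
            self.comment,
        )


def _default_mass(symbol: str) -> float:
    try:
        return ISOTOPE_MASSES_AMU[symbol] * units.AMU_TO_ME
    except KeyError:
        raise UnknownElementError(f"no mass tabulated for element {symbol!r}")


_MASS_DIRECTIVE = re.compile(r"mass\[(\d+)\]\s*=\s*([0-9.eEdD+-]+)")


def read_xyz(path: str | Path) -> Molecule:
    """Read a standard XYZ file (coordinates in angstrom).

    The comment line may carry per-atom mass overrides in amu, written as
    ``mass[i]=value`` with a zero-based atom index.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise MalformedCountError(f"{path}: empty file")
    try:
        n = int(lines[0].strip())
    except ValueError:
        raise MalformedCountError(
            f"{path}: first line {lines[0]!r} is not an atom count"
        ) from None
    if n <= 0:
        raise MalformedCountError(f"{path}: non-positive atom count {n}")
    comment = lines[1] if len(lines) > 1 else ""
    atom_lines = [l for l in lines[2:] if l.strip()]
    if len(atom_lines) < n:
        raise MalformedCountError(
            f"{path}: declared {n} atoms but found {len(atom_lines)}"
        )
    symbols: list[str] = []
    coords = np.empty((n, 3))
    for i, line in enumerate(atom_lines[:n]):
        parts = line.split()
        if len(parts) < 4:
            raise CoordinateParseError(f"{path}: atom line {i}: {line!r}")
        symbols.append(parts[0])
        try:
            coords[i] = [float(p) for p in parts[1:4]]
        except ValueError:
            raise CoordinateParseError(
                f"{path}: atom line {i}: {line!r}"
            ) from None
    masses = np.array([_default_mass(s) for s in symbols])
    for m in _MASS_DIRECTIVE.finditer(comment):
        idx = int(m.group(1))
        if idx >= n:
            raise MalformedCountError(
                f"{path}: mass override index {idx} out of range"
            )
        masses[idx] = float(m.group(2).replace("D", "e").replace("d", "e")) \
            * units.AMU_TO_ME
    return Molecule(symbols, coords * units.ANGSTROM_TO_BOHR, masses, comment)


def write_xyz(molecule: Molecule, path: str | Path) -> None:
    """Write a standard XYZ file (coordinates in angstrom)."""
    lines = [str(molecule.n_atoms), molecule.comment]
    ang = molecule.coords / units.ANGSTROM_TO_BOHR
    for sym, xyz in zip(molecule.symbols, ang):
        lines.append(f"{sym:<4s} {xyz[0]:20.12f} {xyz[1]:20.12f} {xyz[2]:20.12f}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Molden frequency files
# ---------------------------------------------------------------------------

def read_molden_freq(
    path: str | Path,
) -> tuple[Molecule, np.ndarray, np.ndarray]:
    """Read the frequency sections of a Molden file.

    Returns the geometry (``[FR-COORD]`` is in bohr already), the harmonic
    frequencies in cm^-1 in file order (negative values are the usual
    convention for imaginary modes and are kept as written), and the raw
    Cartesian displacement vectors as columns of a ``(3N, n_freq)`` array.
    Displacements are not re-orthonormalized here; that is the job of the
    normal-mode layer.
    """
    text = Path(path).read_text()
    sections = _split_molden_sections(text)
    for name in ("fr-coord", "freq", "fr-norm-coord"):
        if name not in sections:
            raise MoldenSectionError(f"{path}: missing [{name.upper()}] section")

    symbols, coords = [], []
    for line in sections["fr-coord"]:
        parts = line.split()
        if len(parts) < 4:
            raise CoordinateParseError(f"{path}: FR-COORD line {line!r}")
        symbols.append(parts[0])
        coords.append([float(p) for p in parts[1:4]])
    mol = Molecule(symbols, np.asarray(coords))

    freqs = np.array([float(l.split()[0]) for l in sections["freq"]])

    n3 = 3 * mol.n_atoms
    disps: list[np.ndarray] = []
    current: list[float] = []
    for line in sections["fr-norm-coord"]:
        if line.lower().startswith("vibration"):
            if current:
                disps.append(np.asarray(current))
            current = []
        else:
            current.extend(float(p) for p in line.split())
    if current:
        disps.append(np.asarray(current))
    if len(disps) != len(freqs):
        raise MoldenSectionError(
            f"{path}: {len(freqs)} frequencies but {len(disps)} displacement "
            "blocks"
        )
    for i, d in enumerate(disps):
        if d.size != n3:
            raise CoordinateParseError(
                f"{path}: vibration {i + 1} has {d.size} components, "
                f"expected {n3}"
            )
    return mol, freqs, np.column_stack(disps) if disps else np.empty((n3, 0))


def _split_molden_sections(text: str) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current: list[str] | None = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        m = re.match(r"\[([A-Za-z -]+)\]", line)
        if m:
            current = sections.setdefault(m.group(1).strip().lower(), [])
        elif current is not None:
            current.append(line)
    return sections


def write_molden_freq(
    molecule: Molecule,
    freqs_cm1: np.ndarray,
    displacements: np.ndarray,
    path: str | Path,
) -> None:
    """Write a minimal Molden frequency file (bohr coordinates)."""
    out = ["[Molden Format]", "[FR-COORD]"]
    for sym, xyz in zip(molecule.symbols, molecule.coords):
        out.append(f"{sym:<4s} {xyz[0]:18.10f} {xyz[1]:18.10f} {xyz[2]:18.10f}")
    out.append("[FREQ]")
    out.extend(f"{f:14.6f}" for f in np.atleast_1d(freqs_cm1))
    out.append("[FR-NORM-COORD]")
    for i in range(displacements.shape[1]):
        out.append(f"vibration {i + 1}")
        col = displacements[:, i].reshape(-1, 3)
        out.extend(
            f"{r[0]:18.10f} {r[1]:18.10f} {r[2]:18.10f}" for r in col
        )
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Plain-text Hessians
# ---------------------------------------------------------------------------

def read_hessian(path: str | Path, symmetry_tol: float = 1e-8) -> np.ndarray:
    """Read a plain-text Cartesian Hessian in E_h/bohr^2.

    Format: first line the atom count N, then 3N rows of 3N reals
    (row-major).  The matrix must be symmetric within ``symmetry_tol``
    relative to its norm; it is symmetrized on read as ``(H + H.T)/2``.
    """
    tokens = Path(path).read_text().split()
    if not tokens:
        raise HessianFormatError(f"{path}: empty file")
    try:
        n_atoms = int(tokens[0])
    except ValueError:
        raise HessianFormatError(
            f"{path}: first token {tokens[0]!r} is not an atom count"
        ) from None
    n3 = 3 * n_atoms
    values = tokens[1:]
    if len(values) != n3 * n3:
        raise HessianFormatError(
            f"{path}: expected {n3 * n3} matrix entries, found {len(values)}"
        )
    try:
        h = np.array(values, dtype=float).reshape(n3, n3)
    except ValueError:
        raise HessianFormatError(f"{path}: non-numeric Hessian entry") from None
    scale = max(np.abs(h).max(), 1.0)
    if np.abs(h - h.T).max() > symmetry_tol * scale:
        raise HessianFormatError(f"{path}: Hessian asymmetric beyond tolerance")
    return 0.5 * (h + h.T)


def write_hessian(hessian: np.ndarray, path: str | Path) -> None:
    h = np.asarray(hessian, dtype=float)
    n3 = h.shape[0]
    if h.shape != (n3, n3) or n3 % 3:
        raise DimensionMismatchError("Hessian must be 3N x 3N")
    rows = [str(n3 // 3)]
    rows.extend(" ".join(f"{v:22.14e}" for v in row) for row in h)
    Path(path).write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# Two-column tables (flux / cross-section / quantum-yield curves)
# ---------------------------------------------------------------------------

def read_table(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column whitespace table, '#' comments allowed; returns
    (x, y) sorted by x."""
    xs, ys = [], []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 2:
            raise CoordinateParseError(f"{path}: table line {raw!r}")
        xs.append(float(parts[0]))
        ys.append(float(parts[1]))
    x = np.asarray(xs)
    y = np.asarray(ys)
    order = np.argsort(x)
    return x[order], y[order]


def write_table(x: np.ndarray, y: np.ndarray, path: str | Path,
                header: str = "") -> None:
    lines = [f"# {h}" for h in header.splitlines()] if header else []
    lines.extend(f"{a:20.10e} {b:20.10e}" for a, b in zip(x, y))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Ensemble archives (HDF5, schema-versioned)
# ---------------------------------------------------------------------------

def write_ensemble(samples, mode_set, path: str | Path) -> None:
    """Write an ensemble of phase-space samples and its normal-mode set.

    All samples must share the given ``mode_set`` provenance; every sample
    field needed to reconstruct the ensemble losslessly is stored, including
    the RNG seed and the sampling-method tag.
    """
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = ARCHIVE_SCHEMA_VERSION
        f.attrs["kind"] = "ensemble"
        _write_mode_set(f.create_group("mode_set"), mode_set)
        g = f.create_group("samples")
        n = len(samples)
        g.attrs["n_samples"] = n
        if n == 0:
            return
        n_modes = len(samples[0].Q)
        n_atoms = samples[0].x.shape[0]
        for s in samples:
            if len(s.Q) != n_modes or s.x.shape[0] != n_atoms:
                raise DimensionMismatchError("inhomogeneous ensemble")
        g.create_dataset("Q", data=np.array([s.Q for s in samples]))
        g.create_dataset("P", data=np.array([s.P for s in samples]))
        g.create_dataset("x", data=np.array([s.x for s in samples]))
        g.create_dataset("p", data=np.array([s.p for s in samples]))
        g.create_dataset(
            "mode_energies", data=np.array([s.mode_energies for s in samples])
        )
        g.create_dataset(
            "method",
            data=np.array([s.method for s in samples], dtype="S16"),
        )
        g.create_dataset(
            "temperature", data=np.array([s.temperature for s in samples])
        )
        g.create_dataset("seed", data=np.array([s.seed for s in samples]))
        g.create_dataset("index", data=np.array([s.index for s in samples]))
        g.create_dataset(
            "target_energies",
            data=np.array([
                s.target_energies if s.target_energies is not None
                else np.full(n_modes, np.nan)
                for s in samples
            ]),
        )


def read_ensemble(path: str | Path):
    """Read an ensemble archive; returns ``(samples, mode_set)``."""
    from .initial_conditions import PhaseSpaceSample

    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != ARCHIVE_SCHEMA_VERSION:
            raise ArchiveVersionError(
                f"{path}: archive schema {version}, expected "
                f"{ARCHIVE_SCHEMA_VERSION}"
            )
        mode_set = _read_mode_set(f["mode_set"])
        g = f["samples"]
        n = int(g.attrs["n_samples"])
        samples = []
        if n:
            fields = {k: g[k][...] for k in
                      ("Q", "P", "x", "p", "mode_energies", "method",
                       "temperature", "seed", "index", "target_energies")}
            for i in range(n):
                tgt = fields["target_energies"][i]
                s = PhaseSpaceSample(
                    Q=fields["Q"][i], P=fields["P"][i],
                    x=fields["x"][i], p=fields["p"][i],
                    mode_energies=fields["mode_energies"][i],
                    method=fields["method"][i].decode(),
                    temperature=float(fields["temperature"][i]),
                    seed=int(fields["seed"][i]),
                    index=int(fields["index"][i]),
                    target_energies=None if np.all(np.isnan(tgt)) else tgt,
                )
                if not (np.all(np.isfinite(s.Q)) and np.all(np.isfinite(s.P))
                        and np.all(np.isfinite(s.x))
                        and np.all(np.isfinite(s.p))):
                    raise CorruptRecordError(
                        f"{path}: non-finite data in sample record {i}"
                    )
                samples.append(s)
    return samples, mode_set


def write_trajectories(trajectories, path: str | Path) -> None:
    """Write surface-hopping trajectories (snapshots at their stride)."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = ARCHIVE_SCHEMA_VERSION
        f.attrs["kind"] = "trajectories"
        f.attrs["n_trajectories"] = len(trajectories)
        for t_idx, traj in enumerate(trajectories):
            g = f.create_group(f"traj_{t_idx:05d}")
            g.attrs["seed"] = traj.seed
            g.attrs["termination"] = traj.termination
            g.attrs["frustrated"] = traj.frustrated
            g.create_dataset("times", data=traj.times)
            g.create_dataset("active_history", data=traj.active_history)
            g.create_dataset("energy_history", data=traj.energy_history)
            g.create_dataset(
                "hops", data=np.array(traj.hops, dtype=float).reshape(-1, 3)
            )
            g.create_dataset(
                "snap_time", data=np.array([s.time for s in traj.states])
            )
            g.create_dataset(
                "snap_Q", data=np.array([s.Q for s in traj.states])
            )
            g.create_dataset(
                "snap_P", data=np.array([s.P for s in traj.states])
            )
            g.create_dataset(
                "snap_active",
                data=np.array([s.active for s in traj.states]),
            )
            g.create_dataset(
                "snap_c", data=np.array([s.coefficients for s in traj.states])
            )
            g.create_dataset(
                "snap_energies",
                data=np.array([s.energies for s in traj.states]),
            )
            g.create_dataset(
                "snap_total_energy",
                data=np.array([s.total_energy for s in traj.states]),
            )


def read_trajectories(path: str | Path):
    """Read a trajectory archive written by :func:`write_trajectories`."""
    from .surface_hopping import Trajectory, TrajectoryState

    out = []
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != ARCHIVE_SCHEMA_VERSION:
            raise ArchiveVersionError(
                f"{path}: archive schema {version}, expected "
                f"{ARCHIVE_SCHEMA_VERSION}"
            )
        for t_idx in range(int(f.attrs["n_trajectories"])):
            g = f[f"traj_{t_idx:05d}"]
            states = [
                TrajectoryState(
                    time=float(g["snap_time"][i]),
                    Q=g["snap_Q"][i], P=g["snap_P"][i],
                    active=int(g["snap_active"][i]),
                    coefficients=g["snap_c"][i],
                    energies=g["snap_energies"][i],
                    total_energy=float(g["snap_total_energy"][i]),
                )
                for i in range(g["snap_time"].shape[0])
            ]
            out.append(Trajectory(
                states=states,
                times=g["times"][...],
                active_history=g["active_history"][...],
                energy_history=g["energy_history"][...],
                hops=[(float(a), int(b), int(c)) for a, b, c in g["hops"]],
                frustrated=int(g.attrs["frustrated"]),
                seed=int(g.attrs["seed"]),
                termination=str(g.attrs["termination"]),
            ))
    return out


def _write_mode_set(group: h5py.Group, mode_set) -> None:
    mol = mode_set.molecule
    group.create_dataset(
        "symbols", data=np.array(mol.symbols, dtype="S4")
    )
    group.create_dataset("coords", data=mol.coords)
    group.create_dataset("masses", data=mol.masses)
    group.attrs["comment"] = mol.comment
    group.create_dataset("omega", data=mode_set.omega)
    group.create_dataset("modes", data=mode_set.modes)
    group.create_dataset("imaginary", data=mode_set.imaginary)
    group.attrs["n_external"] = mode_set.n_external


def _read_mode_set(group: h5py.Group):
    from .normal_modes import NormalModeSet

    mol = Molecule(
        [s.decode() for s in group["symbols"][...]],
        group["coords"][...],
        group["masses"][...],
        str(group.attrs.get("comment", "")),
    )
    return NormalModeSet(
        molecule=mol,
        omega=group["omega"][...],
        modes=group["modes"][...],
        imaginary=group["imaginary"][...].astype(bool),
        n_external=int(group.attrs["n_external"]),
    )
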