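"""Unit registry and conversions.

Everything inside the package is expressed in Hartree atomic units
(hbar = m_e = e = a0 = 1); user-facing I/O accepts the common laboratory
units (angstrom, amu, cm^-1, eV, fs, K) and converts on ingest.  The
registry stores, for each unit name, its physical dimension and the exact
multiplicative factor to the atomic unit of that dimension, so any
conversion is a single ratio and round trips are exact to floating point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import IncompatibleUnitsError, UnitError

# Conversion factors to atomic units.
AMU_TO_ME = 1822.888486          # electron masses per unified amu
ANGSTROM_TO_BOHR = 1.8897261258
CM1_TO_HARTREE = 4.556335e-6
EV_TO_HARTREE = 3.674932e-2
FS_TO_AUT = 41.341374            # atomic time units per femtosecond
KB_HARTREE_PER_K = 3.166811563e-6
HBAR = 1.0

# lab conventions used by the spectroscopy layer
NM_EV = 1239.841984              # lambda(nm) * E(eV) for a photon


@dataclass(frozen=True)
class _Unit:
    dimension: str
    to_atomic: float


@dataclass
class UnitRegistry:
    """Registry of named units grouped by dimension.

    ``convert(v, a, b)`` multiplies by the exact ratio of the two registered
    factors; converting through any intermediate unit therefore agrees with
    the direct conversion to full precision.
    """

    units: dict[str, _Unit] = field(default_factory=dict)

    def register(self, name: str, dimension: str, to_atomic: float) -> None:
        self.units[name] = _Unit(dimension, to_atomic)

    def _lookup(self, name: str) -> _Unit:
        try:
            return self.units[name]
        except KeyError:
            raise UnitError(f"unknown unit {name!r}") from None

    def convert(self, value: float, from_unit: str, to_unit: str) -> float:
        a, b = self._lookup(from_unit), self._lookup(to_unit)
        if a.dimension != b.dimension:
            raise IncompatibleUnitsError(
                f"cannot convert {from_unit!r} ({a.dimension}) "
                f"to {to_unit!r} ({b.dimension})"
            )
        return value * (a.to_atomic / b.to_atomic)


def default_registry() -> UnitRegistry:
    reg = UnitRegistry()
    # length
    reg.register("bohr", "length", 1.0)
    reg.register("angstrom", "length", ANGSTROM_TO_BOHR)
    # mass
    reg.register("m_e", "mass", 1.0)
    reg.register("amu", "mass", AMU_TO_ME)
    # energy
    reg.register("hartree", "energy", 1.0)
    reg.register("cm-1", "energy", CM1_TO_HARTREE)
    reg.register("eV", "energy", EV_TO_HARTREE)
    reg.register("kelvin", "energy", KB_HARTREE_PER_K)  # k_B T shorthand
    # time
    reg.register("aut", "time", 1.0)
    reg.register("fs", "time", FS_TO_AUT)
    return reg


#: Shared default registry used by all module-level helpers.
REGISTRY = default_registry()


def convert(value: float, from_unit: str, to_unit: str) -> float:
    """Convert ``value`` between two registered units of one dimension."""
    return REGISTRY.convert(value, from_unit, to_unit)
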