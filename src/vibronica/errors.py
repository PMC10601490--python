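"""Named exceptions raised across the package.

Every malformed-input condition maps to a distinct class so callers (and the
CLI) can react to the exact failure mode instead of string-matching messages.
"""


class VibronicaError(Exception):
    """Base class for all package errors."""


class UnitError(VibronicaError):
    """Unknown unit name."""


class IncompatibleUnitsError(UnitError):
    """Conversion requested between units of different dimensions."""


class XYZError(VibronicaError):
    """Base class for XYZ parsing failures."""


class MalformedCountError(XYZError):
    """The atom-count line of an XYZ file is not a positive integer, or the
    declared count disagrees with the number of atom lines present."""


class UnknownElementError(XYZError):
    """An element symbol has no entry in the mass table and no override."""


class CoordinateParseError(XYZError):
    """An atom line does not contain three parseable real coordinates."""


class MoldenSectionError(VibronicaError):
    """A required Molden section ([FREQ], [FR-COORD], [FR-NORM-COORD]) is
    missing; the message names the section."""


class HessianFormatError(VibronicaError):
    """Plain-text Hessian file malformed or asymmetric beyond tolerance."""


class ArchiveVersionError(VibronicaError):
    """Ensemble/trajectory archive written with an unsupported schema
    version."""


class CorruptRecordError(VibronicaError):
    """An archive record failed validation; the message names the record
    index."""


class DimensionMismatchError(VibronicaError):
    """Array arguments have inconsistent shapes."""


class SamplingError(VibronicaError):
    """Invalid sampling request (negative temperature, zero-frequency mode in
    the sampled set, unknown scheme, ...)."""


class ModelError(VibronicaError):
    """Invalid linear-vibronic-coupling model construction or evaluation."""


class PropagationError(VibronicaError):
    """Invalid surface-hopping propagation input (non-finite state,
    non-positive time step, ...)."""


class SpectrumError(VibronicaError):
    """Invalid spectroscopy request (non-positive width, empty ensemble,
    non-overlapping wavelength windows, ...)."""


class KineticsError(VibronicaError):
    """Invalid rate-equation model (negative off-diagonal rate, ...)."""
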