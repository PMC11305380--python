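"""Exception hierarchy.

Everything raised on a bad input or an out-of-domain request derives from
:class:`GsspinError`, so callers (and the CLI) can distinguish usage errors
from genuine bugs.
"""


class GsspinError(Exception):
    """Base class for all package errors."""


class UnsupportedElementError(GsspinError):
    """Metal outside the supported first-row set, or element without data."""


class ValidationError(GsspinError):
    """Inconsistent or out-of-range input values."""


class MissingRadiusError(GsspinError):
    """No covalent radius available for an element encountered in a structure."""

    def __init__(self, element: str):
        self.element = element
        super().__init__(f"no covalent radius for element {element!r}")


class EmptyCoordinationSphereError(GsspinError):
    """No atom falls within the bonding cutoff of the metal."""


class ShapeMismatchError(GsspinError):
    """Vertex count does not match the reference polyhedron."""


class DegenerateGeometryError(GsspinError):
    """All vertices coincide; the shape measure is undefined."""


class UnsupportedCoordinationError(GsspinError):
    """No reference polyhedron with the requested coordination number."""


class OutOfRuleDomainError(GsspinError):
    """The simple unpaired-electron rule does not apply to this d-count."""


class UnassignableError(GsspinError):
    """The decision tree could not reach a terminal rule."""

    def __init__(self, message: str, trace=None):
        self.trace = list(trace or [])
        super().__init__(message)


class AllStatesFailedError(GsspinError):
    """Every spin-state computation for a complex failed to converge."""


class InfeasibleSamplingError(GsspinError):
    """Stratified-sampling target smaller than the number of groups."""


class DegenerateLabelsError(GsspinError):
    """Training labels contain a single class."""


class IncompleteInputError(GsspinError):
    """A feature-vector slot has no upstream value."""


class XYZParseError(GsspinError):
    """Malformed XYZ file."""


class ConfigError(GsspinError):
    """Invalid configuration file or entry."""
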