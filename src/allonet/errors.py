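"""Exception hierarchy shared across the package.

Grouping: data errors (bad or inconsistent input), convergence/stability
errors (the simulation engine), and usage errors (CLI-level). The CLI maps
these onto exit codes 2 and 3 respectively.
"""


class AllonetError(Exception):
    """Base class for all package errors."""


class DataError(AllonetError):
    """Malformed or inconsistent input data."""


class AlignmentFormatError(DataError):
    """Sequences of unequal length, or otherwise not a valid alignment."""


class IdentifierError(DataError):
    """Duplicate or mismatched sequence/leaf identifiers."""


class EmptyInputError(DataError):
    """An input file or collection with no usable content."""


class EmptyResultError(DataError):
    """An operation removed everything (e.g. all columns filtered out)."""


class StructureError(DataError):
    """A structure file without usable coordinates."""


class SerializationError(DataError):
    """A value that cannot be written faithfully (e.g. NaN in a matrix)."""


class SiteError(DataError):
    """A site definition that cannot be resolved in the structure."""


class TreeError(DataError):
    """A phylogenetic tree that cannot be parsed or is too small."""


class ConnectivityError(DataError):
    """An elastic network with disconnected components."""


class ConvergenceError(AllonetError):
    """Equilibration failed to reach the fluctuation criterion."""


class StabilityError(AllonetError):
    """Numerical blow-up during integration; reduce the timestep."""


class ConfigError(AllonetError):
    """Unknown or invalid configuration key."""
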