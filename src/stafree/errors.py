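"""Exception hierarchy.

All package errors derive from :class:`StafreeError`. Input/parse problems map
to CLI exit code 1, solver failures to exit code 2.
"""


class StafreeError(Exception):
    """Base class for all stafree errors."""


class InputError(StafreeError):
    """Invalid or inconsistent input data or configuration."""


class ParseError(InputError):
    """A marker/config file could not be parsed."""


class DegeneratePairError(InputError):
    """Two points that must be distinct coincide (within epsilon)."""


class SolverError(StafreeError):
    """A numerical solve failed or is ill-posed."""


class DegenerateMotionError(SolverError):
    """Insufficient relative rotation to determine a joint position."""


class ShapeSolveError(SolverError):
    """The quadratic shape (distance-identity) system could not be solved."""
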